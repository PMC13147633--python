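"""Over-representation analysis against a user-supplied gene-set collection.

Queries (hub neighbourhoods, network communities) are tested with the
one-sided hypergeometric upper tail P(X >= k) against a panel-restricted
background — the full gene panel the expression data was measured on —
rather than a whole-genome universe, to avoid panel-composition bias.  One
BH family is applied per query.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .corrnet import bh_adjust
from .dcn import DifferentialNetwork

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_upper",
    "hub_neighborhood",
    "enrich",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style); descriptions retained for round-trips."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str | None = None

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description,
    then member genes (duplicates within a line are collapsed)."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields (name, description, genes), got {len(fields)}"
                )
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {g for g in genes if g}
            descriptions[name] = desc
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=descriptions, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes in ``n`` draws without replacement from a population
    of ``N`` containing ``K`` successes.  Evaluated as the survival function
    at k-1 (log-space internally), exact to floating precision.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= k <= min(n, K)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N} "
            "(need 0 <= k <= min(n, K) and K, n <= N)"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hub_neighborhood(
    dcn: DifferentialNetwork, hub: str, sign: str = "both"
) -> set[str]:
    """The hub gene plus its first neighbours joined by edges of the
    requested sign ('positive': stronger co-expression in responders,
    'negative': stronger in non-responders, or 'both')."""
    if sign not in ("positive", "negative", "both"):
        raise ValueError(f"sign must be positive/negative/both, got {sign!r}")
    if hub not in set(dcn.nodes):
        raise KeyError(f"unknown hub gene {hub!r}")
    out = {hub}
    for e in dcn.edges:
        if hub not in (e.gene_a, e.gene_b):
            continue
        if sign == "positive" and e.Z <= 0:
            continue
        if sign == "negative" and e.Z >= 0:
            continue
        out.add(e.gene_b if e.gene_a == hub else e.gene_a)
    return out


def enrich(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str],
    min_term_size: int = 3,
    include_zero_overlap: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each collection set.

    Every term is first intersected with the background; terms with fewer
    than ``min_term_size`` background genes are dropped, as are terms with no
    overlap (both guards configurable).  Returns a table with columns
    (term, k, n, K, N, p, q) sorted by q then p; BH is applied across the
    tested terms of this one query.
    """
    background = set(background)
    query = set(query) & background
    if not query:
        raise ValueError("query is empty after intersection with the background")
    N = len(background)
    n = len(query)
    rows = []
    for term, genes in collection.sets.items():
        term_bg = genes & background
        K = len(term_bg)
        if K < min_term_size:
            continue
        k = len(query & term_bg)
        if k == 0 and not include_zero_overlap:
            continue
        rows.append(
            {"term": term, "k": k, "n": n, "K": K, "N": N,
             "p": hypergeom_upper(k, K, n, N)}
        )
    table = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table = table.sort_values(["q", "p", "term"], kind="mergesort")
        table = table.reset_index(drop=True)
    else:
        table["q"] = np.nan
    return table
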