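"""Spearman correlation networks for immune-profile and expression tables.

A correlation network here is an undirected weighted graph over the variables
of a samples x variables table: an edge joins two variables whose Spearman
correlation clears both an absolute-magnitude threshold and a
Benjamini-Hochberg FDR threshold, and carries the signed coefficient as its
weight.  Variables that are constant across samples cannot be ranked and are
retained as isolated nodes so the node universe stays comparable across
patient groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "WeightedNetwork",
    "NetworkSummary",
    "spearman_matrix",
    "bh_adjust",
    "build_correlation_network",
    "network_summary",
    "cross_correlation",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class CorrelationResult:
    """Pairwise Spearman coefficients with per-pair p and BH q values.

    ``rho``, ``pvalue`` and ``qvalue`` are symmetric V x V DataFrames indexed
    by variable name; entries involving a constant variable are NaN and the
    offending variables are listed in ``constant_variables``.  BH adjustment
    is applied once over the V(V-1)/2 unordered, defined pairs.
    """

    rho: pd.DataFrame
    pvalue: pd.DataFrame
    qvalue: pd.DataFrame
    n_samples: int
    constant_variables: list[str] = field(default_factory=list)


@dataclass
class WeightedNetwork:
    """Undirected correlation network; edge weight = signed Spearman rho."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]
    metadata: dict = field(default_factory=dict)

    def degree(self) -> dict[str, int]:
        d = {n: 0 for n in self.nodes}
        for a, b, _ in self.edges:
            d[a] += 1
            d[b] += 1
        return d

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(**self.metadata)
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    degree: dict[str, int]
    n_components: int


# ---------------------------------------------------------------------------
# core statistics


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    NaN entries (undefined tests, e.g. involving a constant variable) are
    passed through as NaN and do not count toward the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    flat = p.ravel()
    defined = ~np.isnan(flat)
    vals = flat[defined]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out.reshape(p.shape)
    order = np.argsort(vals, kind="mergesort")
    q = vals[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    res = np.empty(m)
    res[order] = q
    out_flat = out.ravel()
    out_flat[defined] = res
    return out_flat.reshape(p.shape)


def _spearman_rho_p(ranked: np.ndarray, n: int):
    """rho and t-approximation p-values from an already rank-transformed
    (midranks) samples x variables array.  Columns with zero variance must be
    excluded by the caller."""
    rho = np.corrcoef(ranked, rowvar=False)
    rho = np.clip(rho, -1.0, 1.0)
    r = np.clip(rho, -0.9999999999, 0.9999999999)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return rho, p


def spearman_matrix(table: pd.DataFrame) -> CorrelationResult:
    """All-pairs Spearman correlation of a samples x variables table.

    Coefficients are Pearson correlations of midranks; p-values use the
    t-approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df, which is the
    standard choice at the cohort sizes this package targets (n ~ 20-44).
    Constant variables are flagged and their rows/columns set to NaN rather
    than dropped.
    """
    table = _as_frame(table)
    n, v = table.shape
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    values = table.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("table contains missing values")
    const = [c for j, c in enumerate(table.columns) if np.ptp(values[:, j]) == 0]
    ok = [j for j, c in enumerate(table.columns) if c not in set(const)]
    rho = np.full((v, v), np.nan)
    pval = np.full((v, v), np.nan)
    if len(ok) >= 2:
        ranked = np.apply_along_axis(stats.rankdata, 0, values[:, ok])
        r_ok, p_ok = _spearman_rho_p(ranked, n)
        rho[np.ix_(ok, ok)] = r_ok
        pval[np.ix_(ok, ok)] = p_ok
    for j in ok:
        rho[j, j] = 1.0
        pval[j, j] = 0.0
    iu = np.triu_indices(v, 1)
    q_upper = bh_adjust(pval[iu])
    qval = np.full((v, v), np.nan)
    qval[iu] = q_upper
    qval[(iu[1], iu[0])] = q_upper
    cols = table.columns
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        pvalue=pd.DataFrame(pval, index=cols, columns=cols),
        qvalue=pd.DataFrame(qval, index=cols, columns=cols),
        n_samples=n,
        constant_variables=const,
    )


def spearman_permutation_p(
    x, y, n_permutations: int = 10_000, seed: int = 0
) -> float:
    """Seeded two-sided permutation p-value for a single Spearman coefficient.

    Offered for very small samples (n < 10) where the t-approximation is
    coarse; not used by the network builders by default.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    obs = stats.spearmanr(x, y).statistic
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        r = stats.spearmanr(x, rng.permutation(y)).statistic
        if abs(r) >= abs(obs) - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# network construction


def build_correlation_network(
    table: pd.DataFrame,
    rho_min: float = 0.55,
    q_max: float = 0.05,
    metadata: dict | None = None,
    precomputed: CorrelationResult | None = None,
) -> WeightedNetwork:
    """Threshold a Spearman matrix into a weighted network.

    An edge (i, j) is present iff |rho_ij| > rho_min and q_ij < q_max.  The
    default thresholds are the circulating-immune-profile settings
    (|rho| > 0.55, FDR < 0.05); expression networks use 0.7 via
    :func:`netstrat.dcn.build_coexpression_networks`.
    """
    if not 0 <= rho_min < 1:
        raise ValueError(f"rho_min must be in [0, 1), got {rho_min}")
    res = precomputed if precomputed is not None else spearman_matrix(table)
    cols = list(res.rho.columns)
    rho = res.rho.to_numpy()
    q = res.qvalue.to_numpy()
    edges = []
    v = len(cols)
    for i in range(v):
        for j in range(i + 1, v):
            r = rho[i, j]
            if np.isnan(r):
                continue
            if abs(r) > rho_min and q[i, j] < q_max:
                edges.append((cols[i], cols[j], float(r)))
    meta = dict(metadata or {})
    meta.update(rho_min=rho_min, q_max=q_max, n_samples=res.n_samples)
    return WeightedNetwork(nodes=cols, edges=edges, metadata=meta)


def network_summary(net: WeightedNetwork) -> NetworkSummary:
    """Node/edge counts, sign split, per-node degree and component count."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((a, b) for a, b, _ in net.edges)
    pos = sum(1 for _, _, w in net.edges if w > 0)
    return NetworkSummary(
        n_nodes=len(net.nodes),
        n_edges=len(net.edges),
        n_positive=pos,
        n_negative=len(net.edges) - pos,
        degree=net.degree(),
        n_components=nx.number_connected_components(g),
    )


def cross_correlation(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Rectangular Spearman correlation between two variable sets measured on
    the same samples (e.g. immune subsets vs hub-gene expression).

    Returns (rho, p, q) as A x B DataFrames; BH is applied over all A*B pairs.
    """
    table_a = _as_frame(table_a)
    table_b = _as_frame(table_b)
    if list(table_a.index) != list(table_b.index):
        missing = sorted(
            set(table_a.index).symmetric_difference(table_b.index)
        )
        raise ValueError(
            "tables must share an identically ordered sample set; "
            f"mismatched or misordered ids: {missing or list(table_a.index)}"
        )
    n = table_a.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    a_cols, b_cols = list(table_a.columns), list(table_b.columns)
    # positional names avoid collisions when the two tables share variables
    left = table_a.set_axis([f"a{i}" for i in range(len(a_cols))], axis=1)
    right = table_b.set_axis([f"b{i}" for i in range(len(b_cols))], axis=1)
    res = spearman_matrix(pd.concat([left, right], axis=1))
    rho = res.rho.iloc[: len(a_cols), len(a_cols):].to_numpy()
    p = res.pvalue.iloc[: len(a_cols), len(a_cols):].to_numpy()
    q = bh_adjust(p)
    mk = lambda m: pd.DataFrame(m, index=a_cols, columns=b_cols)
    return mk(rho), mk(p), mk(q)


def write_edge_list(net: WeightedNetwork, path) -> None:
    """Edge list as TSV: node_a, node_b, weight."""
    rows = [{"node_a": a, "node_b": b, "weight": w} for a, b, w in net.edges]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    arr = np.asarray(table, dtype=float)
    return pd.DataFrame(
        arr, columns=[f"v{j}" for j in range(arr.shape[1])]
    )
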