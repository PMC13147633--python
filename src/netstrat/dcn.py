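"""Differential co-expression network (DCN) construction and topology.

Two group-wise co-expression networks (Spearman |rho| > 0.7, FDR < 0.05) are
compared pair by pair with the Fisher z-test for the difference of two
correlations,

    Z = (atanh(rho_A) - atanh(rho_B)) / sqrt(1/(n_A - 3) + 1/(n_B - 3)),

and gene pairs with |Z| > 2 form the DCN.  A positive edge marks a pair more
strongly co-expressed in group A (responders); negative, in group B.  Hubs
are the right tail of the DCN degree distribution (95th percentile by
default) and communities come from seeded Louvain modularity optimisation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corrnet import WeightedNetwork, build_correlation_network, spearman_matrix

__all__ = [
    "DifferentialEdge",
    "DifferentialNetwork",
    "HubSet",
    "CommunityPartition",
    "fisher_z",
    "differential_z",
    "build_coexpression_networks",
    "build_dcn",
    "select_hubs",
    "louvain_communities",
    "modularity",
]

#: variance of atanh(rho) is 1/(n-3) for Pearson; rank-based coefficients are
#: slightly over-dispersed and 1.06/(n-3) is the classical correction.
SPEARMAN_VARIANCE_INFLATION = 1.06


@dataclass
class DifferentialEdge:
    gene_a: str
    gene_b: str
    rho_A: float
    rho_B: float
    n_A: int
    n_B: int
    Z: float

    @property
    def z_A(self) -> float:
        return fisher_z(self.rho_A)

    @property
    def z_B(self) -> float:
        return fisher_z(self.rho_B)


@dataclass
class DifferentialNetwork:
    nodes: list[str]
    edges: list[DifferentialEdge]
    z_min: float = 2.0
    metadata: dict = field(default_factory=dict)

    def degree(self) -> dict[str, int]:
        d = {n: 0 for n in self.nodes}
        for e in self.edges:
            d[e.gene_a] += 1
            d[e.gene_b] += 1
        return d

    def to_networkx(self, weighted: bool = False):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            w = abs(e.Z) if weighted else 1.0
            g.add_edge(e.gene_a, e.gene_b, weight=w, Z=e.Z, sign=int(np.sign(e.Z)))
        return g

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_a": e.gene_a,
                    "gene_b": e.gene_b,
                    "rho_A": e.rho_A,
                    "rho_B": e.rho_B,
                    "Z": e.Z,
                }
                for e in self.edges
            ],
            columns=["gene_a", "gene_b", "rho_A", "rho_B", "Z"],
        )


@dataclass
class HubSet:
    genes: list[str]          # sorted by degree, descending
    degree: dict[str, int]
    percentile_used: float
    degree_threshold: float


@dataclass
class CommunityPartition:
    membership: dict[str, int]
    modularity_Q: float


# ---------------------------------------------------------------------------
# the differential test


def fisher_z(rho: float) -> float:
    """Variance-stabilising transform z = atanh(rho); requires |rho| < 1."""
    if abs(rho) >= 1:
        raise ValueError(f"|rho| must be < 1 for the Fisher transform, got {rho}")
    return math.atanh(rho)


def differential_z(
    rho_A: float,
    rho_B: float,
    n_A: int,
    n_B: int,
    variance_inflation: float = 1.0,
) -> float:
    """Z-statistic for the difference of two independent correlations.

    ``variance_inflation`` scales the 1/(n-3) variance of each transformed
    coefficient; 1.0 reproduces the classical Pearson-based test (the
    convention this pipeline follows even for Spearman coefficients), while
    ``SPEARMAN_VARIANCE_INFLATION`` (1.06) applies the rank-based correction.
    """
    if n_A <= 3 or n_B <= 3:
        raise ValueError(f"group sizes must exceed 3, got n_A={n_A}, n_B={n_B}")
    den = math.sqrt(variance_inflation * (1.0 / (n_A - 3) + 1.0 / (n_B - 3)))
    return (fisher_z(rho_A) - fisher_z(rho_B)) / den


# ---------------------------------------------------------------------------
# network construction


def _split_groups(expr: pd.DataFrame, groups) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a genes x samples matrix into (group A, group B) sub-matrices.

    ``groups`` maps sample id -> label; the two labels are taken in sorted
    order unless exactly {'responder','non-responder'}-style labels are used,
    in which case 'responder' is group A.
    """
    groups = dict(groups)
    missing = [s for s in expr.columns if s not in groups]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    labels = sorted({groups[s] for s in expr.columns})
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    # responders are conventionally group A (positive Z = stronger in responders)
    for resp in ("responder", "R", "res"):
        if resp in labels:
            labels = [resp] + [l for l in labels if l != resp]
            break
    a_cols = [s for s in expr.columns if groups[s] == labels[0]]
    b_cols = [s for s in expr.columns if groups[s] == labels[1]]
    return expr[a_cols], expr[b_cols]


def build_coexpression_networks(
    expr: pd.DataFrame,
    groups,
    rho_min: float = 0.7,
    q_max: float = 0.05,
) -> tuple[WeightedNetwork, WeightedNetwork]:
    """Per-group co-expression networks from a genes x samples matrix."""
    expr_a, expr_b = _split_groups(expr, groups)
    if expr_a.shape[1] <= 3 or expr_b.shape[1] <= 3:
        raise ValueError(
            "each group needs more than 3 samples, got "
            f"{expr_a.shape[1]} and {expr_b.shape[1]}"
        )
    nets = []
    for tbl, name in ((expr_a, "A"), (expr_b, "B")):
        net = build_correlation_network(
            tbl.T, rho_min=rho_min, q_max=q_max, metadata={"group": name}
        )
        nets.append(net)
    return nets[0], nets[1]


def build_dcn(
    expr: pd.DataFrame,
    groups,
    z_min: float = 2.0,
    rho_min: float = 0.7,
    q_max: float = 0.05,
    pair_universe: str = "union_of_networks",
    variance_inflation: float = 1.0,
) -> DifferentialNetwork:
    """Differential co-expression network between two response groups.

    The candidate pair set defaults to the union of the two group
    co-expression networks' edge sets (the group networks are built first,
    then differenced); ``pair_universe='all_pairs'`` tests every gene pair.
    Pairs with a perfect sample correlation in either group are excluded with
    a warning (the Fisher transform diverges).
    """
    if pair_universe not in ("union_of_networks", "all_pairs"):
        raise ValueError(f"unknown pair_universe: {pair_universe!r}")
    expr_a, expr_b = _split_groups(expr, groups)
    n_a, n_b = expr_a.shape[1], expr_b.shape[1]
    if n_a <= 3 or n_b <= 3:
        raise ValueError("each group needs more than 3 samples")
    res_a = spearman_matrix(expr_a.T)
    res_b = spearman_matrix(expr_b.T)
    genes = list(expr.index)
    index = {g: i for i, g in enumerate(genes)}

    if pair_universe == "union_of_networks":
        net_a = build_correlation_network(
            expr_a.T, rho_min=rho_min, q_max=q_max, precomputed=res_a
        )
        net_b = build_correlation_network(
            expr_b.T, rho_min=rho_min, q_max=q_max, precomputed=res_b
        )
        candidates = sorted(
            {tuple(sorted((a, b))) for a, b, _ in net_a.edges}
            | {tuple(sorted((a, b))) for a, b, _ in net_b.edges}
        )
    else:
        candidates = [
            (genes[i], genes[j])
            for i in range(len(genes))
            for j in range(i + 1, len(genes))
        ]

    rho_a = res_a.rho.to_numpy()
    rho_b = res_b.rho.to_numpy()
    den = math.sqrt(
        variance_inflation * (1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    )
    edges = []
    n_excluded = 0
    for ga, gb in candidates:
        i, j = index[ga], index[gb]
        ra, rb = rho_a[i, j], rho_b[i, j]
        if np.isnan(ra) or np.isnan(rb):
            continue
        if abs(ra) >= 1.0 or abs(rb) >= 1.0:
            n_excluded += 1
            continue
        z = (math.atanh(ra) - math.atanh(rb)) / den
        if abs(z) > z_min:
            edges.append(
                DifferentialEdge(ga, gb, float(ra), float(rb), n_a, n_b, float(z))
            )
    if n_excluded:
        warnings.warn(
            f"{n_excluded} gene pair(s) with a perfect sample correlation "
            "were excluded from the differential test",
            stacklevel=2,
        )
    return DifferentialNetwork(
        nodes=genes,
        edges=edges,
        z_min=z_min,
        metadata={
            "n_A": n_a,
            "n_B": n_b,
            "rho_min": rho_min,
            "q_max": q_max,
            "pair_universe": pair_universe,
            "n_excluded_perfect": n_excluded,
        },
    )


# ---------------------------------------------------------------------------
# topology


def select_hubs(net: DifferentialNetwork, percentile: float = 95.0) -> HubSet:
    """Right-tail hub selection on the DCN degree distribution.

    The threshold is the requested percentile (linear interpolation) of the
    degrees of nodes with degree >= 1.  Hubs are the nodes strictly above the
    threshold, together with any node tied at the smallest degree that made
    the cut — so discrete ties at the boundary are kept rather than split
    arbitrarily.
    """
    if not net.edges:
        raise ValueError("cannot select hubs from an empty network")
    deg = net.degree()
    nonzero = np.array([d for d in deg.values() if d >= 1])
    threshold = float(np.percentile(nonzero, percentile))
    above = [g for g, d in deg.items() if d > threshold]
    if above:
        min_included = min(deg[g] for g in above)
        above = [g for g, d in deg.items() if d > threshold or d == min_included]
    hubs = sorted(above, key=lambda g: (-deg[g], g))
    return HubSet(
        genes=hubs,
        degree={g: deg[g] for g in hubs},
        percentile_used=percentile,
        degree_threshold=threshold,
    )


def louvain_communities(
    net: DifferentialNetwork,
    resolution: float = 1.0,
    seed: int = 0,
    weighted: bool = False,
) -> CommunityPartition:
    """Louvain modularity communities of the DCN (unweighted by default;
    ``weighted=True`` uses |Z| edge weights).  Deterministic under the seed.
    """
    import networkx as nx

    if not net.edges:
        raise ValueError("cannot detect communities in an empty network")
    g = net.to_networkx(weighted=weighted)
    comms = nx.community.louvain_communities(
        g, weight="weight" if weighted else None, resolution=resolution, seed=seed
    )
    membership = {}
    for cid, members in enumerate(comms):
        for node in members:
            membership[node] = cid
    q = nx.community.modularity(
        g, comms, weight="weight" if weighted else None, resolution=resolution
    )
    return CommunityPartition(membership=membership, modularity_Q=float(q))


def modularity(
    net: DifferentialNetwork, membership: dict[str, int], weighted: bool = False
) -> float:
    """Newman modularity Q of a node -> community assignment on the DCN."""
    import networkx as nx

    missing = [n for n in net.nodes if n not in membership]
    if missing:
        raise ValueError(f"nodes missing from membership: {missing[:5]}")
    g = net.to_networkx(weighted=weighted)
    groups: dict[int, set] = {}
    for node, cid in membership.items():
        groups.setdefault(cid, set()).add(node)
    return float(
        nx.community.modularity(
            g, list(groups.values()), weight="weight" if weighted else None
        )
    )
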