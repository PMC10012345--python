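"""Global structural properties, triad motifs, scaling, and clustering.

Inferred networks can look statistically similar yet be structurally
unlike a real GRN.  This module computes a 13-property global profile per
network — regulator / self-regulation / max-out-connectivity / giant
component fractions, density times regulator fraction, three normalized
triad-motif densities, average clustering, normalized diameter and
average path length, and power-law goodness of fit (R^2) for the degree
distribution P(k) and the clustering-by-degree curve C(k) — scales each
property to [0, 1] across networks, and clusters the profiles with
Ward's method (optionally on the pairwise Pearson-correlation rows).

Motif densities are counts divided by the number of potential motifs
n!/(n-r)! * (TFn/n)^TFm, with r = 3 and TFm = 2 for feedforward and
complex-feedforward loops and TFm = 3 for three-node feedback loops
(those need three regulators).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .netio import GeneNetwork

logger = logging.getLogger(__name__)

#: Profile fields used as the clustering vector, in report order.
PROFILE_FIELDS = (
    "regulators_frac",
    "selfreg_frac",
    "kmax_out_frac",
    "density_x_regfrac",
    "ffl_norm",
    "complex_ffl_norm",
    "fbl3_norm",
    "giant_frac",
    "avg_clustering",
    "diameter_norm",
    "avg_path_norm",
    "r2_pk",
    "r2_ck",
)


@dataclass(frozen=True)
class MotifCounts:
    ffl: int
    complex_ffl: int
    fbl3: int
    n: int
    tf_n: int
    r: int = 3
    tf_m_ffl: int = 2
    tf_m_fbl: int = 3


@dataclass(frozen=True)
class StructuralProfile:
    network: str
    n_nodes: int
    n_components: int
    regulators_frac: float
    selfreg_frac: float
    kmax_out_frac: float
    density_x_regfrac: float
    ffl_norm: float
    complex_ffl_norm: float
    fbl3_norm: float
    giant_frac: float
    avg_clustering: float
    diameter_norm: float
    avg_path_norm: float
    r2_pk: float
    r2_ck: float

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PROFILE_FIELDS], dtype=float)


# ---------------------------------------------------------------------------
# Triad motifs


def _classify_triad(arcs: frozenset[tuple[int, int]]) -> str | None:
    """Classify the induced arc set of a node triple {0,1,2}.

    Exact-pattern matching keeps the three classes mutually exclusive:
    a feedforward loop is exactly {A>B, A>C, B>C}; the complex variant
    adds the reciprocal B>A arc (the two regulators regulate each other);
    a 3-feedback loop is exactly a directed 3-cycle.
    """
    m = len(arcs)
    if m == 3:
        for a, b, c in permutations((0, 1, 2)):
            if arcs == {(a, b), (a, c), (b, c)}:
                return "ffl"
        if arcs in ({(0, 1), (1, 2), (2, 0)}, {(0, 2), (2, 1), (1, 0)}):
            return "fbl3"
        return None
    if m == 4:
        for a, b, c in permutations((0, 1, 2)):
            if arcs == {(a, b), (b, a), (a, c), (b, c)}:
                return "complex_ffl"
    return None


def count_triad_motifs(network: GeneNetwork, tf_set: frozenset[str] | None = None) -> MotifCounts:
    """Count FFL / complex-FFL / 3-feedback-loop triads, each triple once.

    Self-loops are ignored.  3-feedback loops are only counted when all
    three members are TFs (the motif requires three regulators); the FFL
    variants inherently involve two TFs as sources.
    """
    if not network.directed:
        raise ValueError("triad motifs require a directed network")
    tfs = frozenset(tf_set) if tf_set is not None else network.regulators
    out: dict[str, set[str]] = {}
    nbrs: dict[str, set[str]] = {}
    arcs = set()
    for u, v in network.edges:
        if u == v:
            continue
        arcs.add((u, v))
        out.setdefault(u, set()).add(v)
        nbrs.setdefault(u, set()).add(v)
        nbrs.setdefault(v, set()).add(u)
    # Candidate triples: an edge plus any neighbor of either endpoint.
    # Every motif has >=3 arcs, so it contains such a configuration.
    triples: set[frozenset[str]] = set()
    for u, v in arcs:
        for w in (nbrs.get(u, set()) | nbrs.get(v, set())) - {u, v}:
            triples.add(frozenset((u, v, w)))
    counts = {"ffl": 0, "complex_ffl": 0, "fbl3": 0}
    for triple in triples:
        a, b, c = sorted(triple)
        idx = {a: 0, b: 1, c: 2}
        induced = frozenset(
            (idx[x], idx[y])
            for x, y in ((a, b), (b, a), (a, c), (c, a), (b, c), (c, b))
            if (x, y) in arcs
        )
        kind = _classify_triad(induced)
        if kind == "fbl3" and not triple <= tfs:
            continue
        if kind:
            counts[kind] += 1
    return MotifCounts(
        ffl=counts["ffl"],
        complex_ffl=counts["complex_ffl"],
        fbl3=counts["fbl3"],
        n=network.n_nodes,
        tf_n=len(tfs & network.nodes),
    )


def motif_potential(n: int, tf_n: int, tf_m: int, r: int = 3) -> float:
    """Number of potential size-r motifs: n!/(n-r)! * (TFn/n)^TFm."""
    if n < r:
        raise ValueError(f"network size {n} smaller than motif size {r}")
    if tf_n < tf_m:
        logger.info("motif_potential: %d TFs < %d required; no motif possible", tf_n, tf_m)
        return 0.0
    ordered = 1.0
    for i in range(r):
        ordered *= n - i
    return ordered * (tf_n / n) ** tf_m


# ---------------------------------------------------------------------------
# Scalar profile


def distribution_r2(values: dict[float, float]) -> float:
    """R^2 of an ordinary least-squares power-law fit in log-log space.

    Points with k <= 0 or value <= 0 are excluded (log-undefined); fewer
    than 3 usable points leaves the statistic undefined (NaN), which the
    scaling step treats as missing.  A constant curve has no variance to
    explain and scores 0.
    """
    pts = [(k, v) for k, v in values.items() if k > 0 and v > 0]
    if len(pts) < 3:
        logger.info("distribution_r2: %d usable points (<3); undefined", len(pts))
        return float("nan")
    x = np.log10([k for k, _ in pts])
    y = np.log10([v for _, v in pts])
    if np.ptp(y) == 0.0:
        return 0.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def _directed_view(network: GeneNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes)
    for u, v in network.edges:
        g.add_edge(u, v)
        if not network.directed:
            g.add_edge(v, u)
    return g


def structural_profile(
    network: GeneNetwork, tf_set: frozenset[str] | None = None
) -> StructuralProfile:
    """The 13 normalized global properties of one network.

    Count-like properties (regulators, self-regulations, maximum
    out-connectivity, giant component) are divided by the number of
    nodes; density enters as its product with the regulator fraction;
    diameter and average path length are computed on the undirected
    projection of the giant (weakly connected) component and divided by
    n-2, the longest shortest path a network without shortcuts could
    have.  Undirected networks are viewed as reciprocal-arc digraphs for
    the direction-dependent properties.
    """
    n = network.n_nodes
    if n < 3:
        raise ValueError("need at least 3 nodes (diameter normalization n-2)")
    tfs = frozenset(tf_set) & network.nodes if tf_set is not None else network.regulators
    dg = _directed_view(network)
    und = nx.Graph(dg)
    und.remove_edges_from(nx.selfloop_edges(und))

    n_self = sum(1 for u, v in network.edges if u == v)
    kmax_out = max((d for _, d in dg.out_degree()), default=0)
    m_simple = sum(1 for u, v in dg.edges() if u != v)
    density = m_simple / (n * (n - 1))
    reg_frac = len(tfs) / n

    motifs = count_triad_motifs(
        network if network.directed else GeneNetwork.build(network.name, True, dg.edges()),
        tfs,
    )

    def norm_motif(count: int, tf_m: int) -> float:
        pot = motif_potential(n, len(tfs), tf_m)
        return count / pot if pot > 0 else 0.0

    comps = list(nx.connected_components(und))
    giant_nodes = max(comps, key=len)
    giant = und.subgraph(giant_nodes)
    if giant.number_of_nodes() >= 2:
        diam = nx.diameter(giant)
        apl = nx.average_shortest_path_length(giant)
    else:
        diam, apl = 0.0, 0.0

    deg = dict(und.degree())
    total_deg = {v: dg.out_degree(v) + dg.in_degree(v) for v in dg.nodes()}
    pk: dict[float, float] = {}
    for k in total_deg.values():
        pk[k] = pk.get(k, 0.0) + 1.0 / n
    clust = nx.clustering(und)
    ck_acc: dict[int, list[float]] = {}
    for v, k in deg.items():
        ck_acc.setdefault(k, []).append(clust[v])
    ck = {k: float(np.mean(vals)) for k, vals in ck_acc.items()}

    return StructuralProfile(
        network=network.name,
        n_nodes=n,
        n_components=len(comps),
        regulators_frac=reg_frac,
        selfreg_frac=n_self / n,
        kmax_out_frac=kmax_out / n,
        density_x_regfrac=density * reg_frac,
        ffl_norm=norm_motif(motifs.ffl, 2),
        complex_ffl_norm=norm_motif(motifs.complex_ffl, 2),
        fbl3_norm=norm_motif(motifs.fbl3, 3),
        giant_frac=len(giant_nodes) / n,
        avg_clustering=float(nx.average_clustering(und)),
        diameter_norm=diam / (n - 2),
        avg_path_norm=apl / (n - 2),
        r2_pk=distribution_r2(pk),
        r2_ck=distribution_r2(ck),
    )


# ---------------------------------------------------------------------------
# Scaling and clustering


def scale_profiles(profiles: list[StructuralProfile]) -> pd.DataFrame:
    """Min-max scale every property to [0, 1] across networks.

    Constant columns become 0; columns with any undefined (NaN) entry are
    dropped from the clustering matrix.  Both events are logged.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to scale across networks")
    mat = pd.DataFrame(
        [p.vector() for p in profiles],
        index=[p.network for p in profiles],
        columns=list(PROFILE_FIELDS),
    )
    bad = [c for c in mat.columns if mat[c].isna().any()]
    if bad:
        logger.info("scale_profiles: dropping columns with undefined values: %s", bad)
        mat = mat.drop(columns=bad)
    lo, hi = mat.min(), mat.max()
    span = hi - lo
    const = span == 0
    if const.any():
        logger.info(
            "scale_profiles: constant columns set to 0: %s",
            list(mat.columns[const]),
        )
    scaled = (mat - lo) / span.replace(0, 1)
    scaled.loc[:, const] = 0.0
    return scaled


def cluster_profiles(
    matrix: pd.DataFrame | np.ndarray,
    mode: str = "ward",
    n_clusters: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Ward clustering of scaled profile rows.

    ``mode="ward"`` links the scaled rows by Euclidean distance;
    ``mode="correlation-ward"`` first takes the pairwise Pearson
    correlation matrix of the rows and links its rows by Euclidean
    distance.  Returns (linkage matrix, flat labels for an
    ``n_clusters``-cut); the procedure is deterministic.
    """
    rows = np.asarray(matrix, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if mode == "ward":
        data = rows
    elif mode == "correlation-ward":
        with np.errstate(invalid="ignore"):
            data = np.corrcoef(rows)
        data = np.nan_to_num(data, nan=0.0)  # constant rows correlate with nothing
    else:
        raise ValueError(f"unknown mode {mode!r}")
    z = linkage(data, method="ward")
    labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return z, labels
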