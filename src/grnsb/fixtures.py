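"""Synthetic GRNs, planted predictions, and condition sampling.

Real benchmarking runs on curated gold standards and on the output of
many inference tools; neither is needed to exercise the framework.  This
module generates (a) directed scale-free GRNs with a transcription-factor
subset and heavy-tailed out-degrees, the canonical global shape of
bacterial transcriptional networks; (b) ranked predictions with a planted
per-entry precision and controllable tie structure, in the two flavors
real tools produce (directed TF->TG "caus" lists and undirected
co-expression "coex" lists whose true pairs are co-regulation pairs);
(c) snowball (link-tracing) subnetwork samples; and (d) families of
caus-like vs coex-like networks with the structural contrast the two tool
classes exhibit.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .goldstandard import expand_coregulation
from .netio import GeneNetwork, RankedPrediction

logger = logging.getLogger(__name__)

#: Snowball node-count cutoff used when none is given; matches the
#: condition-sampling setup this generator emulates.
DEFAULT_SNOWBALL_CUTOFF = 198


@dataclass(frozen=True)
class FixtureSpec:
    """Size and shape of a synthetic GRN.

    ``out_degree_exponent`` is the power-law exponent gamma of the TF
    out-degree distribution (P(k) ~ k^-gamma); smaller gamma gives
    heavier hubs.  ``p_self`` is the per-TF autoregulation probability.
    """

    n_genes: int = 500
    n_tfs: int = 50
    n_edges: int = 1500
    out_degree_exponent: float = 2.0
    p_self: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs must not exceed n_genes")
        if self.n_edges > self.n_tfs * self.n_genes:
            raise ValueError("n_edges exceeds n_tfs * n_genes")
        if not 0.0 <= self.p_self <= 1.0:
            raise ValueError("p_self must be in [0, 1]")
        if self.out_degree_exponent <= 1.0:
            raise ValueError("out_degree_exponent must exceed 1")


def _gene_names(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def generate_grn(spec: FixtureSpec) -> GeneNetwork:
    """Directed scale-free GRN: every edge source is a TF.

    TF out-degree quotas follow a discrete power law with the requested
    exponent, rescaled (largest-remainder rounding, capacity-capped) so
    the realized edge count equals ``n_edges`` exactly.  Self-loops are
    planted on TFs with probability ``p_self`` and count toward the
    total.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    tfs = genes[: spec.n_tfs]

    self_loops = [t for t in tfs if rng.random() < spec.p_self]
    n_rest = spec.n_edges - len(self_loops)
    if n_rest < 0:
        self_loops = self_loops[: spec.n_edges]
        n_rest = 0

    # Heavy-tailed raw out-degree weights: Pareto with tail index gamma-1.
    w = 1.0 + rng.pareto(spec.out_degree_exponent - 1.0, size=spec.n_tfs)
    cap = np.full(spec.n_tfs, spec.n_genes - 1)  # non-self targets per TF
    if n_rest > int(cap.sum()):
        raise ValueError(
            f"infeasible spec: {n_rest} non-self edges exceed capacity {int(cap.sum())}"
        )
    ideal = w / w.sum() * n_rest
    quota = np.minimum(np.floor(ideal).astype(int), cap)
    # Largest-remainder top-up until the exact total is hit.
    while quota.sum() < n_rest:
        remainder = np.where(quota < cap, ideal - quota, -np.inf)
        quota[int(np.argmax(remainder))] += 1

    edges: list[tuple[str, str]] = [(t, t) for t in self_loops]
    for i, tf in enumerate(tfs):
        if quota[i] == 0:
            continue
        pool = [g for g in genes if g != tf]
        targets = rng.choice(len(pool), size=quota[i], replace=False)
        edges.extend((tf, pool[j]) for j in targets)
    net = GeneNetwork.build(
        f"grn_seed{spec.seed}", True, edges, nodes=genes, tf_list=tfs
    )
    assert net.n_edges == spec.n_edges
    return net


def generate_prediction(
    gs: GeneNetwork,
    precision: float,
    length: int,
    tie_fraction: float = 0.0,
    seed: int = 0,
    style: str = "caus",
) -> RankedPrediction:
    """Ranked prediction with per-entry planted precision.

    Each list position is a true pair with probability ``precision``
    (independent Bernoulli draws, so the realized number of trues is
    exactly binomial), otherwise a decoy.  Style "caus" draws true pairs
    from the directed gold-standard edges and decoys from non-edges with
    a TF source; style "coex" is undirected, drawing true pairs from the
    co-regulation clique expansion of the gold standard and decoys from
    arbitrary unordered non-pairs.  Scores decrease strictly except that
    each adjacent pair shares a score with probability ``tie_fraction``.
    """
    if not 0.0 <= precision <= 1.0:
        raise ValueError("precision must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = sorted(gs.nodes)
    if style == "caus":
        true_pool = sorted(gs.edges)
        tf_sorted = sorted(gs.regulators)
        decoy_pool = [
            (tf, g)
            for tf in tf_sorted
            for g in genes
            if tf != g and not gs.has_edge(tf, g)
        ]
        directed = True
        network_type = "CAUS"
    elif style == "coex":
        coreg = expand_coregulation(gs)
        true_pool = sorted(coreg.edges)
        true_set = coreg.edges
        decoy_pool = [
            (a, b)
            for i, a in enumerate(genes)
            for b in genes[i + 1 :]
            if (a, b) not in true_set
        ]
        directed = False
        network_type = "COEX"
    else:
        raise ValueError(f"unknown style {style!r}")

    is_true = rng.random(length) < precision
    k = int(is_true.sum())
    if k > len(true_pool):
        raise ValueError(
            f"cannot plant {k} true pairs: only {len(true_pool)} available"
        )
    if length - k > len(decoy_pool):
        raise ValueError("not enough decoy pairs to fill the list")
    true_idx = rng.choice(len(true_pool), size=k, replace=False)
    decoy_idx = rng.choice(len(decoy_pool), size=length - k, replace=False)
    trues = iter(true_idx)
    decoys = iter(decoy_idx)
    pairs = [
        true_pool[next(trues)] if flag else decoy_pool[next(decoys)]
        for flag in is_true
    ]

    scores = np.empty(length)
    if length:
        scores[0] = 1.0
        for i in range(1, length):
            if rng.random() < tie_fraction:
                scores[i] = scores[i - 1]
            else:
                scores[i] = scores[i - 1] - 1.0 / (length + 1)
    entries = tuple((a, b, float(s)) for (a, b), s in zip(pairs, scores))
    return RankedPrediction(
        method=f"{style}_p{precision}_s{seed}",
        network_type=network_type,
        entries=entries,
        directed=directed,
    )


def snowball_sample(
    network: GeneNetwork,
    cutoff: int = DEFAULT_SNOWBALL_CUTOFF,
    seed_node: str | None = None,
) -> GeneNetwork:
    """Link-tracing subnetwork of ``cutoff`` nodes around a hub seed.

    Traversal runs breadth-first over the undirected projection starting
    from the highest-total-degree node (ties broken lexicographically)
    unless a seed is given.  Nodes are admitted wave by wave, within a
    wave by descending degree then lexicographically, until the cutoff;
    the induced directed subgraph is returned.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    if not network.nodes:
        raise ValueError("empty network")
    nbrs: dict[str, set[str]] = {v: set() for v in network.nodes}
    deg: dict[str, int] = {v: 0 for v in network.nodes}
    for u, v in network.edges:
        deg[u] += 1
        if u != v:
            deg[v] += 1
            nbrs[u].add(v)
            nbrs[v].add(u)
    if cutoff >= len(network.nodes):
        logger.info("snowball cutoff >= network size; returning the full network")
        return network
    if seed_node is None:
        seed_node = min(network.nodes, key=lambda v: (-deg[v], v))
    elif seed_node not in network.nodes:
        raise ValueError(f"seed node {seed_node!r} not in network")
    admitted: list[str] = [seed_node]
    admitted_set = {seed_node}
    wave = [seed_node]
    while wave and len(admitted) < cutoff:
        frontier = set()
        for v in wave:
            frontier |= nbrs[v] - admitted_set
        nxt = sorted(frontier, key=lambda v: (-deg[v], v))
        for v in nxt:
            if len(admitted) >= cutoff:
                break
            admitted.append(v)
            admitted_set.add(v)
        wave = [v for v in nxt if v in admitted_set]
    keep = admitted_set
    edges = [(u, v) for u, v in network.edges if u in keep and v in keep]
    return GeneNetwork.build(
        f"{network.name}_snowball{cutoff}",
        network.directed,
        edges,
        nodes=keep,
        tf_list=network.regulators & keep,
    )


def generate_family(
    kind: str, n_networks: int, base_spec: FixtureSpec
) -> list[GeneNetwork]:
    """Families with the structural contrast of causal vs co-expression output.

    "caus-like" members are sparse directed scale-free GRNs (few
    regulators, pronounced hubs).  "coex-like" members are undirected
    unions of cliques over co-regulated gene groups: almost every
    connected node has edges ("regulators" under the undirected reading),
    clustering is high, and the maximum degree is modest relative to
    network size.
    """
    nets: list[GeneNetwork] = []
    for i in range(n_networks):
        seed = base_spec.seed + i
        if kind == "caus-like":
            nets.append(generate_grn(replace(base_spec, seed=seed)))
        elif kind == "coex-like":
            # Shuffled partition into co-regulated groups, each a clique:
            # nearly every node incident to edges ("regulators" under the
            # undirected reading), high clustering, modest max degree.
            rng = np.random.default_rng(seed + 1_000_003)
            genes = _gene_names(base_spec.n_genes)
            order = [genes[j] for j in rng.permutation(len(genes))]
            edges: set[tuple[str, str]] = set()
            pos = 0
            while pos < len(order):
                size = int(rng.integers(4, 9))
                members = sorted(order[pos : pos + size])
                pos += size
                for a_i, a in enumerate(members):
                    for b in members[a_i + 1 :]:
                        edges.add((a, b))
            nets.append(
                GeneNetwork.build(
                    f"coex_seed{seed}", False, edges, nodes=genes
                )
            )
        else:
            raise ValueError(f"unknown family kind {kind!r}")
    return nets
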