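"""Gold-standard engineering for GRN assessment.

Curated regulatory networks mix gene nodes with regulatory protein
complexes; only gene-gene interactions can be inferred from expression
data, so complexes are projected onto their constituent genes.  Genes
without expression data cannot be predicted and are removed.  Finally,
for assessing co-expression tools on their own terms, each regulon (a TF
with its targets) is expanded into a clique of co-regulated genes,
producing an undirected co-regulation gold standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

from .netio import GeneNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Regulon:
    """A transcription factor and the set of genes it regulates."""

    tf: str
    targets: frozenset[str]
    autoregulated: bool

    @property
    def size(self) -> int:
        return len(self.targets)


def project_complexes(
    network: GeneNetwork, complex_map: Mapping[str, Iterable[str]]
) -> GeneNetwork:
    """Replace regulatory-complex nodes by their constituent genes.

    Every edge incident to a complex node becomes one edge per
    constituent; duplicates arising from the expansion collapse.  Nodes
    named in ``complex_map`` are the complexes; anything else is a gene.
    A complex mapping to an empty set is an error (it would silently
    delete interactions).
    """
    cmap = {c: frozenset(genes) for c, genes in complex_map.items()}
    empty = sorted(c for c, g in cmap.items() if not g)
    if empty:
        raise ValueError(f"complexes with no constituent genes: {empty}")

    def expand(node: str) -> frozenset[str]:
        return cmap.get(node, frozenset([node]))

    edges = set()
    for u, v in network.edges:
        for uu in expand(u):
            for vv in expand(v):
                edges.add((uu, vv))
    nodes = set()
    for n in network.nodes:
        nodes |= expand(n)
    tf_decl = set()
    for r in network.regulators:
        tf_decl |= expand(r)
    return GeneNetwork.build(
        network.name, network.directed, edges, nodes=nodes, tf_list=tf_decl
    )


def restrict_to_universe(network: GeneNetwork, genes: Iterable[str]) -> GeneNetwork:
    """Induced subgraph on the genes with expression data.

    Regulators are recomputed from the surviving edges (plus surviving
    declared TFs); removal counts are logged.
    """
    keep = frozenset(genes) & network.nodes
    if not keep:
        raise ValueError("no network gene has expression data; degenerate gold standard")
    edges = [(u, v) for u, v in network.edges if u in keep and v in keep]
    logger.info(
        "restrict_to_universe(%s): removed %d nodes, %d edges",
        network.name,
        network.n_nodes - len(keep),
        network.n_edges - len(edges),
    )
    return GeneNetwork.build(
        network.name,
        network.directed,
        edges,
        nodes=keep,
        tf_list=network.regulators & keep,
    )


def extract_regulons(network: GeneNetwork) -> list[Regulon]:
    """One regulon per regulator with at least one target (directed only)."""
    if not network.directed:
        raise ValueError("regulon extraction requires a directed network")
    targets: dict[str, set[str]] = {}
    for u, v in network.edges:
        targets.setdefault(u, set()).add(v)
    return [
        Regulon(tf, frozenset(tgts), tf in tgts)
        for tf, tgts in sorted(targets.items())
    ]


def expand_coregulation(network: GeneNetwork) -> GeneNetwork:
    """Build the undirected co-regulation gold standard by clique expansion.

    The targets of each regulon form a clique (any two genes regulated by
    the same TF are co-regulated).  The TF itself joins its clique only
    when it regulates its own transcription — in which case it is already
    among its targets and enters as an ordinary member.  Overlapping
    regulons contribute each unordered pair once; the output has no
    self-edges and keeps the input node set.
    """
    if not network.directed:
        raise ValueError("clique expansion requires a directed network")
    pairs: set[tuple[str, str]] = set()
    for reg in extract_regulons(network):
        members = sorted(reg.targets)
        for a, b in combinations(members, 2):
            pairs.add((a, b))
    return GeneNetwork.build(
        f"{network.name}_coregulation", False, pairs, nodes=network.nodes
    )
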