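"""Graph and prediction data model plus edge-list readers/writers.

The framework's currency is two objects: :class:`GeneNetwork` (a gold
standard or an inferred/structural network) and :class:`RankedPrediction`
(the scored edge list one inference method emits).  Everything is plain
tab-separated text: ``source<TAB>target[<TAB>score|effect]`` with ``#``
comments, one gene identifier per line for TF lists.

Gene identifiers are opaque case-sensitive strings; no synonym resolution
is attempted (curated inputs are assumed harmonized upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Recognized prediction classes: co-expression (undirected), causal
#: (directed TF->TG), hybrid (co-expression filtered to TF edges) and
#: Borda-integrated communities.
NETWORK_TYPES = ("COEX", "CAUS", "HYBR", "COMMUNITY")

Edge = tuple[str, str]


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list rows; message names the line."""


def canonical_edge(u: str, v: str, directed: bool) -> Edge:
    """Ordered pair for directed networks, sorted pair for undirected."""
    if directed or u <= v:
        return (u, v)
    return (v, u)


@dataclass(frozen=True)
class GeneNetwork:
    """A gene-gene network: gold standard, inference output, or sample.

    ``regulators`` holds every node with at least one outgoing edge plus
    any node declared in an external TF list.  For undirected networks
    "outgoing" degenerates to "incident".  ``effects`` optionally maps an
    edge to a sign label (activation/repression/dual); it is carried
    through but ignored by all assessment metrics.
    """

    name: str
    directed: bool
    nodes: frozenset[str]
    edges: frozenset[Edge]
    regulators: frozenset[str] = frozenset()
    effects: Mapping[Edge, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge endpoint not in node set: ({u}, {v})")
            if not self.directed and (u, v) != canonical_edge(u, v, False):
                raise ValueError(f"undirected edge not canonical: ({u}, {v})")
        if not self.regulators <= self.nodes:
            raise ValueError("regulators must be a subset of nodes")

    @classmethod
    def build(
        cls,
        name: str,
        directed: bool,
        edges: Iterable[Edge],
        nodes: Iterable[str] = (),
        tf_list: Iterable[str] = (),
        effects: Mapping[Edge, str] | None = None,
    ) -> "GeneNetwork":
        """Canonicalize edges, infer nodes/regulators, and validate."""
        canon = frozenset(canonical_edge(u, v, directed) for u, v in edges)
        node_set = frozenset(nodes) | {g for e in canon for g in e} | frozenset(tf_list)
        if directed:
            regs = frozenset(u for u, _ in canon) | frozenset(tf_list)
        else:
            regs = frozenset(g for e in canon for g in e) | frozenset(tf_list)
        eff = {}
        if effects:
            eff = {canonical_edge(u, v, directed): s for (u, v), s in effects.items()}
        return cls(name, directed, node_set, canon, regs, eff)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def out_degree(self, node: str) -> int:
        if self.directed:
            return sum(1 for u, _ in self.edges if u == node)
        return sum(1 for e in self.edges if node in e)

    def has_edge(self, u: str, v: str) -> bool:
        return canonical_edge(u, v, self.directed) in self.edges

    def to_networkx(self):
        """Export to a networkx (Di)Graph with all isolated nodes kept."""
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g


@dataclass(frozen=True)
class RankedPrediction:
    """Ordered, scored edge list from one inference method.

    Entries are sorted by score descending; equal scores form contiguous
    tie blocks and are treated as equally ranked throughout assessment.
    """

    method: str
    network_type: str
    entries: tuple[tuple[str, str, float], ...]
    directed: bool

    def __post_init__(self) -> None:
        if self.network_type not in NETWORK_TYPES:
            raise ValueError(f"unknown network type: {self.network_type!r}")
        seen: set[Edge] = set()
        prev = None
        for reg, tgt, score in self.entries:
            if prev is not None and score > prev:
                raise ValueError("scores must be non-increasing")
            prev = score
            pair = (reg, tgt)
            if pair in seen:
                raise ValueError(f"duplicate pair {pair}")
            seen.add(pair)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def pairs(self) -> tuple[Edge, ...]:
        return tuple((r, t) for r, t, _ in self.entries)

    def tie_blocks(self) -> list[list[tuple[str, str, float]]]:
        """Contiguous runs of equal score, in rank order."""
        blocks: list[list[tuple[str, str, float]]] = []
        for entry in self.entries:
            if blocks and blocks[-1][0][2] == entry[2]:
                blocks[-1].append(entry)
            else:
                blocks.append([entry])
        return blocks


@dataclass(frozen=True)
class Universe:
    """The set of gene pairs over which positives and negatives are defined.

    For a directed assessment the universe is the Cartesian product
    regulator_set x target_set; self-pairs are kept by default because
    autoregulation is biologically real.  For an undirected (co-regulation)
    assessment use :meth:`unordered`, whose pairs are unordered.
    """

    regulator_set: frozenset[str]
    target_set: frozenset[str]
    include_self_pairs: bool = True
    directed: bool = True

    @classmethod
    def unordered(cls, genes: Iterable[str], include_self_pairs: bool = False) -> "Universe":
        gs = frozenset(genes)
        return cls(gs, gs, include_self_pairs, directed=False)

    @property
    def n_pairs(self) -> int:
        if self.directed:
            n = len(self.regulator_set) * len(self.target_set)
            if not self.include_self_pairs:
                n -= len(self.regulator_set & self.target_set)
            return n
        g = len(self.regulator_set)
        n = g * (g - 1) // 2
        if self.include_self_pairs:
            n += g
        return n

    def canonical(self, u: str, v: str) -> Edge:
        return canonical_edge(u, v, self.directed)

    def __contains__(self, pair: Edge) -> bool:
        u, v = pair
        if u == v and not self.include_self_pairs:
            return False
        if self.directed:
            return u in self.regulator_set and v in self.target_set
        return u in self.regulator_set and v in self.regulator_set

    def iter_pairs(self) -> Iterable[Edge]:
        """All pairs in deterministic lexicographic order."""
        if self.directed:
            for u in sorted(self.regulator_set):
                for v in sorted(self.target_set):
                    if u == v and not self.include_self_pairs:
                        continue
                    yield (u, v)
        else:
            genes = sorted(self.regulator_set)
            for i, u in enumerate(genes):
                start = i if self.include_self_pairs else i + 1
                for v in genes[start:]:
                    yield (u, v)


# ---------------------------------------------------------------------------
# Readers / writers


def _rows(path: str | Path):
    text = Path(path).read_text()
    lineno = 0
    any_row = False
    for line in text.splitlines():
        lineno += 1
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        any_row = True
        yield lineno, stripped.split("\t")
    if not any_row:
        raise EdgeListParseError(f"{path}: no data rows")


def read_tf_list(path: str | Path) -> frozenset[str]:
    """One identifier per line; '#' comments and blanks skipped."""
    out = set()
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.add(s.split("\t")[0])
    return frozenset(out)


def read_network(
    path: str | Path,
    directed: bool = True,
    tf_list: str | Path | None = None,
    name: str | None = None,
) -> GeneNetwork:
    """Read a TSV edge list (source, target[, effect]) into a GeneNetwork.

    Duplicate rows are collapsed to a single edge; the number collapsed is
    logged.  An optional third column is kept as the edge's effect label.
    """
    edges: list[Edge] = []
    effects: dict[Edge, str] = {}
    for lineno, cols in _rows(path):
        if len(cols) < 2 or len(cols) > 3:
            raise EdgeListParseError(
                f"{path}:{lineno}: expected 2-3 tab-separated columns, got {len(cols)}"
            )
        u, v = cols[0], cols[1]
        edges.append((u, v))
        if len(cols) == 3 and cols[2]:
            effects[canonical_edge(u, v, directed)] = cols[2]
    tfs = read_tf_list(tf_list) if tf_list else frozenset()
    net = GeneNetwork.build(
        name or Path(path).stem, directed, edges, tf_list=tfs, effects=effects
    )
    n_dup = len(edges) - len(net.edges)
    if n_dup:
        logger.info("read_network(%s): collapsed %d duplicate rows", path, n_dup)
    return net


def write_edges(network: GeneNetwork, path: str | Path) -> None:
    """Write the canonical edge list as TSV (with effect column if any)."""
    lines = []
    for u, v in sorted(network.edges):
        eff = network.effects.get((u, v))
        lines.append(f"{u}\t{v}\t{eff}" if eff else f"{u}\t{v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_prediction(
    path: str | Path,
    method: str,
    network_type: str,
    directed: bool | None = None,
) -> RankedPrediction:
    """Read a scored prediction TSV (regulator, target, score).

    Rows may be unsorted; output is sorted by score descending with input
    order preserved inside ties (methods that report equal scores rank
    those interactions equally, and the file order is the only
    reproducible tie order).  Duplicate pairs keep the highest-scored
    occurrence.  A missing score column is accepted only for COMMUNITY
    (rank-only) inputs, where the score becomes the negated line number.
    """
    if directed is None:
        directed = network_type != "COEX"
    best: dict[Edge, tuple[int, float]] = {}
    n_dup = 0
    for lineno, cols in _rows(path):
        if len(cols) == 2:
            if network_type != "COMMUNITY":
                raise EdgeListParseError(
                    f"{path}:{lineno}: missing score column for scored method"
                )
            score = -float(lineno)
        elif len(cols) == 3:
            try:
                score = float(cols[2])
            except ValueError:
                raise EdgeListParseError(
                    f"{path}:{lineno}: unparseable score {cols[2]!r}"
                ) from None
            if not (score == score and abs(score) != float("inf")):
                raise EdgeListParseError(f"{path}:{lineno}: non-finite score")
        else:
            raise EdgeListParseError(
                f"{path}:{lineno}: expected 2-3 columns, got {len(cols)}"
            )
        pair = (cols[0], cols[1])
        if pair in best:
            n_dup += 1
            if score <= best[pair][1]:
                continue
        best[pair] = (lineno, score)
    if n_dup:
        logger.info("read_prediction(%s): dropped %d duplicate pairs", path, n_dup)
    ordered = sorted(best.items(), key=lambda kv: (-kv[1][1], kv[1][0]))
    entries = tuple((p[0], p[1], s) for p, (_, s) in ordered)
    return RankedPrediction(method, network_type, entries, directed)


def write_prediction(pred: RankedPrediction, path: str | Path) -> None:
    lines = [f"{r}\t{t}\t{s!r}" for r, t, s in pred.entries]
    Path(path).write_text("\n".join(lines) + "\n")


def symmetrize_prediction(pred: RankedPrediction) -> RankedPrediction:
    """Duplicate every undirected entry in both directions, same score.

    Co-expression outputs carry no direction; assessing them against a
    directed gold standard requires both orientations of every pair to be
    on the list.  Self-pairs appear once.  The result is flagged directed;
    applying this to an already-directed prediction is an error (it would
    double-count).
    """
    if pred.directed:
        raise ValueError("prediction already directed; refusing to symmetrize")
    entries: list[tuple[str, str, float]] = []
    for r, t, s in pred.entries:
        entries.append((r, t, s))
        if r != t:
            entries.append((t, r, s))
    return replace(pred, entries=tuple(entries), directed=True)
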