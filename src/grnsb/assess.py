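"""Rank-based assessment of ranked edge lists against a gold standard.

The gold-standard interactions inside the universe are the positive set
P; every other universe pair is a negative.  Predictions are trimmed to
the expected size of the complete GRN, swept one tie block at a time to
build PR and ROC curves, and summarized by AUPR (the headline measure,
because P is tiny relative to N), AUROC, MCC and F1.  Interactions a
method did not rank are all placed immediately after its last predicted
one, so longer predictions penalize missing interactions more.

A regulon-level view compares each TF's predicted target set against its
gold-standard regulon with MCC/F1, for plotting against the TF's
out-degree normalized by the network maximum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from .goldstandard import extract_regulons
from .netio import Edge, GeneNetwork, RankedPrediction, Universe

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class AssessmentResult:
    aupr: float
    auroc: float
    pr_points: tuple[tuple[float, float], ...]
    roc_points: tuple[tuple[float, float], ...]
    counts_at_cutoff: ConfusionCounts
    mcc: float
    f1: float


@dataclass(frozen=True)
class RegulonScore:
    tf: str
    mcc: float
    f1: float
    kout: int
    kout_over_kmax: float


@dataclass(frozen=True)
class TieRanks:
    """Tie-aware ranks of a prediction over a universe.

    Listed pairs get the mean of their positional ranks within their tie
    block; every universe pair absent from the list shares rank L+1,
    where L is the number of listed pairs.
    """

    ranks: dict[Edge, float]
    missing_rank: float
    n_listed: int
    universe: Universe

    def __getitem__(self, pair: Edge) -> float:
        return self.ranks.get(self.universe.canonical(*pair), self.missing_rank)


def trim_prediction(pred: RankedPrediction, n_expected: int) -> RankedPrediction:
    """Keep the first ``n_expected`` entries, never splitting a tie block.

    A score-based cutoff cannot separate equal scores, so a block
    straddling the boundary is kept whole and the overshoot logged.
    """
    if n_expected <= 0:
        raise ValueError("n_expected must be positive")
    if len(pred.entries) <= n_expected:
        return pred
    cut = n_expected
    boundary_score = pred.entries[n_expected - 1][2]
    while cut < len(pred.entries) and pred.entries[cut][2] == boundary_score:
        cut += 1
    if cut > n_expected:
        logger.info(
            "trim_prediction(%s): tie block at cutoff kept whole (+%d entries)",
            pred.method,
            cut - n_expected,
        )
    return replace(pred, entries=pred.entries[:cut])


def _universe_entries(
    pred: RankedPrediction, universe: Universe
) -> list[tuple[str, str, float]]:
    """Canonicalize pairs to the universe convention, drop outsiders.

    For an unordered universe the two orientations of a pair collapse;
    the better-ranked occurrence is kept.
    """
    seen: set[Edge] = set()
    kept: list[tuple[str, str, float]] = []
    n_dropped = 0
    for r, t, s in pred.entries:
        pair = universe.canonical(r, t)
        if pair not in universe:
            n_dropped += 1
            continue
        if pair in seen:
            continue
        seen.add(pair)
        kept.append((pair[0], pair[1], s))
    if n_dropped:
        logger.info(
            "%s: dropped %d predicted pairs outside the universe",
            pred.method,
            n_dropped,
        )
    return kept


def rank_with_ties(pred: RankedPrediction, universe: Universe) -> TieRanks:
    """Mid-rank every listed pair; missing universe pairs rank L+1."""
    if universe.n_pairs == 0:
        raise ValueError("empty universe")
    entries = _universe_entries(pred, universe)
    ranks: dict[Edge, float] = {}
    i = 0
    while i < len(entries):
        j = i
        while j < len(entries) and entries[j][2] == entries[i][2]:
            j += 1
        mid = (i + 1 + j) / 2.0  # mean of positions i+1 .. j
        for r, t, _ in entries[i:j]:
            ranks[(r, t)] = mid
        i = j
    return TieRanks(ranks, float(len(entries) + 1), len(entries), universe)


def _positive_set(gs: GeneNetwork, universe: Universe) -> frozenset[Edge]:
    return frozenset(
        p
        for u, v in gs.edges
        if (p := universe.canonical(u, v)) in universe
    )


def confusion_at_cutoff(
    pred: RankedPrediction, gs: GeneNetwork, universe: Universe
) -> ConfusionCounts:
    """Confusion table of the (already trimmed) list taken as a whole."""
    positives = _positive_set(gs, universe)
    entries = _universe_entries(pred, universe)
    tp = sum(1 for r, t, _ in entries if (r, t) in positives)
    fp = len(entries) - tp
    fn = len(positives) - tp
    tn = (universe.n_pairs - len(positives)) - fp
    return ConfusionCounts(tp, fp, fn, tn)


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float]:
    """(MCC, F1); degenerate denominators yield 0 by convention."""
    denom = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0.0:
        logger.debug("MCC denominator degenerate; returning 0")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / denom
    f1_denom = 2 * c.tp + c.fp + c.fn
    f1 = 2 * c.tp / f1_denom if f1_denom else 0.0
    return mcc, f1


def assess_global(
    pred: RankedPrediction, gs: GeneNetwork, universe: Universe
) -> AssessmentResult:
    """AUPR/AUROC/MCC/F1 of a trimmed prediction against a gold standard.

    Against a directed gold standard the prediction must already be
    directed (symmetrize co-expression output first).  Against an
    undirected co-regulation gold standard, direction is ignored: pairs
    are compared unordered, keeping the better-ranked orientation.

    The PR curve is traversed one tie block at a time (all members of a
    block enter together) and integrated by trapezoid over the recall
    actually reached, anchored on the left at (0, precision of the first
    block) — a truncated list is not extrapolated to recall 1.  AUROC is
    the tie-corrected Mann-Whitney statistic over the whole universe,
    with every unranked pair sharing the rank just past the list's end.
    """
    if gs.directed and not pred.directed:
        raise ValueError(
            "undirected prediction vs directed gold standard: symmetrize first"
        )
    if universe.directed != gs.directed:
        raise ValueError("universe directedness must match the gold standard")
    positives = _positive_set(gs, universe)
    n_pos = len(positives)
    n_neg = universe.n_pairs - n_pos
    if n_pos == 0:
        raise ValueError("no gold-standard positives inside the universe")
    if n_neg == 0:
        raise ValueError("no negatives: gold standard covers the whole universe")

    entries = _universe_entries(pred, universe)

    # --- curve sweep, one tie block at a time
    pr_points: list[tuple[float, float]] = []
    roc_points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(entries):
        j = i
        while j < len(entries) and entries[j][2] == entries[i][2]:
            j += 1
        for r, t, _ in entries[i:j]:
            if (r, t) in positives:
                tp += 1
            else:
                fp += 1
        pr_points.append((tp / n_pos, tp / (tp + fp)))
        roc_points.append((fp / n_neg, tp / n_pos))
        i = j

    if pr_points:
        anchored = [(0.0, pr_points[0][1])] + pr_points
    else:  # empty prediction: no precision is defined anywhere
        anchored = [(0.0, 0.0)]
    aupr = 0.0
    for (r0, p0), (r1, p1) in zip(anchored, anchored[1:]):
        aupr += (r1 - r0) * (p0 + p1) / 2.0

    # --- tie-corrected Mann-Whitney AUROC over the full universe
    ranks = rank_with_ties(replace(pred, entries=tuple(entries)), universe)
    rank_sum_pos = sum(ranks[p] for p in positives)
    # Unranked pairs all sit in one tie block spanning positions L+1..n;
    # their mid-rank replaces the nominal L+1 for the U statistic.
    n_missing = universe.n_pairs - ranks.n_listed
    if n_missing:
        missing_mid = ranks.n_listed + (n_missing + 1) / 2.0
        n_pos_missing = sum(
            1 for p in positives if p not in ranks.ranks
        )
        rank_sum_pos += n_pos_missing * (missing_mid - ranks.missing_rank)
    u_stat = n_pos * n_neg + n_pos * (n_pos + 1) / 2.0 - rank_sum_pos
    auroc = u_stat / (n_pos * n_neg)
    if n_missing:
        roc_points.append((1.0, 1.0))

    counts = confusion_at_cutoff(pred, gs, universe)
    mcc, f1 = confusion_metrics(counts)
    return AssessmentResult(
        aupr=aupr,
        auroc=auroc,
        pr_points=tuple(pr_points),
        roc_points=tuple(roc_points),
        counts_at_cutoff=counts,
        mcc=mcc,
        f1=f1,
    )


def assess_regulons(
    pred: RankedPrediction, gs: GeneNetwork, universe: Universe
) -> list[RegulonScore]:
    """Per-TF comparison of predicted vs gold-standard target sets.

    For each gold-standard regulon, the TF's predicted targets and true
    targets are compared as binary vectors over ``universe.target_set``;
    local-TF performance can then be read against kout/kmax, the TF's
    out-degree normalized by the network maximum.
    """
    if not gs.directed:
        raise ValueError("regulon-level assessment requires a directed gold standard")
    regulons = extract_regulons(gs)
    if not regulons:
        return []
    kmax = max(r.size for r in regulons)
    predicted: dict[str, set[str]] = {}
    for r, t, _ in pred.entries:
        predicted.setdefault(r, set()).add(t)
    scores: list[RegulonScore] = []
    candidates = universe.target_set
    for reg in regulons:
        if reg.tf not in universe.regulator_set:
            logger.info("regulon %s skipped: TF outside the universe", reg.tf)
            continue
        true_t = reg.targets & candidates
        pred_t = predicted.get(reg.tf, set()) & candidates
        tp = len(true_t & pred_t)
        fp = len(pred_t - true_t)
        fn = len(true_t - pred_t)
        tn = len(candidates) - tp - fp - fn
        mcc, f1 = confusion_metrics(ConfusionCounts(tp, fp, fn, tn))
        scores.append(
            RegulonScore(
                tf=reg.tf,
                mcc=mcc,
                f1=f1,
                kout=reg.size,
                kout_over_kmax=reg.size / kmax,
            )
        )
    return scores
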