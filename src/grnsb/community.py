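"""Borda-count integration of predictions and dominance combinatorics.

A community network aggregates several inference methods by ranking each
universe pair with every method (tie-aware; pairs a method did not list
rank right after its last listed one) and scoring the pair by its mean
rank.  Selective communities restrict the aggregation to a subset of
methods; the dominance score of a tool at community size r is the
fraction of the C(n-1, r-1) size-r communities containing it whose AUPR
strictly beats the all-inclusive community's.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterator, Mapping, Sequence

from .assess import rank_with_ties, trim_prediction
from .netio import RankedPrediction, Universe


@dataclass(frozen=True)
class DominanceTable:
    """One tool's outperformance probability at one community size."""

    tool: str
    r: int
    wins: int
    max_t: int
    dominance: float


def borda_integrate(
    preds: Sequence[RankedPrediction],
    universe: Universe,
    n_expected: int | None = None,
    method: str | None = None,
) -> RankedPrediction:
    """Average per-method ranks over the universe into one ranked list.

    Lower mean rank is better; the score column is the negated mean rank
    so the usual non-increasing-score invariant holds.  Mean-rank ties
    are broken lexicographically by (regulator, target) for
    reproducibility; lexicographic order never affects tie-aware
    assessment, which sees equal scores as one block.  When
    ``n_expected`` is given the output is trimmed to the expected size of
    the complete GRN.
    """
    if not preds:
        raise ValueError("need at least one prediction")
    if len({p.directed for p in preds}) != 1:
        raise ValueError("cannot mix directed and undirected predictions")
    all_ranks = [rank_with_ties(p, universe) for p in preds]
    k = len(all_ranks)
    scored = []
    for pair in universe.iter_pairs():
        mean_rank = sum(tr[pair] for tr in all_ranks) / k
        scored.append((mean_rank, pair))
    scored.sort(key=lambda mp: (mp[0], mp[1]))
    entries = tuple((r, t, -mean) for mean, (r, t) in scored)
    out = RankedPrediction(
        method=method or "community(" + "+".join(sorted(p.method for p in preds)) + ")",
        network_type="COMMUNITY",
        entries=entries,
        directed=preds[0].directed,
    )
    if n_expected is not None:
        out = trim_prediction(out, n_expected)
    return out


def selective_communities(
    preds: Sequence[RankedPrediction],
    r: int,
    universe: Universe,
    n_expected: int | None = None,
) -> Iterator[tuple[tuple[str, ...], RankedPrediction]]:
    """Every size-r community, in lexicographic order of method labels."""
    n = len(preds)
    if not 2 <= r <= n - 1:
        raise ValueError(f"community size r={r} out of range [2, {n - 1}]")
    by_label = sorted(preds, key=lambda p: p.method)
    labels = [p.method for p in by_label]
    if len(set(labels)) != n:
        raise ValueError("method labels must be unique")
    for subset in combinations(range(n), r):
        chosen = [by_label[i] for i in subset]
        names = tuple(labels[i] for i in subset)
        yield names, borda_integrate(chosen, universe, n_expected)


def dominance_score(
    auprs: Mapping[frozenset[str] | tuple[str, ...], float],
    aupr_all: float,
    tool: str,
    r: int,
    n: int,
) -> DominanceTable:
    """Probability that a size-r community with ``tool`` beats the full one.

    ``auprs`` maps each size-r method subset to its community AUPR and
    must cover every subset containing the tool; max_t = C(n-1, r-1) is
    the number of such subsets.  Only strict improvement counts as a win.
    """
    scores = {frozenset(k): v for k, v in auprs.items()}
    max_t = comb(n - 1, r - 1)
    wins = 0
    n_seen = 0
    for subset, aupr in scores.items():
        if tool not in subset or len(subset) != r:
            continue
        n_seen += 1
        if aupr > aupr_all:
            wins += 1
    if n_seen != max_t:
        raise ValueError(
            f"expected {max_t} size-{r} subsets containing {tool!r}, got {n_seen}"
        )
    return DominanceTable(tool, r, wins, max_t, wins / max_t)
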