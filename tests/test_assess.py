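import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grnsb import (
    ConfusionCounts,
    Universe,
    assess_global,
    assess_regulons,
    confusion_at_cutoff,
    confusion_metrics,
    rank_with_ties,
    symmetrize_prediction,
    trim_prediction,
)

from conftest import net, pred, rng_for
from oracles import curve_areas


def make_universe(n_regs, n_targets):
    regs = frozenset(f"r{i}" for i in range(n_regs))
    tgts = frozenset(f"g{i}" for i in range(n_targets))
    return Universe(regs, tgts)


def random_instance(rng, max_pairs=30):
    """Random universe, positives, and tied ranked list for oracle checks."""
    n_regs = int(rng.integers(1, 4))
    n_tgts = int(rng.integers(2, max(3, max_pairs // n_regs + 1)))
    uni = make_universe(n_regs, n_tgts)
    pairs = list(uni.iter_pairs())
    while len(pairs) > max_pairs:
        pairs = pairs[: max_pairs]
    n_pos = int(rng.integers(1, len(pairs)))
    pos_idx = rng.choice(len(pairs), size=n_pos, replace=False)
    positives = {pairs[i] for i in pos_idx}
    n_listed = int(rng.integers(1, len(pairs) + 1))
    listed = [pairs[i] for i in rng.choice(len(pairs), size=n_listed, replace=False)]
    # scores with deliberate ties
    score = 1.0
    entries = []
    for p in listed:
        if entries and rng.random() < 0.4:
            entries.append((p[0], p[1], score))
        else:
            score -= 0.01
            entries.append((p[0], p[1], score))
    gs = net(positives, name="gs")
    return uni, positives, entries, gs


class TestTrim:
    def test_plain_trim(self):
        p = pred([("a", str(i), 1.0 - i / 10) for i in range(5)])
        assert len(trim_prediction(p, 3)) == 3

    def test_tie_block_kept_whole(self):
        scores = [0.9, 0.5, 0.5, 0.5, 0.1]
        p = pred([("a", str(i), s) for i, s in enumerate(scores)])
        assert len(trim_prediction(p, 2)) == 4

    def test_short_list_passes_through(self):
        p = pred([("a", "b", 0.9)])
        assert trim_prediction(p, 10) is p


class TestRankWithTies:
    def test_missing_ranked_after_last(self):
        uni = make_universe(1, 4)
        p = pred([("r0", "g0", 0.9), ("r0", "g1", 0.5)])
        tr = rank_with_ties(p, uni)
        assert tr[("r0", "g0")] == 1 and tr[("r0", "g1")] == 2
        assert tr[("r0", "g2")] == 3 and tr[("r0", "g3")] == 3

    def test_tied_pair_mean_of_positions(self):
        uni = make_universe(1, 4)
        p = pred([("r0", "g0", 0.5), ("r0", "g1", 0.5)])
        tr = rank_with_ties(p, uni)
        assert tr[("r0", "g0")] == tr[("r0", "g1")] == 1.5

    def test_empty_list_all_rank_one(self):
        uni = make_universe(1, 3)
        tr = rank_with_ties(pred([]), uni)
        assert all(tr[p] == 1 for p in uni.iter_pairs())

    def test_outside_universe_dropped(self):
        uni = make_universe(1, 2)
        p = pred([("zz", "g0", 0.9), ("r0", "g0", 0.5)])
        tr = rank_with_ties(p, uni)
        assert tr[("r0", "g0")] == 1 and tr.n_listed == 1


class TestConfusion:
    def test_perfect(self):
        gs = net([("r0", "g0"), ("r0", "g1")])
        uni = make_universe(1, 3)
        c = confusion_at_cutoff(pred([("r0", "g0", 0.9), ("r0", "g1", 0.8)]), gs, uni)
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_disjoint(self):
        gs = net([("r0", "g0")])
        uni = make_universe(1, 3)
        c = confusion_at_cutoff(pred([("r0", "g1", 0.9), ("r0", "g2", 0.8)]), gs, uni)
        assert (c.tp, c.fp) == (0, 2)

    def test_set_arithmetic(self):
        # |P|=5, universe 100, list of 4 with 3 true -> (3,1,2,94)
        uni = make_universe(10, 10)
        rng = rng_for(3)
        pairs = list(uni.iter_pairs())
        positives = [pairs[i] for i in rng.choice(100, 5, replace=False)]
        gs = net(positives)
        listed = positives[:3] + [p for p in pairs if p not in positives][:1]
        c = confusion_at_cutoff(
            pred([(a, b, 1 - i / 10) for i, (a, b) in enumerate(listed)]), gs, uni
        )
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 1, 2, 94)


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts,mcc,f1",
        [
            ((5, 0, 0, 95), 1.0, 1.0),
            ((3, 1, 2, 94), 0.65563, 2 / 3),
            ((0, 4, 5, 91), None, 0.0),  # mcc just needs to be negative
        ],
    )
    def test_known_tables(self, counts, mcc, f1):
        m, f = confusion_metrics(ConfusionCounts(*counts))
        if mcc is None:
            assert m < 0
        else:
            assert m == pytest.approx(mcc, abs=1e-4)
        assert f == pytest.approx(f1, abs=1e-12)

    def test_degenerate_denominator_zero(self):
        m, f = confusion_metrics(ConfusionCounts(0, 0, 0, 10))
        assert m == 0.0 and f == 0.0

    def test_mcc_swap_symmetry_f1_not(self):
        rng = rng_for(5)
        asymmetric_seen = False
        for _ in range(50):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 20, size=4))
            c = ConfusionCounts(tp, fp, fn, tn)
            swapped = ConfusionCounts(tn, fn, fp, tp)
            m1, f1_ = confusion_metrics(c)
            m2, f2_ = confusion_metrics(swapped)
            assert m1 == pytest.approx(m2, abs=1e-12)
            # direct-formula cross-check
            denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            if denom:
                assert m1 == pytest.approx((tp * tn - fp * fn) / denom, abs=1e-12)
            if f1_ != pytest.approx(f2_):
                asymmetric_seen = True
        assert asymmetric_seen


class TestAssessGlobal:
    def test_perfect_prediction(self):
        gs = net([("r0", "g0"), ("r0", "g1")])
        uni = make_universe(1, 4)
        p = pred([("r0", "g0", 0.9), ("r0", "g1", 0.8)])
        res = assess_global(p, gs, uni)
        assert res.aupr == 1.0 and res.auroc == 1.0
        assert res.mcc == 1.0 and res.f1 == 1.0

    def test_all_tied_whole_universe_auroc_half(self):
        uni = make_universe(2, 5)
        pairs = list(uni.iter_pairs())
        gs = net(pairs[:3])
        p = pred([(a, b, 0.5) for a, b in pairs])
        res = assess_global(p, gs, uni)
        assert res.auroc == pytest.approx(0.5, abs=1e-12)

    def test_worked_pr_integration(self):
        # P={e1,e3} in a 6-pair universe, ranked [e1,e2,e3]:
        # blocks give (0.5, 1), (0.5, 1/2), (1.0, 2/3); anchored at (0,1).
        uni = make_universe(1, 6)
        pairs = list(uni.iter_pairs())
        gs = net([pairs[0], pairs[2]])
        p = pred([(a, b, 1 - i / 10) for i, (a, b) in enumerate(pairs[:3])])
        res = assess_global(p, gs, uni)
        expected = 0.5 * 1.0 + 0.0 + 0.5 * (0.5 + 2 / 3) / 2
        assert res.aupr == pytest.approx(expected, abs=1e-12)
        assert res.aupr == pytest.approx(0.7917, abs=1e-4)

    def test_matches_enumeration_oracle_on_random_instances(self):
        for seed in range(100):
            rng = rng_for(seed)
            uni, positives, entries, gs = random_instance(rng)
            res = assess_global(pred(entries), gs, uni)
            o_aupr, o_auroc = curve_areas(
                [((a, b), s) for a, b, s in entries], positives, uni.n_pairs
            )
            assert res.aupr == pytest.approx(o_aupr, abs=1e-9), seed
            assert res.auroc == pytest.approx(o_auroc, abs=1e-9), seed

    def test_random_permutation_auroc_converges_to_half(self):
        uni = make_universe(5, 100)
        pairs = list(uni.iter_pairs())
        gs = net([pairs[i] for i in rng_for(0).choice(len(pairs), 40, replace=False)])
        vals = []
        for seed in range(200):
            rng = rng_for(1000 + seed)
            perm = rng.permutation(len(pairs))
            p = pred(
                [(pairs[i][0], pairs[i][1], 1 - k / (len(pairs) + 1)) for k, i in enumerate(perm)]
            )
            vals.append(assess_global(p, gs, uni).auroc)
        assert abs(float(np.mean(vals)) - 0.5) < 0.02

    def test_reversed_ranking_flips_auroc(self):
        rng = rng_for(17)
        uni, positives, entries, gs = random_instance(rng)
        # remove ties and cover the whole universe so reversal is exact
        pairs = list(uni.iter_pairs())
        entries = [(a, b, 1 - i / (len(pairs) + 1)) for i, (a, b) in enumerate(pairs)]
        fwd = assess_global(pred(entries), gs, uni).auroc
        rev_entries = [
            (a, b, 1 - i / (len(pairs) + 1))
            for i, (a, b, _) in enumerate(reversed(entries))
        ]
        rev = assess_global(pred(rev_entries), gs, uni).auroc
        assert fwd + rev == pytest.approx(1.0, abs=1e-12)

    def test_undirected_vs_directed_gs_requires_symmetrize(self):
        gs = net([("a", "b")])
        uni = Universe(frozenset("ab"), frozenset("ab"))
        p = pred([("b", "a", 0.9)], network_type="COEX", directed=False)
        with pytest.raises(ValueError, match="symmetrize"):
            assess_global(p, gs, uni)
        res = assess_global(symmetrize_prediction(p), gs, uni)
        assert res.counts_at_cutoff.tp == 1

    def test_coregulation_gs_ignores_direction(self):
        gs = net([("a", "b"), ("b", "c")], directed=False)
        uni = Universe.unordered("abc")
        p = pred([("b", "a", 0.9), ("a", "b", 0.8), ("c", "b", 0.7)])
        res = assess_global(p, gs, uni)
        # (b,a) and (a,b) collapse to one pair; both GS pairs recovered
        assert res.counts_at_cutoff.tp == 2
        assert res.counts_at_cutoff.fp == 0

    def test_degenerate_positive_or_negative_sets_error(self):
        uni = make_universe(1, 2)
        p = pred([("r0", "g0", 0.9)])
        with pytest.raises(ValueError, match="positives"):
            assess_global(p, net([("zz", "qq")]), uni)
        with pytest.raises(ValueError, match="negatives"):
            assess_global(p, net([("r0", "g0"), ("r0", "g1")]), uni)


class TestAssessRegulons:
    def test_perfect_regulon(self, toy_gs, full_universe):
        entries = [(u, v, 1 - i / 10) for i, (u, v) in enumerate(sorted(toy_gs.edges))]
        scores = {s.tf: s for s in assess_regulons(pred(entries), toy_gs, full_universe)}
        assert scores["t1"].mcc == 1.0 and scores["t1"].f1 == 1.0

    def test_no_predicted_targets_zero_f1(self, toy_gs, full_universe):
        scores = {s.tf: s for s in assess_regulons(pred([]), toy_gs, full_universe)}
        assert scores["t1"].f1 == 0.0

    def test_kout_normalization(self, toy_gs, full_universe):
        scores = {s.tf: s for s in assess_regulons(pred([]), toy_gs, full_universe)}
        # kmax = 3 (t2 regulates b, c, itself); t1 has kout 2
        assert scores["t1"].kout == 2
        assert scores["t1"].kout_over_kmax == pytest.approx(2 / 3)
        assert scores["t2"].kout_over_kmax == 1.0

    def test_tf_outside_universe_skipped(self, toy_gs):
        uni = Universe(frozenset({"t1"}), frozenset(toy_gs.nodes))
        scores = assess_regulons(pred([]), toy_gs, uni)
        assert [s.tf for s in scores] == ["t1"]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_property_oracle_agreement(seed):
    """AUPR/AUROC equal threshold enumeration for arbitrary tied lists."""
    rng = rng_for(seed)
    uni, positives, entries, gs = random_instance(rng, max_pairs=20)
    res = assess_global(pred(entries), gs, uni)
    o_aupr, o_auroc = curve_areas(
        [((a, b), s) for a, b, s in entries], positives, uni.n_pairs
    )
    assert res.aupr == pytest.approx(o_aupr, abs=1e-9)
    assert res.auroc == pytest.approx(o_auroc, abs=1e-9)
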