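"""Weight normalization, scores, evalue optimization, grid search."""

import math

import numpy as np
import pytest

from tiervar.consensus import MembershipRow, MembershipTable, build_membership, tier1
from tiervar.variant_model import VariantKey
from tiervar.weighting import (
    CallerVafStats,
    EvalCounts,
    counts_at_threshold,
    enumerate_weight_grid,
    grid_search,
    normalize_weights,
    optimize_threshold,
    pr_metrics,
    score_binary,
    score_vaf,
)

from conftest import make_callset, make_key


def brute_force_min_evalue(scores, labels, candidates):
    """Exhaustive threshold scan, plain python."""
    best = None
    for thr in sorted(candidates):
        fp = sum(1 for s, y in zip(scores, labels) if s >= thr and not y)
        fn = sum(1 for s, y in zip(scores, labels) if s < thr and y)
        if best is None or fp + fn < best[1]:
            best = (thr, fp + fn)
    return best


class TestNormalizeWeights:
    @pytest.mark.parametrize(
        "v, expected",
        [
            ((1.0, 1.0, 1.0), (1 / 3, 1 / 3, 1 / 3)),
            ((0.0, 0.0, 0.5), (0.0, 0.0, 1.0)),
            ((0.2, 0.3, 0.5), (0.2, 0.3, 0.5)),
        ],
    )
    def test_examples(self, v, expected):
        w = normalize_weights(v).w
        assert w == pytest.approx(expected)
        assert sum(w) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_weights((0.0, 0.0, 0.0))

    def test_scale_invariance(self):
        a = normalize_weights((0.1, 0.2, 0.3)).w
        b = normalize_weights((0.2, 0.4, 0.6)).w
        assert a == pytest.approx(b, abs=1e-12)


class TestScores:
    def test_binary_examples(self):
        w = normalize_weights((1.0, 1.0, 1.0))
        assert score_binary(w, (True, True, True)) == pytest.approx(1.0)
        assert score_binary(w, (True, False, True)) == pytest.approx(2 / 3)

    def test_binary_matches_dot_product(self, rng):
        for _ in range(50):
            v = tuple(rng.choice(np.round(np.arange(0, 1.1, 0.1), 1), 3))
            if sum(v) == 0:
                continue
            w = normalize_weights(v)
            c = tuple(bool(b) for b in rng.integers(0, 2, 3))
            expected = sum(wi * int(ci) for wi, ci in zip(w.w, c))
            assert score_binary(w, c) == pytest.approx(expected, abs=1e-12)

    def test_vaf_centering_and_unit_z(self):
        stats = CallerVafStats((0.2, 0.3, 0.4), (0.1, 0.1, 0.2))
        w = normalize_weights((1.0, 1.0, 1.0))
        assert score_vaf(w, (0.2, 0.3, 0.4), stats) == pytest.approx(0.0)
        w_m = normalize_weights((0.0, 0.0, 1.0))
        assert score_vaf(w_m, (None, None, 0.6), stats) == pytest.approx(1.0)

    def test_zero_sd_with_positive_weight_rejected(self):
        stats = CallerVafStats((0.2, 0.3, 0.4), (0.1, 0.0, 0.2))
        with pytest.raises(ValueError, match="standard deviation"):
            score_vaf(normalize_weights((0, 1.0, 0)), (0.1, 0.2, 0.3), stats)

    def test_missing_vaf_contributes_zero_value_z(self):
        stats = CallerVafStats((0.5, 0.5, 0.5), (0.25, 0.25, 0.25))
        w = normalize_weights((0.0, 0.0, 1.0))
        assert score_vaf(w, (None, None, None), stats) == pytest.approx(-2.0)


class TestOptimizeThreshold:
    def test_perfect_separation_smallest_threshold(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [False, False, True, True]
        thr, counts = optimize_threshold(scores, labels, "binary")
        assert counts.evalue == 0
        assert thr == pytest.approx(0.8)  # smallest achievable zero-evalue threshold

    def test_all_positive_labels(self):
        scores = [0.3, 0.6, 0.9]
        thr, counts = optimize_threshold(scores, [True] * 3, "binary")
        assert thr <= min(scores) and counts.fn == 0

    def test_matches_bruteforce_small_instances(self, rng):
        for _ in range(30):
            n = 30
            scores = list(np.round(rng.random(n), 3))
            labels = list(rng.random(n) < 0.4)
            thr, counts = optimize_threshold(scores, labels, "binary")
            b_thr, b_ev = brute_force_min_evalue(scores, labels, set(scores))
            assert counts.evalue == b_ev
            assert thr == pytest.approx(b_thr)

    def test_vaf_mode_grid(self, rng):
        scores = list(rng.normal(0, 1, 40))
        labels = list(np.asarray(scores) > 0.5)
        thr, counts = optimize_threshold(scores, labels, "vaf", step=0.01)
        assert -3.0 <= thr <= 3.0
        cand = [-3.0 + 0.01 * i for i in range(601)]
        _, b_ev = brute_force_min_evalue(scores, labels, cand)
        assert counts.evalue == b_ev

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            optimize_threshold([], [], "binary")


class TestEvalCounts:
    def test_evalue_and_rates(self):
        c = EvalCounts(tp=452, fp=63, fn=1327)
        assert c.evalue == 1390
        assert c.precision == pytest.approx(452 / 515)
        assert c.recall == pytest.approx(452 / 1779)
        assert c.fn_rate == pytest.approx(1327 / 1779)

    def test_undefined_flags(self):
        c = EvalCounts(0, 0, 0)
        assert not c.precision_defined and not c.recall_defined
        assert math.isnan(c.precision) and math.isnan(c.recall)


class TestPrMetrics:
    def test_perfect_ranking(self):
        curve, auprc = pr_metrics([0.1, 0.2, 0.8, 0.9], [False, False, True, True])
        assert auprc == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        _, auprc = pr_metrics([0.5] * 10, [True] * 3 + [False] * 7)
        assert auprc == pytest.approx(0.3)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_metrics([0.1, 0.2], [False, False])

    def test_matches_rank_based_computation(self, rng):
        for _ in range(20):
            scores = rng.random(20)
            labels = rng.random(20) < 0.5
            if not labels.any():
                continue
            _, auprc = pr_metrics(scores, labels)
            # step-integration oracle over distinct thresholds, descending
            n_pos = labels.sum()
            expected, prev_recall = 0.0, 0.0
            for thr in sorted(set(scores), reverse=True):
                called = scores >= thr
                tp = int((called & labels).sum())
                prec = tp / called.sum()
                rec = tp / n_pos
                expected += (rec - prev_recall) * prec
                prev_recall = rec
            assert auprc == pytest.approx(expected, abs=1e-12)


class TestWeightGrid:
    def test_raw_grid_size(self):
        groups = enumerate_weight_grid()
        assert sum(len(v) for v in groups.values()) == 11 ** 3 - 1  # 1330

    def test_collapsed_grid_strictly_smaller(self):
        groups = enumerate_weight_grid()
        assert len(groups) < 1330
        # e.g. (0.1,0.1,0.1) and (1,1,1) normalize identically
        key = tuple(round(1 / 3, 10) for _ in range(3))
        assert len(groups[key]) >= 2


def _random_membership(rng, n=25, sample="S1"):
    rows = {}
    for i in range(n):
        called = tuple(bool(b) for b in rng.integers(0, 2, 3))
        if not any(called):
            called = (True, False, False)
        vafs = tuple(
            round(float(rng.uniform(0.05, 0.9)), 3) if c else None for c in called
        )
        rows[make_key(10 * (i + 1), sample=sample)] = MembershipRow(called, vafs)
    return MembershipTable(sample, rows)


class TestGridSearch:
    def test_single_caller_corner_is_that_callers_confusion(self, rng):
        mt = _random_membership(rng)
        truth = {k for k in mt.rows if rng.random() < 0.5} or {next(iter(mt.rows))}
        universe = set(mt.rows) | truth
        res = grid_search(mt, truth, "binary", universe=universe)
        row = res.table[
            (res.table.w_s == 0) & (res.table.w_r == 0) & (res.table.w_m == 1.0)
        ].iloc[0]
        m_calls = {k for k, r in mt.rows.items() if r.called[2]}
        fp_m = len(m_calls - truth)
        fn_m = len(truth - m_calls)
        # the optimum cannot beat the single-caller partition, and when the
        # threshold selects exactly the caller's calls it equals fp+fn
        assert row["evalue"] <= fp_m + fn_m

    def test_min_evalue_not_above_equal_weights(self, rng):
        mt = _random_membership(rng)
        truth = {k for k in mt.rows if rng.random() < 0.4}
        res = grid_search(mt, truth, "binary")
        eq_key = round(1 / 3, 10)
        eq_row = res.table[
            np.isclose(res.table.w_s, eq_key)
            & np.isclose(res.table.w_r, eq_key)
            & np.isclose(res.table.w_m, eq_key)
        ].iloc[0]
        assert res.table["evalue"].min() <= eq_row["evalue"]

    def test_equal_weights_threshold_one_reproduces_tier1(self, rng):
        cs_s = make_callset("snpir", [int(p) for p in rng.choice(range(10, 400, 10), 20, replace=False)])
        cs_r = make_callset("rvboost", [int(p) for p in rng.choice(range(10, 400, 10), 20, replace=False)])
        cs_m = make_callset("mutect2", [int(p) for p in rng.choice(range(10, 400, 10), 20, replace=False)])
        mt = build_membership(cs_s, cs_r, cs_m)
        truth = {make_key(int(p)) for p in rng.choice(range(10, 400, 10), 15, replace=False)}
        universe = set(mt.rows) | truth
        keys = sorted(universe)
        w = normalize_weights((1.0, 1.0, 1.0))
        scores = np.array(
            [
                score_binary(w, mt.rows[k].called) if k in mt.rows else 0.0
                for k in keys
            ]
        )
        labels = np.array([k in truth for k in keys])
        counts = counts_at_threshold(scores, labels, 1.0 - 1e-9)
        t1 = tier1(mt)
        assert counts.tp == len(t1 & truth)
        assert counts.fp == len(t1 - truth)
        assert counts.fn == len(truth - t1)
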