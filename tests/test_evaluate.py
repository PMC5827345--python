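"""Concordance, triage, editing candidates, VAF correlation, comparisons."""

import math

import numpy as np
import pytest

from tiervar.evaluate import (
    CorrelationResult,
    EditingCandidate,
    TriageThresholds,
    TruthRecord,
    TruthSet,
    compare_callsets,
    concordance,
    format_percent,
    mutation_count_ttest,
    read_truth_vcf,
    restrict_callable,
    round_half_up,
    triage_discordant,
    triage_missed,
    vaf_correlation,
    write_truth_vcf,
)
from tiervar.variant_model import (
    NORMAL_DNA,
    TUMOR_DNA,
    TUMOR_RNA,
    EvidenceTable,
    SiteEvidence,
    VariantKey,
)

from conftest import make_key


def _truth(entries):
    """entries: {pos: (region, dp, dna_vaf, rna_vaf)}"""
    return TruthSet(
        {
            make_key(pos): TruthRecord(region, dp, dvaf, rvaf)
            for pos, (region, dp, dvaf, rvaf) in entries.items()
        }
    )


class TestRounding:
    @pytest.mark.parametrize(
        "num, den, decimals, expected",
        [
            (68, 125, 2, "54.40%"),
            (78, 125, 2, "62.40%"),
            (61, 116, 2, "52.59%"),
            (452, 1305, 1, "34.6%"),
            (8517, 9845, 1, "86.5%"),
            (474, 9845, 1, "4.8%"),
            (724, 9845, 1, "7.4%"),
            (53, 116, 1, "45.7%"),
            (22, 116, 1, "19.0%"),
        ],
    )
    def test_printed_percentages(self, num, den, decimals, expected):
        assert format_percent(num, den, decimals) == expected

    def test_half_up_ties(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(54.405, 2) == 54.41


class TestRestrictCallable:
    def test_boundary_depth_10_retained(self):
        truth = _truth({1: ("exonic", 10, 0.3, 0.3), 2: ("exonic", 9, 0.3, 0.3)})
        kept = restrict_callable(truth)
        assert {k.pos for k in kept.variants} == {1}

    def test_all_zero_depth_empty(self):
        truth = _truth({p: ("exonic", 0, 0.2, 0.2) for p in range(1, 6)})
        assert len(restrict_callable(truth)) == 0

    def test_matches_independent_scan(self, small_dataset):
        kept = restrict_callable(small_dataset.truth)
        expected = sum(
            1 for r in small_dataset.truth.records.values() if r.expression_dp >= 10
        )
        assert len(kept) == expected


class TestConcordance:
    def test_identity(self):
        truth = _truth({p: ("exonic", 50, 0.4, 0.4) for p in range(1, 11)})
        rep = concordance(truth.variants, truth, truth)
        c = rep.counts
        assert (c.tp, c.fp, c.fn, c.evalue) == (10, 0, 0, 0)
        assert c.precision == 1.0 and c.recall == 1.0

    def test_published_contingency_shape(self):
        # 515 RNA calls, 452 concordant, against 1779 callable truth
        truth_full = _truth({p: ("exonic", 50, 0.4, 0.4) for p in range(1, 10_362)})
        callable_keys = sorted(truth_full.variants)[:1779]
        truth_callable = TruthSet({k: truth_full.records[k] for k in callable_keys})
        calls = set(callable_keys[:452]) | {make_key(100_000 + i) for i in range(63)}
        rep = concordance(calls, truth_full, truth_callable)
        c = rep.counts
        assert (c.tp, c.fp, c.fn) == (452, 63, 1327)
        assert format_percent(c.fn, c.tp + c.fn, 1) == "74.6%"
        # restricting truth further only reduces fn, never tp/fp
        tighter = TruthSet({k: truth_full.records[k] for k in callable_keys[:500]})
        rep2 = concordance(calls, truth_full, tighter)
        assert rep2.counts.tp == 452 and rep2.counts.fp == 63
        assert rep2.counts.fn <= c.fn

    def test_partition_identities(self, small_dataset):
        truth = small_dataset.truth
        callable_t = restrict_callable(truth)
        calls = set(list(truth.variants)[:40]) | {make_key(999_999)}
        rep = concordance(calls, truth, callable_t)
        c = rep.counts
        assert c.tp + c.fp == len(calls)
        assert c.fn + len(calls & callable_t.variants) == len(callable_t.variants)


class TestTriageMissed:
    def test_priority_categories(self):
        truth = _truth(
            {
                1: ("exonic", 0, 0.5, 0.5),     # not expressed
                2: ("exonic", 5, 0.5, 0.5),     # low expression
                3: ("non_exonic", 50, 0.5, 0.5),  # non-exonic
                4: ("exonic", 50, 0.05, 0.5),   # low DNA VAF
                5: ("exonic", 50, 0.5, 0.05),   # low RNA VAF
                6: ("exonic", 50, 0.5, 0.5),    # uncalled
                7: ("exonic", 50, 0.5, 0.5),    # called (not missed)
            }
        )
        report = triage_missed(truth, {make_key(7)})
        got = {c: [k.pos for k in ks] for c, ks in report.categories.items()}
        assert got == {
            "not_expressed": [1], "low_expression": [2], "non_exonic": [3],
            "low_dna_vaf": [4], "low_rna_vaf": [5], "filtered": [], "uncalled": [6],
        }
        assert report.denominator == 6
        assert report.fraction("not_expressed") == pytest.approx(1 / 6)

    def test_partition_is_exact(self, small_dataset):
        truth = small_dataset.truth
        calls = set(list(truth.variants)[::3])
        report = triage_missed(truth, calls)
        all_cat = [k for ks in report.categories.values() for k in ks]
        missed = truth.variants - calls
        assert len(all_cat) == len(set(all_cat)) == len(missed) == report.denominator

    def test_matches_rule_by_rule_scan(self, small_dataset):
        truth = small_dataset.truth
        report = triage_missed(truth, set())
        th = TriageThresholds()
        for cat, keys in report.categories.items():
            for key in keys:
                r = truth.records[key]
                if cat == "not_expressed":
                    assert r.expression_dp == 0
                elif cat == "low_expression":
                    assert 0 < r.expression_dp <= 10
                elif cat == "non_exonic":
                    assert r.expression_dp > 10 and r.region_class == "non_exonic"
                elif cat == "low_dna_vaf":
                    assert r.dna_vaf < th.low_vaf and r.region_class == "exonic"
                elif cat == "low_rna_vaf":
                    assert r.rna_vaf < th.low_vaf and r.dna_vaf >= th.low_vaf


class TestTriageDiscordant:
    def _evidence(self, key, rna=(50, 20), dna=(80, 0), normal=(60, 0)):
        ev = EvidenceTable()
        ev.put(key, SiteEvidence(TUMOR_RNA, *rna))
        ev.put(key, SiteEvidence(TUMOR_DNA, *dna))
        ev.put(key, SiteEvidence(NORMAL_DNA, *normal))
        return ev

    def test_low_rna_depth_first(self):
        key = make_key(50)
        report, cands = triage_discordant([key], self._evidence(key, rna=(7, 3)))
        assert report.categories["rna_dp_lt10"] == [key]
        assert not cands

    def test_dna_vaf_positive(self):
        key = make_key(50)
        report, _ = triage_discordant([key], self._evidence(key, dna=(80, 4)))
        assert report.categories["dna_vaf_gt0"] == [key]

    def test_editing_candidate_recurrence_across_samples(self):
        # the same A>G site, zero DNA VAF and deep coverage, in 4 samples
        ev = EvidenceTable()
        keys = []
        for i in range(4):
            key = VariantKey(f"S{i}", "chr3", 58141791, "A", "G")
            keys.append(key)
            ev.put(key, SiteEvidence(TUMOR_RNA, 60, 25))
            ev.put(key, SiteEvidence(TUMOR_DNA, 90, 0))
            ev.put(key, SiteEvidence(NORMAL_DNA, 70, 0))
        report, cands = triage_discordant(keys, ev)
        assert len(report.categories["editing_candidate"]) == 4
        assert len(cands) == 1
        cand = cands[0]
        assert (cand.chrom, cand.pos, cand.substitution) == ("chr3", 58141791, "A>G")
        assert cand.recurrence == 4

    def test_non_editing_substitution_is_unexplained(self):
        key = make_key(50, ref="G", alt="A")  # G>A is not an editing class
        report, cands = triage_discordant([key], self._evidence(key))
        assert report.categories["unexplained"] == [key]
        assert not cands

    def test_categories_partition(self, small_dataset):
        disc = sorted(small_dataset.evidence.keys() - small_dataset.truth.variants)
        report, _ = triage_discordant(disc, small_dataset.evidence)
        total = sum(len(v) for v in report.categories.values())
        assert total == len(disc) == report.denominator


class TestVafCorrelation:
    def _sites_and_evidence(self, pairs):
        sites, ev = {}, EvidenceTable()
        for i, (d, r) in enumerate(pairs):
            key = make_key(10 * (i + 1))
            sites[key] = (d, r)
            ev.put(key, SiteEvidence(TUMOR_RNA, 50, int(50 * r)))
            ev.put(key, SiteEvidence(TUMOR_DNA, 50, int(50 * d)))
            ev.put(key, SiteEvidence(NORMAL_DNA, 50, 0))
        return sites, ev

    def test_perfect_positive_and_negative(self):
        vals = [0.1, 0.3, 0.5, 0.7]
        sites, ev = self._sites_and_evidence([(v, v) for v in vals])
        res = vaf_correlation(sites, ev)["dp_gt10_all"]
        assert res.defined and res.r == pytest.approx(1.0)
        sites, ev = self._sites_and_evidence([(v, 1 - v) for v in vals])
        res = vaf_correlation(sites, ev)["dp_gt10_all"]
        assert res.r == pytest.approx(-1.0)

    def test_undefined_flagged(self):
        sites, ev = self._sites_and_evidence([(0.5, 0.5), (0.6, 0.4)])
        res = vaf_correlation(sites, ev)["dp_gt10_all"]
        assert not res.defined and math.isnan(res.r) and res.n == 2

    def test_strata_select_by_depth(self):
        sites, ev = self._sites_and_evidence([(v, v) for v in (0.1, 0.4, 0.7)])
        shallow = make_key(999)
        sites[shallow] = (0.2, 0.9)
        ev.put(shallow, SiteEvidence(TUMOR_RNA, 5, 4))
        ev.put(shallow, SiteEvidence(TUMOR_DNA, 50, 10))
        ev.put(shallow, SiteEvidence(NORMAL_DNA, 50, 0))
        res = vaf_correlation(sites, ev)
        assert res["dp_gt10_all"].n == 3       # shallow RNA site excluded
        assert res["dp_gt10_tumor_dna"].n == 4


class TestCompareCallsets:
    def test_published_partition(self):
        both = {make_key(i + 1) for i in range(175)}
        a_only = {make_key(1000 + i) for i in range(12)}
        b_only = {make_key(2000 + i) for i in range(121)}
        cmp = compare_callsets(both | a_only, both | b_only)
        assert (cmp.both, cmp.a_only, cmp.b_only) == (175, 12, 121)
        assert cmp.union_size == 308

    def test_identical_sets(self):
        a = {make_key(i) for i in range(1, 8)}
        cmp = compare_callsets(a, set(a))
        assert (cmp.both, cmp.a_only, cmp.b_only) == (7, 0, 0)

    def test_random_sets_match_set_arithmetic(self, rng):
        for _ in range(20):
            a = {make_key(int(p)) for p in rng.integers(1, 200, 40)}
            b = {make_key(int(p)) for p in rng.integers(1, 200, 40)}
            cmp = compare_callsets(a, b)
            assert cmp.both == len(a & b)
            assert cmp.a_only == len(a - b)
            assert cmp.b_only == len(b - a)
            assert cmp.union_size == len(a | b)


class TestTtestWrapper:
    def test_degrees_of_freedom(self, rng):
        a = rng.poisson(30, 11)
        b = rng.poisson(20, 10)
        t, p, df = mutation_count_ttest(a, b)
        assert df == 19
        assert 0 <= p <= 1


class TestTruthVcfRoundTrip:
    def test_round_trip(self, small_dataset, tmp_path):
        path = tmp_path / "truth.vcf"
        write_truth_vcf(small_dataset.truth, path, small_dataset.contigs,
                        small_dataset.sample_id)
        back = read_truth_vcf(path, small_dataset.sample_id)
        assert back.records == small_dataset.truth.records
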