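"""Concordance of RNA callsets against DNA-derived truth, with triage.

The truth set is the collection of somatic variants supported by at
least two DNA callers.  Because RNA-based discovery is only possible at
expressed sites, false negatives are counted against the *callable*
truth (tumor-RNA read depth above 10 at the site), while true and
false positives are counted against the full truth set — the
asymmetric denominators of the published contingency construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats as sps

from .filters import FilterVerdict
from .consensus import MembershipTable
from .variant_model import (
    NORMAL_DNA,
    TUMOR_DNA,
    TUMOR_RNA,
    EvidenceTable,
    VariantKey,
    _vcf_header,
)
from .weighting import EvalCounts

EDITING_CLASSES = ("A>G", "C>T")

MISSED_CATEGORIES = (
    "not_expressed",
    "low_expression",
    "non_exonic",
    "low_dna_vaf",
    "low_rna_vaf",
    "filtered",
    "uncalled",
)

DISCORDANT_CATEGORIES = (
    "rna_dp_lt10",
    "dna_dp_lt10",
    "dna_vaf_gt0",
    "editing_candidate",
    "unexplained",
)


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero, matching printed report style."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(numerator: int, denominator: int, decimals: int = 1) -> str:
    """Percentage string with half-up rounding, e.g. 68/125 -> '54.40%'."""
    if denominator == 0:
        return "NA"
    pct = round_half_up(100.0 * numerator / denominator, decimals)
    return f"{pct:.{decimals}f}%"


@dataclass(frozen=True)
class TruthRecord:
    region_class: str  # 'exonic' or 'non_exonic'
    expression_dp: int  # tumor-RNA dp_hq at the site
    dna_vaf: float
    rna_vaf: float
    cosmic_flag: bool = False

    def __post_init__(self) -> None:
        if self.region_class not in ("exonic", "non_exonic"):
            raise ValueError(f"bad region_class {self.region_class!r}")
        if self.expression_dp < 0:
            raise ValueError("expression_dp must be >= 0")


class TruthSet:
    """DNA-derived somatic truth variants with per-variant annotations."""

    def __init__(self, records: dict[VariantKey, TruthRecord] | None = None) -> None:
        self.records: dict[VariantKey, TruthRecord] = dict(records or {})

    @property
    def variants(self) -> set[VariantKey]:
        return set(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.records


def restrict_callable(truth: TruthSet, min_rna_dp: int = 10) -> TruthSet:
    """Truth subset discoverable from RNA: sites with RNA depth >= min_rna_dp.

    The published rule removes DNA calls "with a read depth below 10 in
    RNA", so depth exactly 10 is retained.
    """
    return TruthSet(
        {k: r for k, r in truth.records.items() if r.expression_dp > min_rna_dp - 1}
    )


@dataclass
class ConcordanceReport:
    counts: EvalCounts
    n_calls: int
    n_truth_full: int
    n_truth_callable: int

    def summary_lines(self) -> list[str]:
        c = self.counts
        return [
            f"calls: {self.n_calls}",
            f"truth (full): {self.n_truth_full}",
            f"truth (callable): {self.n_truth_callable}",
            f"concordant (TP): {c.tp}",
            f"discordant (FP): {c.fp}",
            f"missed callable (FN): {c.fn}",
            f"precision: {format_percent(c.tp, c.tp + c.fp)}",
            f"recall (callable): {format_percent(c.tp, c.tp + c.fn)}",
            f"FN rate: {format_percent(c.fn, c.tp + c.fn)}",
            f"evalue: {c.evalue}",
        ]


def concordance(
    calls: set[VariantKey],
    truth_full: TruthSet,
    truth_callable: TruthSet,
) -> ConcordanceReport:
    """TP against the full truth, FN against the callable truth.

    tp = |calls ∩ truth_full|; fp = |calls \\ truth_full|;
    fn = |truth_callable \\ calls|.
    """
    tfull = truth_full.variants
    tcall = truth_callable.variants
    tp = len(calls & tfull)
    fp = len(calls - tfull)
    fn = len(tcall - calls)
    return ConcordanceReport(
        counts=EvalCounts(tp, fp, fn),
        n_calls=len(calls),
        n_truth_full=len(tfull),
        n_truth_callable=len(tcall),
    )


@dataclass
class TriageReport:
    """Category -> (count, fraction of denominator, variant list).

    Categories are assigned by a fixed priority order; each variant
    falls in exactly one.
    """

    categories: dict[str, list[VariantKey]]
    denominator: int

    def count(self, category: str) -> int:
        return len(self.categories.get(category, []))

    def fraction(self, category: str) -> float:
        return self.count(category) / self.denominator if self.denominator else math.nan

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category": cat,
                "count": len(keys),
                "fraction": len(keys) / self.denominator if self.denominator else math.nan,
            }
            for cat, keys in self.categories.items()
        ]
        return pd.DataFrame(rows, columns=["category", "count", "fraction"])


@dataclass
class TriageThresholds:
    expressed_min_dp: int = 1      # expressed iff expression_dp > 0
    abundant_min_dp: int = 11      # abundant iff expression_dp > 10
    low_vaf: float = 0.20          # low VAF iff vaf < 0.20
    deep_dp: int = 10              # 'deep' coverage for discordant triage


def triage_missed(
    truth_full: TruthSet,
    calls: set[VariantKey],
    per_caller_membership: MembershipTable | None = None,
    verdicts: Mapping[VariantKey, FilterVerdict] | None = None,
    thresholds: TriageThresholds | None = None,
) -> TriageReport:
    """Explain each truth variant missed by the final callset.

    Priority: not_expressed -> low_expression -> non_exonic ->
    low_dna_vaf -> low_rna_vaf -> filtered (a caller called it but a
    hard filter removed it) -> uncalled.
    """
    th = thresholds or TriageThresholds()
    categories: dict[str, list[VariantKey]] = {c: [] for c in MISSED_CATEGORIES}
    missed = [k for k in sorted(truth_full.records) if k not in calls]
    for key in missed:
        rec = truth_full.records[key]
        if rec.expression_dp < th.expressed_min_dp:
            cat = "not_expressed"
        elif rec.expression_dp < th.abundant_min_dp:
            cat = "low_expression"
        elif rec.region_class != "exonic":
            cat = "non_exonic"
        elif rec.dna_vaf < th.low_vaf:
            cat = "low_dna_vaf"
        elif rec.rna_vaf < th.low_vaf:
            cat = "low_rna_vaf"
        else:
            called_by_any = (
                per_caller_membership is not None and key in per_caller_membership
            )
            filtered = (
                verdicts is not None
                and key in verdicts
                and not verdicts[key].passed
            )
            cat = "filtered" if (called_by_any and filtered) else "uncalled"
        categories[cat].append(key)
    return TriageReport(categories=categories, denominator=len(missed))


@dataclass(frozen=True)
class EditingCandidate:
    """Putative RNA-editing site: alt in RNA, zero DNA VAF despite deep
    coverage in tumor RNA, tumor DNA and normal DNA; class A>G or C>T
    as written on the reference strand."""

    chrom: str
    pos: int
    ref: str
    alt: str
    recurrence: int
    samples: tuple[str, ...]

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"


def triage_discordant(
    discordant_calls: Iterable[VariantKey],
    evidence: EvidenceTable,
    thresholds: TriageThresholds | None = None,
) -> tuple[TriageReport, list[EditingCandidate]]:
    """Explain calls absent from the DNA truth set.

    Priority: rna_dp_lt10 -> dna_dp_lt10 -> dna_vaf_gt0 ->
    editing_candidate -> unexplained.  Editing candidates are
    aggregated across samples by site, with recurrence counts.
    """
    th = thresholds or TriageThresholds()
    categories: dict[str, list[VariantKey]] = {c: [] for c in DISCORDANT_CATEGORIES}
    editing_by_site: dict[tuple[str, int, str, str], set[str]] = {}
    keys = sorted(set(discordant_calls))
    for key in keys:
        rna = evidence.get(key, TUMOR_RNA)
        dna = evidence.get(key, TUMOR_DNA)
        normal = evidence.get(key, NORMAL_DNA)
        rna_dp = rna.dp_hq if rna else 0
        dna_dp = dna.dp_hq if dna else 0
        normal_dp = normal.dp_hq if normal else 0
        dna_vaf = dna.vaf if dna else 0.0
        if rna_dp < th.deep_dp:
            cat = "rna_dp_lt10"
        elif dna_dp < th.deep_dp:
            cat = "dna_dp_lt10"
        elif dna_vaf > 0.0:
            cat = "dna_vaf_gt0"
        elif (
            normal_dp >= th.deep_dp
            and key.substitution in EDITING_CLASSES
        ):
            cat = "editing_candidate"
            editing_by_site.setdefault(key.site(), set()).add(key.sample_id)
        else:
            cat = "unexplained"
        categories[cat].append(key)
    candidates = [
        EditingCandidate(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            recurrence=len(samples), samples=tuple(sorted(samples)),
        )
        for (chrom, pos, ref, alt), samples in sorted(editing_by_site.items())
    ]
    report = TriageReport(categories=categories, denominator=len(keys))
    return report, candidates


#: the four read-depth strata of the published RNA/DNA VAF comparison
DEFAULT_VAF_STRATA: dict[str, dict[str, int]] = {
    "dp_gt0_all": {TUMOR_DNA: 1, TUMOR_RNA: 1},
    "dp_gt10_tumor_dna": {TUMOR_DNA: 11},
    "dp_gt10_tumor_and_normal_dna": {TUMOR_DNA: 11, NORMAL_DNA: 11},
    "dp_gt10_all": {TUMOR_DNA: 11, TUMOR_RNA: 11, NORMAL_DNA: 11},
}


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    defined: bool


def vaf_correlation(
    sites: Mapping[VariantKey, tuple[float, float]],
    evidence: EvidenceTable,
    strata: Mapping[str, Mapping[str, int]] | None = None,
) -> dict[str, CorrelationResult]:
    """Pearson r between DNA and RNA VAF per read-depth stratum.

    ``sites`` maps variant -> (dna_vaf, rna_vaf); a stratum is a map
    specimen -> minimum dp_hq.  Undefined (n < 3 or zero variance)
    strata are flagged rather than raised.
    """
    strata = strata or DEFAULT_VAF_STRATA
    out: dict[str, CorrelationResult] = {}
    for name, min_dp in strata.items():
        dna_vals, rna_vals = [], []
        for key in sorted(sites):
            ok = True
            for specimen, dp_min in min_dp.items():
                ev = evidence.get(key, specimen)
                if ev is None or ev.dp_hq < dp_min:
                    ok = False
                    break
            if ok:
                d, r = sites[key]
                dna_vals.append(d)
                rna_vals.append(r)
        n = len(dna_vals)
        if n < 3 or np.std(dna_vals) == 0 or np.std(rna_vals) == 0:
            out[name] = CorrelationResult(math.nan, n, False)
        else:
            r, _ = sps.pearsonr(dna_vals, rna_vals)
            out[name] = CorrelationResult(float(r), n, True)
    return out


@dataclass(frozen=True)
class CallsetComparison:
    both: int
    a_only: int
    b_only: int

    @property
    def union_size(self) -> int:
        return self.both + self.a_only + self.b_only


def compare_callsets(a: set[VariantKey], b: set[VariantKey]) -> CallsetComparison:
    """Disjoint partition of two callsets: shared, a-only, b-only."""
    return CallsetComparison(
        both=len(a & b), a_only=len(a - b), b_only=len(b - a)
    )


def mutation_count_ttest(
    counts_a: Sequence[int], counts_b: Sequence[int]
) -> tuple[float, float, int]:
    """Plain two-sample t-test on per-sample mutation counts.

    Convenience wrapper only; returns (t, p, df) with pooled-variance
    degrees of freedom n_a + n_b - 2.
    """
    res = sps.ttest_ind(counts_a, counts_b, equal_var=True)
    return float(res.statistic), float(res.pvalue), len(counts_a) + len(counts_b) - 2


# ---------------------------------------------------------------------------
# truth-set VCF I/O

_TRUTH_INFO_LINES = [
    '##INFO=<ID=REGION,Number=1,Type=String,Description="exonic or non_exonic">',
    '##INFO=<ID=RNA_DP,Number=1,Type=Integer,Description="Tumor RNA high-quality depth">',
    '##INFO=<ID=DNA_VAF,Number=1,Type=Float,Description="Tumor DNA variant allele fraction">',
    '##INFO=<ID=RNA_VAF,Number=1,Type=Float,Description="Tumor RNA variant allele fraction">',
    '##INFO=<ID=COSMIC,Number=0,Type=Flag,Description="Known COSMIC site">',
]


def write_truth_vcf(
    truth: TruthSet, path: str | Path, contigs: Mapping[str, int | None],
    sample_id: str,
) -> None:
    header = _vcf_header(contigs, _TRUTH_INFO_LINES + [f"##tiervar_sample={sample_id}"])
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in sorted(truth.records):
            rec_in = truth.records[key]
            rec = out.new_record(
                contig=key.chrom, start=key.pos - 1, alleles=(key.ref, key.alt)
            )
            rec.filter.add("PASS")
            rec.info["REGION"] = rec_in.region_class
            rec.info["RNA_DP"] = rec_in.expression_dp
            rec.info["DNA_VAF"] = round(rec_in.dna_vaf, 6)
            rec.info["RNA_VAF"] = round(rec_in.rna_vaf, 6)
            if rec_in.cosmic_flag:
                rec.info["COSMIC"] = True
            out.write(rec)


def read_truth_vcf(path: str | Path, sample_id: str) -> TruthSet:
    records: dict[VariantKey, TruthRecord] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                key = VariantKey(sample_id, rec.chrom, rec.pos, rec.ref.upper(), alt.upper())
                info = rec.info
                records[key] = TruthRecord(
                    region_class=str(info.get("REGION", "exonic")),
                    expression_dp=int(info.get("RNA_DP", 0)),
                    dna_vaf=round(float(info.get("DNA_VAF", 0.0)), 6),
                    rna_vaf=round(float(info.get("RNA_VAF", 0.0)), 6),
                    cosmic_flag=bool(info.get("COSMIC", False)),
                )
    return TruthSet(records)
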