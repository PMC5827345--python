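"""Post-consensus hard filters.

Two families: the germline-evidence filter (normal-DNA depth >= 5 and
VAF < 3% in uniquely mapping reads), and annotation/sequence filters in
the style of RNA germline-caller hard filtering — repeat regions, known
RNA-editing sites, intronic positions near splice junctions,
homopolymer runs, and alt support restricted to the first 6 read bases.
Filters fail closed: a variant whose required evidence is missing is
removed, with a machine-readable reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .variant_model import (
    NORMAL_DNA,
    Callset,
    CallerCall,
    EvidenceTable,
    SiteEvidence,
    VariantKey,
)

logger = logging.getLogger(__name__)

FILTER_REASONS = (
    "germline_dp",
    "germline_vaf",
    "repeat",
    "editing_site",
    "splice_junction",
    "homopolymer",
    "first6bp",
    "mismap_flag",
)


@dataclass(frozen=True)
class ReadSupportSummary:
    """Alt-read positional support: how many alt reads mismatch within
    the first 6 bases of the read."""

    n_alt_reads: int
    n_alt_first6: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_alt_first6 <= self.n_alt_reads):
            raise ValueError("require 0 <= n_alt_first6 <= n_alt_reads")


@dataclass(frozen=True)
class FilterVerdict:
    key: VariantKey
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for r in self.reasons:
            if r not in FILTER_REASONS:
                raise ValueError(f"unknown filter reason {r!r}")

    @property
    def passed(self) -> bool:
        return not self.reasons


def _merge(key: VariantKey, *verdicts: FilterVerdict) -> FilterVerdict:
    reasons: list[str] = []
    for v in verdicts:
        for r in v.reasons:
            if r not in reasons:
                reasons.append(r)
    return FilterVerdict(key, tuple(reasons))


# ---------------------------------------------------------------------------
# annotation resources

class ReferenceSequence:
    """Random access to reference bases, 1-based closed coordinates."""

    def __init__(self, source: str | Path | Mapping[str, str]) -> None:
        if isinstance(source, (str, Path)):
            self._fasta: Fasta | None = Fasta(str(source), sequence_always_upper=True)
            self._seqs: Mapping[str, str] | None = None
        else:
            self._fasta = None
            self._seqs = {c: s.upper() for c, s in source.items()}

    def contig_length(self, chrom: str) -> int | None:
        if self._fasta is not None:
            if chrom not in self._fasta:
                return None
            return len(self._fasta[chrom])
        assert self._seqs is not None
        seq = self._seqs.get(chrom)
        return None if seq is None else len(seq)

    def fetch(self, chrom: str, start: int, end: int) -> str | None:
        """Bases [start, end] 1-based closed, or None if unavailable."""
        length = self.contig_length(chrom)
        if length is None or start < 1 or end > length or start > end:
            return None
        if self._fasta is not None:
            return str(self._fasta[chrom][start - 1 : end])
        assert self._seqs is not None
        return self._seqs[chrom][start - 1 : end]


@dataclass
class AnnotationSet:
    """Interval/position tracks plus reference sequence for the filters.

    All intervals are stored 1-based closed (converted from BED on
    load).  The exon table is kept sorted per contig so membership
    lookups can bisect instead of scanning every gene.
    """

    repeats: dict[str, IntervalTree] | None = None
    editing_sites: dict[str, set[int]] | None = None
    splice_junctions: list[tuple[str, int, int]] | None = None
    exons: dict[str, list[tuple[int, int, str]]] | None = None
    reference: ReferenceSequence | None = None

    def is_exonic(self, chrom: str, pos: int) -> bool:
        import bisect

        table = (self.exons or {}).get(chrom)
        if not table:
            return False
        # rightmost exon starting at or before pos; exons may overlap so
        # scan left while starts could still cover pos
        idx = bisect.bisect_right(table, (pos, float("inf"), "")) - 1
        while idx >= 0:
            start, end, _ = table[idx]
            if start <= pos <= end:
                return True
            idx -= 1
            # starts are sorted; once start < pos - max_exon_len we could
            # stop, but exon counts per contig are small enough to scan
        return False


def load_bed_intervals(path: str | Path) -> dict[str, IntervalTree]:
    """Load a BED file into per-contig interval trees (1-based closed)."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            # BED half-open [start0, end0) -> 1-based closed [start0+1, end0]
            trees.setdefault(chrom, IntervalTree()).addi(start0 + 1, end0 + 1)
    return trees


def load_bed_positions(path: str | Path) -> dict[str, set[int]]:
    """Load a BED file of single positions into per-contig position sets."""
    sites: dict[str, set[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            sites.setdefault(chrom, set()).update(range(start0 + 1, end0 + 1))
    return sites


def load_bed_exons(path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    """Load an exon BED (name column = gene) into a sorted per-contig table."""
    exons: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            gene = fields[3] if len(fields) > 3 else ""
            exons.setdefault(chrom, []).append((start0 + 1, end0, gene))
    for chrom in exons:
        exons[chrom].sort()
    return exons


def load_junctions_tsv(path: str | Path) -> list[tuple[str, int, int]]:
    """Load a junction list TSV with columns contig, intron_start, intron_end."""
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r["contig"]), int(r["intron_start"]), int(r["intron_end"]))
        for _, r in df.iterrows()
    ]


def load_annotations(
    *,
    repeats_bed: str | Path | None = None,
    editing_bed: str | Path | None = None,
    exons_bed: str | Path | None = None,
    junctions_tsv: str | Path | None = None,
    reference_fasta: str | Path | None = None,
) -> AnnotationSet:
    ann = AnnotationSet()
    if repeats_bed:
        ann.repeats = load_bed_intervals(repeats_bed)
    if editing_bed:
        ann.editing_sites = load_bed_positions(editing_bed)
    if exons_bed:
        ann.exons = load_bed_exons(exons_bed)
    if junctions_tsv:
        ann.splice_junctions = load_junctions_tsv(junctions_tsv)
    if reference_fasta:
        ann.reference = ReferenceSequence(reference_fasta)
    return ann


# ---------------------------------------------------------------------------
# individual filters

def germline_filter(
    key: VariantKey, normal_evidence: SiteEvidence | None
) -> FilterVerdict:
    """Require normal-DNA dp_hq >= 5 and VAF strictly below 3%.

    Missing normal evidence is treated as zero depth (fails the depth
    clause): with no germline coverage a somatic assignment cannot be
    supported.
    """
    if normal_evidence is None:
        return FilterVerdict(key, ("germline_dp",))
    reasons = []
    if normal_evidence.dp_hq < 5:
        reasons.append("germline_dp")
    if normal_evidence.vaf >= 0.03:
        reasons.append("germline_vaf")
    return FilterVerdict(key, tuple(reasons))


def interval_filter(
    key: VariantKey, intervals: Mapping[str, IntervalTree], label: str
) -> FilterVerdict:
    """Fail with `label` iff pos lies inside any interval on its contig."""
    tree = intervals.get(key.chrom)
    if tree is not None and tree.overlaps_point(key.pos):
        return FilterVerdict(key, (label,))
    return FilterVerdict(key)


def editing_site_filter(
    key: VariantKey, sites: Mapping[str, set[int]]
) -> FilterVerdict:
    if key.pos in sites.get(key.chrom, ()):
        return FilterVerdict(key, ("editing_site",))
    return FilterVerdict(key)


def splice_junction_filter(
    key: VariantKey,
    junctions: Sequence[tuple[str, int, int]],
    window: int = 4,
) -> FilterVerdict:
    """Fail iff pos is intronic and within `window` bases of an intron end.

    "Within window bases" means the first `window` intronic positions at
    either boundary; exonic positions adjacent to the junction pass.
    """
    for chrom, istart, iend in junctions:
        if chrom != key.chrom or not (istart <= key.pos <= iend):
            continue
        if key.pos - istart < window or iend - key.pos < window:
            return FilterVerdict(key, ("splice_junction",))
    return FilterVerdict(key)


def homopolymer_filter(
    key: VariantKey,
    reference: ReferenceSequence | None,
    run_len: int = 5,
    flank: int = 4,
) -> FilterVerdict:
    """Fail iff a mononucleotide run of length >= run_len overlaps
    [pos - flank, pos + flank]; fails closed when sequence is unavailable."""
    if reference is None:
        logger.warning("homopolymer filter: no reference; failing closed at %s", key)
        return FilterVerdict(key, ("homopolymer",))
    length = reference.contig_length(key.chrom)
    if length is None:
        logger.warning("homopolymer filter: contig %s unavailable; failing closed", key.chrom)
        return FilterVerdict(key, ("homopolymer",))
    win_start = max(1, key.pos - flank - run_len)
    win_end = min(length, key.pos + flank + run_len)
    seq = reference.fetch(key.chrom, win_start, win_end)
    if seq is None:
        logger.warning("homopolymer filter: window unavailable at %s; failing closed", key)
        return FilterVerdict(key, ("homopolymer",))
    core_lo = max(win_start, key.pos - flank)
    core_hi = min(win_end, key.pos + flank)
    run_start = 0
    for i in range(1, len(seq) + 1):
        if i == len(seq) or seq[i] != seq[run_start]:
            if i - run_start >= run_len:
                g_start = win_start + run_start
                g_end = win_start + i - 1
                if g_start <= core_hi and g_end >= core_lo:
                    return FilterVerdict(key, ("homopolymer",))
            run_start = i
    return FilterVerdict(key)


def first6bp_filter(
    key: VariantKey,
    support: ReadSupportSummary | None,
    min_remaining: int = 1,
    min_remaining_frac: float = 0.0,
) -> FilterVerdict:
    """Fail unless enough alt reads mismatch outside the first 6 read bases."""
    if support is None:
        return FilterVerdict(key, ("first6bp",))
    remaining = support.n_alt_reads - support.n_alt_first6
    frac = remaining / support.n_alt_reads if support.n_alt_reads > 0 else 0.0
    if remaining < min_remaining or frac < min_remaining_frac:
        return FilterVerdict(key, ("first6bp",))
    return FilterVerdict(key)


def mismap_filter(key: VariantKey, flagged: bool) -> FilterVerdict:
    """Honor an externally computed mismapping flag (re-alignment step)."""
    return FilterVerdict(key, ("mismap_flag",) if flagged else ())


# ---------------------------------------------------------------------------
# filter chain

@dataclass
class FilterConfig:
    """Which filters are active and their thresholds.

    The default chain is the resource-light interval set plus the
    germline filter; the read-level filters (first6bp) and the external
    mismap flag activate only when their inputs are supplied.
    """

    germline: bool = True
    repeat: bool = True
    editing_site: bool = True
    splice_junction: bool = True
    homopolymer: bool = True
    first6bp: bool = False
    mismap: bool = False

    germline_min_dp: int = 5
    germline_max_vaf: float = 0.03  # strict: vaf >= this fails
    splice_window: int = 4
    homopolymer_run_len: int = 5
    homopolymer_flank: int = 4
    first6bp_min_remaining: int = 1
    first6bp_min_remaining_frac: float = 0.0


def _germline_with_config(
    key: VariantKey, ev: SiteEvidence | None, cfg: FilterConfig
) -> FilterVerdict:
    if ev is None:
        return FilterVerdict(key, ("germline_dp",))
    reasons = []
    if ev.dp_hq < cfg.germline_min_dp:
        reasons.append("germline_dp")
    if ev.vaf >= cfg.germline_max_vaf:
        reasons.append("germline_vaf")
    return FilterVerdict(key, tuple(reasons))


def apply_filter_chain(
    callset: Callset,
    evidence: EvidenceTable | None,
    annotations: AnnotationSet,
    config: FilterConfig | None = None,
    *,
    read_support: Mapping[VariantKey, ReadSupportSummary] | None = None,
    mismap_flags: Mapping[VariantKey, bool] | None = None,
) -> tuple[Callset, list[FilterVerdict]]:
    """Apply the configured filters to every variant in the callset.

    Returns the passing callset and one verdict per input variant.  The
    passing set equals the intersection of the per-filter passing sets;
    filter order cannot affect it because every filter always runs.
    """
    config = config or FilterConfig()
    if config.germline and evidence is None:
        raise ValueError("germline filter enabled but no evidence table supplied")
    required = {
        "repeat": (config.repeat, annotations.repeats),
        "editing_site": (config.editing_site, annotations.editing_sites),
        "splice_junction": (config.splice_junction, annotations.splice_junctions),
        "homopolymer": (config.homopolymer, annotations.reference),
    }
    for name, (enabled, resource) in required.items():
        if enabled and resource is None:
            raise ValueError(f"{name} filter enabled but its annotation track is not loaded")

    verdicts: list[FilterVerdict] = []
    passing = Callset(callset.caller_id, callset.sample_id)
    for call in sorted(callset, key=lambda c: c.key):
        key = call.key
        parts: list[FilterVerdict] = []
        if config.germline:
            assert evidence is not None
            parts.append(_germline_with_config(key, evidence.get(key, NORMAL_DNA), config))
        if config.repeat:
            parts.append(interval_filter(key, annotations.repeats, "repeat"))
        if config.editing_site:
            parts.append(editing_site_filter(key, annotations.editing_sites))
        if config.splice_junction:
            parts.append(
                splice_junction_filter(key, annotations.splice_junctions, config.splice_window)
            )
        if config.homopolymer:
            parts.append(
                homopolymer_filter(
                    key, annotations.reference, config.homopolymer_run_len,
                    config.homopolymer_flank,
                )
            )
        if config.first6bp:
            support = read_support.get(key) if read_support else None
            parts.append(
                first6bp_filter(
                    key, support, config.first6bp_min_remaining,
                    config.first6bp_min_remaining_frac,
                )
            )
        if config.mismap:
            flagged = bool(mismap_flags.get(key, False)) if mismap_flags else False
            parts.append(mismap_filter(key, flagged))
        verdict = _merge(key, *parts) if parts else FilterVerdict(key)
        verdicts.append(verdict)
        if verdict.passed:
            passing.add(call)
    return passing, verdicts


def verdicts_to_frame(verdicts: Sequence[FilterVerdict]) -> pd.DataFrame:
    """One row per (variant, reason); passing variants get reason 'PASS'."""
    rows = []
    for v in verdicts:
        base = {
            "sample": v.key.sample_id, "chrom": v.key.chrom, "pos": v.key.pos,
            "ref": v.key.ref, "alt": v.key.alt, "passed": int(v.passed),
        }
        if v.passed:
            rows.append({**base, "reason": "PASS"})
        else:
            for r in v.reasons:
                rows.append({**base, "reason": r})
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "pos", "ref", "alt", "passed", "reason"]
    )
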