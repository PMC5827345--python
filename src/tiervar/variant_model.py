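"""Core variant and evidence data model shared by every pipeline stage.

Coordinates are 1-based and fully closed throughout (VCF convention);
BED inputs are converted from 0-based half-open at load time.  Variant
identity is the full substitution key ``(sample, chrom, pos, ref, alt)``
so that a different alternate allele at the same site never matches.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

CALLER_IDS = ("snpir", "rvboost", "mutect2")

#: specimen labels used in evidence tables
TUMOR_RNA = "tumor_rna"
TUMOR_DNA = "tumor_dna"
NORMAL_DNA = "normal_dna"
SPECIMENS = (TUMOR_RNA, TUMOR_DNA, NORMAL_DNA)

_ALLELE_RE = re.compile(r"^[ACGTN]+$")


class ParseError(ValueError):
    """Record-level parse failure with file/line context."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized genomic substitution identity.

    Equality and hashing are defined over all five fields, so the same
    substitution in two samples is two distinct keys.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be nonempty")
        if self.ref != self.ref.upper() or self.alt != self.alt.upper():
            raise ValueError("alleles must be uppercase")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def substitution(self) -> str:
        """Substitution class as written on the reference strand, e.g. 'A>G'."""
        return f"{self.ref}>{self.alt}"

    def site(self) -> tuple[str, int, str, str]:
        """Sample-independent site identity (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SiteEvidence:
    """High-quality pileup summary for one specimen at one site.

    ``dp_hq``/``alt_hq`` count uniquely mapping reads (mapping quality
    >= 40).  ``vaf`` is ``alt_hq / dp_hq``, defined as 0 at zero depth.
    """

    specimen: str
    dp_hq: int
    alt_hq: int

    def __post_init__(self) -> None:
        if self.specimen not in SPECIMENS:
            raise ValueError(f"unknown specimen {self.specimen!r}")
        if not (0 <= self.alt_hq <= self.dp_hq):
            raise ValueError(
                f"require 0 <= alt_hq <= dp_hq, got alt_hq={self.alt_hq} dp_hq={self.dp_hq}"
            )

    @property
    def vaf(self) -> float:
        return self.alt_hq / self.dp_hq if self.dp_hq > 0 else 0.0


@dataclass(frozen=True)
class CallerCall:
    """One caller's call of one variant, with its reported tumor-RNA VAF."""

    key: VariantKey
    caller_id: str
    vaf: float | None = None
    dp: int | None = None

    def __post_init__(self) -> None:
        if self.caller_id not in CALLER_IDS:
            raise ValueError(f"caller_id must be one of {CALLER_IDS}, got {self.caller_id!r}")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")


class Callset:
    """All calls of one caller on one sample, keyed by :class:`VariantKey`."""

    def __init__(self, caller_id: str, sample_id: str) -> None:
        if caller_id not in CALLER_IDS:
            raise ValueError(f"caller_id must be one of {CALLER_IDS}, got {caller_id!r}")
        self.caller_id = caller_id
        self.sample_id = sample_id
        self.calls: dict[VariantKey, CallerCall] = {}

    def add(self, call: CallerCall) -> None:
        """Add a call; duplicates of the same key keep the max reported VAF."""
        prev = self.calls.get(call.key)
        if prev is None:
            self.calls[call.key] = call
        else:
            new_vaf = max(
                (v for v in (prev.vaf, call.vaf) if v is not None), default=None
            )
            keep = call if call.vaf == new_vaf else prev
            self.calls[call.key] = CallerCall(call.key, call.caller_id, new_vaf, keep.dp)

    def keys(self) -> set[VariantKey]:
        return set(self.calls)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[CallerCall]:
        return iter(self.calls.values())

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.calls

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Callset):
            return NotImplemented
        return (
            self.caller_id == other.caller_id
            and self.sample_id == other.sample_id
            and self.calls == other.calls
        )


def _trim_trailing(ref: str, alt: str) -> tuple[str, str]:
    # right-trim shared bases; position and the first base stay fixed
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return ref, alt


def normalize_record(
    chrom: str,
    pos: int,
    ref: str,
    alts: Iterable[str],
    sample_id: str,
    *,
    context: str = "",
) -> tuple[list[tuple[VariantKey, str]], int]:
    """Normalize one raw VCF-style record into per-alt variant keys.

    Multiallelic records are split, alleles uppercased, and shared
    trailing bases trimmed (position fixed).  Symbolic / non-ACGTN
    alternate alleles are dropped and counted, not errors.

    Returns ``(pairs, n_dropped)`` where each pair is ``(key, alt_as_given)``.

    Raises
    ------
    ParseError
        On malformed position or an empty allele, with ``context``
        (file/line) in the message.
    """
    try:
        pos = int(pos)
    except (TypeError, ValueError):
        raise ParseError(f"malformed position {pos!r} {context}") from None
    if pos < 1:
        raise ParseError(f"position must be >= 1, got {pos} {context}")
    if not ref:
        raise ParseError(f"empty REF allele {context}")
    ref = ref.upper()
    if not _ALLELE_RE.match(ref):
        # a symbolic REF makes every alt symbolic too
        return [], len(list(alts))
    out: list[tuple[VariantKey, str]] = []
    dropped = 0
    for raw_alt in alts:
        if raw_alt is None or raw_alt == "":
            raise ParseError(f"empty ALT allele {context}")
        alt = raw_alt.upper()
        if not _ALLELE_RE.match(alt) or alt == ref:
            dropped += 1
            continue
        t_ref, t_alt = _trim_trailing(ref, alt)
        if t_ref == t_alt:
            dropped += 1
            continue
        out.append((VariantKey(sample_id, chrom, pos, t_ref, t_alt), raw_alt))
    return out, dropped


def _record_vaf_dp(rec: pysam.VariantRecord) -> tuple[float | None, int | None]:
    vaf = None
    dp = None
    info = rec.info
    if "VAF" in info:
        v = info["VAF"]
        vaf = float(v[0] if isinstance(v, tuple) else v)
    elif "AF" in info:
        v = info["AF"]
        vaf = float(v[0] if isinstance(v, tuple) else v)
    if "DP" in info:
        dp = int(info["DP"])
    if vaf is None and rec.samples:
        sample = rec.samples[0]
        if "AF" in sample and sample["AF"] is not None:
            v = sample["AF"]
            vaf = float(v[0] if isinstance(v, tuple) else v)
    if vaf is not None:
        # VCF stores Float as binary32; round away the excess precision
        vaf = round(min(max(vaf, 0.0), 1.0), 6)
    return vaf, dp


def read_caller_vcf(
    path: str | Path,
    caller_id: str,
    sample_id: str,
    *,
    include_filtered: bool = False,
) -> Callset:
    """Load one caller's VCF into a :class:`Callset`.

    Only records with FILTER ``PASS`` or ``.`` are loaded unless
    ``include_filtered``; each upstream caller's own filtering is part
    of its published behaviour.  Duplicate keys after normalization are
    collapsed keeping the maximum reported VAF.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cs = Callset(caller_id, sample_id)
    n_loaded = n_dropped = n_filtered = 0
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf):
            filters = list(rec.filter.keys())
            if not include_filtered and filters and filters != ["PASS"]:
                n_filtered += 1
                continue
            pairs, dropped = normalize_record(
                rec.chrom,
                rec.pos,
                rec.ref,
                rec.alts or (),
                sample_id,
                context=f"({path.name} record {i + 1})",
            )
            n_dropped += dropped
            vaf, dp = _record_vaf_dp(rec)
            for key, _ in pairs:
                cs.add(CallerCall(key, caller_id, vaf, dp))
                n_loaded += 1
    logger.info(
        "%s: loaded %d calls (%d symbolic dropped, %d FILTERed skipped)",
        path.name,
        n_loaded,
        n_dropped,
        n_filtered,
    )
    return cs


def _vcf_header(contigs: Mapping[str, int | None], extra_lines: Iterable[str] = ()) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        if length:
            header.add_line(f"##contig=<ID={name},length={length}>")
        else:
            header.add_line(f"##contig=<ID={name}>")
    for line in extra_lines:
        header.add_line(line)
    return header


def write_callset_vcf(
    callset: Callset,
    path: str | Path,
    contigs: Mapping[str, int | None],
) -> None:
    """Write a callset as VCF 4.2 with INFO keys VAF and DP."""
    header = _vcf_header(
        contigs,
        [
            '##INFO=<ID=VAF,Number=1,Type=Float,Description="Caller-reported tumor RNA variant allele fraction">',
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Caller-reported read depth">',
            f"##tiervar_caller={callset.caller_id}",
            f"##tiervar_sample={callset.sample_id}",
        ],
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(callset, key=lambda c: c.key):
            rec = out.new_record(
                contig=call.key.chrom,
                start=call.key.pos - 1,
                alleles=(call.key.ref, call.key.alt),
            )
            rec.filter.add("PASS")
            if call.vaf is not None:
                rec.info["VAF"] = round(call.vaf, 6)
            if call.dp is not None:
                rec.info["DP"] = call.dp
            out.write(rec)


class EvidenceTable:
    """High-quality depth/alt counts per (variant key, specimen).

    Backed by a plain dict; missing (site, specimen) pairs are queryable
    as absent (``get`` returns None).
    """

    COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "specimen", "dp_hq", "alt_hq"]

    def __init__(self) -> None:
        self._data: dict[tuple[VariantKey, str], SiteEvidence] = {}

    def put(self, key: VariantKey, evidence: SiteEvidence) -> None:
        self._data[(key, evidence.specimen)] = evidence

    def get(self, key: VariantKey, specimen: str) -> SiteEvidence | None:
        return self._data.get((key, specimen))

    def keys(self) -> set[VariantKey]:
        return {k for k, _ in self._data}

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvidenceTable):
            return NotImplemented
        return self._data == other._data

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": key.sample_id,
                "chrom": key.chrom,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "specimen": specimen,
                "dp_hq": ev.dp_hq,
                "alt_hq": ev.alt_hq,
            }
            for (key, specimen), ev in sorted(
                self._data.items(), key=lambda kv: (kv[0][0], kv[0][1])
            )
        ]
        return pd.DataFrame(rows, columns=self.COLUMNS)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EvidenceTable":
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"evidence table missing columns: {sorted(missing)}")
        table = cls()
        for idx, row in df.iterrows():
            if row["alt_hq"] > row["dp_hq"]:
                raise ValueError(
                    f"row {idx}: alt_hq ({row['alt_hq']}) exceeds dp_hq ({row['dp_hq']})"
                )
            key = VariantKey(
                str(row["sample"]), str(row["chrom"]), int(row["pos"]),
                str(row["ref"]), str(row["alt"]),
            )
            table.put(key, SiteEvidence(str(row["specimen"]), int(row["dp_hq"]), int(row["alt_hq"])))
        return table

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EvidenceTable":
        df = pd.read_csv(path, sep="\t")
        return cls.from_frame(df)
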