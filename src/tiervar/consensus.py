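"""Caller-membership table and tiered consensus callsets.

Tier 1 is the intersection of all three RNA callers (SNPiR, RVBoost,
MuTect2).  Tier 2 supplements Tier 1 with variants called by both
MuTect2 and SNPiR; since Tier 1 is a subset of SNPiR∩MuTect2 the two
formulations coincide and the simpler one is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .variant_model import Callset, VariantKey, _vcf_header

import pysam

#: fixed caller column order: SNPiR, RVBoost, MuTect2
CALLER_ORDER = ("snpir", "rvboost", "mutect2")


@dataclass(frozen=True)
class MembershipRow:
    """Per-variant call vector (c_s, c_r, c_m) and per-caller VAFs."""

    called: tuple[bool, bool, bool]
    vafs: tuple[float | None, float | None, float | None]

    def __post_init__(self) -> None:
        if not any(self.called):
            raise ValueError("membership row must have at least one caller call")


class MembershipTable:
    """Rows keyed by :class:`VariantKey`, one per variant in the union."""

    def __init__(self, sample_id: str, rows: dict[VariantKey, MembershipRow]) -> None:
        self.sample_id = sample_id
        self.rows = rows

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.rows

    def caller_keys(self, caller_idx: int) -> set[VariantKey]:
        return {k for k, r in self.rows.items() if r.called[caller_idx]}

    def to_frame(self) -> pd.DataFrame:
        records = []
        for key in sorted(self.rows):
            row = self.rows[key]
            records.append(
                {
                    "sample": key.sample_id,
                    "chrom": key.chrom,
                    "pos": key.pos,
                    "ref": key.ref,
                    "alt": key.alt,
                    "c_s": int(row.called[0]),
                    "c_r": int(row.called[1]),
                    "c_m": int(row.called[2]),
                    "vaf_s": row.vafs[0],
                    "vaf_r": row.vafs[1],
                    "vaf_m": row.vafs[2],
                }
            )
        return pd.DataFrame(
            records,
            columns=["sample", "chrom", "pos", "ref", "alt",
                     "c_s", "c_r", "c_m", "vaf_s", "vaf_r", "vaf_m"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MembershipTable":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        rows: dict[VariantKey, MembershipRow] = {}
        sample_id = ""
        for _, r in df.iterrows():
            key = VariantKey(str(r["sample"]), str(r["chrom"]), int(r["pos"]),
                             str(r["ref"]), str(r["alt"]))
            sample_id = key.sample_id
            vafs = tuple(
                None if pd.isna(r[c]) else float(r[c]) for c in ("vaf_s", "vaf_r", "vaf_m")
            )
            rows[key] = MembershipRow(
                (bool(r["c_s"]), bool(r["c_r"]), bool(r["c_m"])), vafs  # type: ignore[arg-type]
            )
        return cls(sample_id, rows)


def build_membership(
    callset_s: Callset,
    callset_r: Callset,
    callset_m: Callset,
    *,
    include_indels: bool = False,
) -> MembershipTable:
    """Union the three callsets into a membership table.

    Indels are excluded by default; the downstream analysis is
    SNV-centric.  All three callsets must share a sample id.
    """
    triple = (callset_s, callset_r, callset_m)
    for cs, expected in zip(triple, CALLER_ORDER):
        if cs.caller_id != expected:
            raise ValueError(
                f"callsets must be passed in order {CALLER_ORDER}; got {cs.caller_id!r} "
                f"in the {expected!r} slot"
            )
    sample_ids = {cs.sample_id for cs in triple}
    if len(sample_ids) != 1:
        raise ValueError(f"callsets from different samples: {sorted(sample_ids)}")
    sample_id = sample_ids.pop()

    union: set[VariantKey] = set()
    for cs in triple:
        union |= cs.keys()
    rows: dict[VariantKey, MembershipRow] = {}
    for key in union:
        if not include_indels and not key.is_snv:
            continue
        called = tuple(key in cs for cs in triple)
        vafs = tuple(
            cs.calls[key].vaf if key in cs else None for cs in triple
        )
        rows[key] = MembershipRow(called, vafs)  # type: ignore[arg-type]
    return MembershipTable(sample_id, rows)


def tier1(mt: MembershipTable) -> set[VariantKey]:
    """Variants called by all three methods."""
    return {k for k, r in mt.rows.items() if all(r.called)}


def tier2(mt: MembershipTable) -> set[VariantKey]:
    """Tier 1 plus variants called by both MuTect2 and SNPiR.

    Implemented as c_s ∧ c_m directly; Tier 1 is a subset of that set.
    """
    return {k for k, r in mt.rows.items() if r.called[0] and r.called[2]}


def venn_counts(mt: MembershipTable) -> dict[str, int]:
    """Counts of the 7 regions of the three-caller Venn diagram.

    Region labels use the callers' initials: 's', 'r', 'm', 'sr', 'sm',
    'rm', 'srm' (exclusive regions).
    """
    labels = ("s", "r", "m")
    counts = {lab: 0 for lab in ("s", "r", "m", "sr", "sm", "rm", "srm")}
    for row in mt.rows.values():
        region = "".join(lab for lab, c in zip(labels, row.called) if c)
        counts[region] += 1
    return counts


def write_tier_vcf(
    mt: MembershipTable,
    keys: set[VariantKey],
    tier: int,
    path: str | Path,
    contigs: Mapping[str, int | None],
) -> None:
    """Write a tier callset as VCF with TIER and per-caller CALLED_* flags."""
    header = _vcf_header(
        contigs,
        [
            '##INFO=<ID=TIER,Number=1,Type=Integer,Description="Consensus tier (1 or 2)">',
            '##INFO=<ID=CALLED_S,Number=0,Type=Flag,Description="Called by SNPiR">',
            '##INFO=<ID=CALLED_R,Number=0,Type=Flag,Description="Called by RVBoost">',
            '##INFO=<ID=CALLED_M,Number=0,Type=Flag,Description="Called by MuTect2">',
            f"##tiervar_sample={mt.sample_id}",
        ],
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key in sorted(keys):
            row = mt.rows[key]
            rec = out.new_record(
                contig=key.chrom, start=key.pos - 1, alleles=(key.ref, key.alt)
            )
            rec.filter.add("PASS")
            rec.info["TIER"] = tier
            for flag, called in zip(("CALLED_S", "CALLED_R", "CALLED_M"), row.called):
                if called:
                    rec.info[flag] = True
            out.write(rec)
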