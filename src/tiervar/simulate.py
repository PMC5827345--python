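"""Synthetic multi-caller dataset generator.

Stands in for tumor/normal sequencing plus three upstream RNA callers:
it emits a DNA-derived truth set, three caller VCFs, a high-quality
pileup evidence table, annotation tracks and a reference FASTA, all
with the statistical structure the downstream analysis assumes —
expression-dependent RNA depth, Beta-distributed allele fractions with
a configurable DNA↔RNA Pearson correlation (Gaussian copula), per-
caller logistic detection models and false-positive rates, germline
contaminants, and recurrent zero-DNA-VAF A>G / C>T editing artifacts.

Simulation operates at the callset/evidence level; no reads or BAMs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .evaluate import TruthRecord, TruthSet, write_truth_vcf
from .filters import AnnotationSet, ReferenceSequence
from .variant_model import (
    CALLER_IDS,
    NORMAL_DNA,
    TUMOR_DNA,
    TUMOR_RNA,
    Callset,
    CallerCall,
    EvidenceTable,
    SiteEvidence,
    VariantKey,
    write_callset_vcf,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class CallerModel:
    """Detection and false-positive behaviour of one upstream caller.

    Detection probability is logistic(a + b*vaf + c*log1p(dp)) in the
    tumor RNA; ``detection_prob`` overrides it with a constant.
    ``fp_rate`` is the per-exonic-base probability of a spurious call.
    """

    fp_rate: float = 5e-4
    logit_a: float = -3.0
    logit_b_vaf: float = 6.0
    logit_c_logdp: float = 0.6
    detection_prob: float | None = None
    vaf_noise_sd: float = 0.03
    germline_detection: float = 0.9
    editing_detection: float = 0.8

    def detection(self, vaf: float, dp: int) -> float:
        if self.detection_prob is not None:
            return self.detection_prob
        x = self.logit_a + self.logit_b_vaf * vaf + self.logit_c_logdp * math.log1p(dp)
        return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class SpikeConfig:
    """Artificial spike-in experiment: attempted sites, their allele
    fractions, and the minimum RNA depth for a successful injection."""

    n_sites: int = 200
    vaf_range: tuple[float, float] = (0.05, 0.95)
    min_dp_for_success: int = 10


@dataclass
class SimConfig:
    """Full generative description of one synthetic sample.

    Defaults mirror the study conditions the analysis was built for:
    a few hundred somatic SNVs per sample, ~30% silent genes,
    log-normal expression mapped to negative-binomial RNA depth,
    Beta(2,5) DNA allele fractions correlated 0.74 with RNA, and three
    callers of decreasing false-positive rate (SNPiR > RVBoost >
    MuTect2).
    """

    seed: int = 0
    sample_id: str = "S1"
    contig: str = "chr1"

    # genome / gene structure
    n_genes: int = 200
    exon_len_range: tuple[int, int] = (200, 600)
    intron_len: int = 150
    intergenic_len: int = 300
    n_repeats: int = 20
    repeat_len_range: tuple[int, int] = (50, 200)
    n_homopolymers: int = 40
    homopolymer_len_range: tuple[int, int] = (6, 8)

    # expression -> RNA depth
    p_silent: float = 0.3
    expr_log_mean: float = math.log(30.0)
    expr_log_sd: float = 1.0
    nb_dispersion: float = 5.0
    nonexonic_dp_mean: float = 0.5
    intron_dp_frac: float = 0.15  # pre-mRNA coverage relative to the mature transcript
    dna_dp_mean: float = 80.0
    normal_dp_mean: float = 60.0

    # somatic truth
    n_somatic: int = 500
    frac_non_exonic: float = 0.25
    dna_vaf_alpha: float = 2.0
    dna_vaf_beta: float = 5.0
    rna_dna_vaf_correlation: float = 0.74
    cosmic_rate: float = 0.15

    # contaminants / artifacts
    n_germline: int = 25
    germline_vaf_mean: float = 0.5
    n_editing: int = 12
    editing_known_frac: float = 0.5
    editing_rna_vaf_range: tuple[float, float] = (0.2, 0.8)
    fp_call_vaf_alpha: float = 1.2
    fp_call_vaf_beta: float = 8.0
    fp_pileup_vaf: float = 0.04

    callers: dict[str, CallerModel] = field(
        default_factory=lambda: {
            "snpir": CallerModel(fp_rate=1e-3),
            "rvboost": CallerModel(fp_rate=6e-4),
            "mutect2": CallerModel(fp_rate=2.5e-4),
        }
    )
    spike: SpikeConfig | None = None

    def validate(self) -> None:
        for name in CALLER_IDS:
            if name not in self.callers:
                raise ValueError(f"caller model missing for {name!r}")
        n_exonic = self.n_genes * 2 * self.exon_len_range[0]
        demand = self.n_somatic + self.n_germline + self.n_editing + (
            self.spike.n_sites if self.spike else 0
        )
        if demand > n_exonic // 2:
            raise ValueError(
                f"infeasible config: {demand} variant sites requested but only "
                f"~{n_exonic} exonic bases guaranteed"
            )
        if not (0.0 <= self.rna_dna_vaf_correlation < 1.0):
            raise ValueError("rna_dna_vaf_correlation must be in [0, 1)")


@lru_cache(maxsize=32)
def _calibrated_copula_rho(target_r: float, alpha: float, beta: float) -> float:
    """Normal-copula correlation producing Pearson `target_r` on the
    Beta-transformed margins.

    The monotone transform attenuates Pearson correlation slightly, so
    the latent rho is found by inverting an empirically tabulated
    attenuation curve (common random numbers, fixed internal seed —
    independent of the simulation seed, hence deterministic).
    """
    if target_r == 0.0:
        return 0.0
    rng = np.random.default_rng(202404)
    z = rng.standard_normal((2, 50_000))
    x = sps.beta.ppf(sps.norm.cdf(z[0]), alpha, beta)
    rhos = np.linspace(0.01, 0.999, 30)
    attained = []
    for rho in rhos:
        z2 = rho * z[0] + math.sqrt(1.0 - rho * rho) * z[1]
        y = sps.beta.ppf(sps.norm.cdf(z2), alpha, beta)
        attained.append(np.corrcoef(x, y)[0, 1])
    return float(np.interp(target_r, attained, rhos))


def _nb_draw(rng: np.random.Generator, mu: float, r: float, size: int | None = None):
    """Negative-binomial with mean mu and dispersion r (variance mu + mu^2/r)."""
    if mu <= 0:
        return 0 if size is None else np.zeros(size, dtype=int)
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=size)


@dataclass
class Gene:
    name: str
    exons: list[tuple[int, int]]           # 1-based closed
    intron: tuple[int, int]                # 1-based closed
    abundance: float                       # expected RNA depth; 0 = silent


@dataclass
class SpikeReport:
    attempted: int
    succeeded: int
    attempted_keys: list[VariantKey]
    succeeded_keys: list[VariantKey]
    failed_keys: list[VariantKey]


@dataclass
class SimulatedDataset:
    """In-memory result of :func:`simulate_dataset`, with file writers."""

    config: SimConfig
    sample_id: str
    genome: dict[str, str]
    genes: list[Gene]
    exons: dict[str, list[tuple[int, int, str]]]
    junctions: list[tuple[str, int, int]]
    repeats: list[tuple[str, int, int]]            # 1-based closed
    editing_annotation: list[tuple[str, int]]      # known editing positions
    truth: TruthSet
    callsets: dict[str, Callset]
    evidence: EvidenceTable
    germline_keys: list[VariantKey]
    editing_keys: list[VariantKey]
    fp_keys: dict[str, list[VariantKey]]
    spike_report: SpikeReport | None = None

    @property
    def contigs(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def annotations(self) -> AnnotationSet:
        """Build the in-memory annotation bundle for the filter chain."""
        from intervaltree import IntervalTree

        repeats: dict[str, IntervalTree] = {}
        for chrom, start, end in self.repeats:
            repeats.setdefault(chrom, IntervalTree()).addi(start, end + 1)
        editing: dict[str, set[int]] = {}
        for chrom, pos in self.editing_annotation:
            editing.setdefault(chrom, set()).add(pos)
        return AnnotationSet(
            repeats=repeats,
            editing_sites=editing,
            splice_junctions=list(self.junctions),
            exons={c: sorted(t) for c, t in self.exons.items()},
            reference=ReferenceSequence(self.genome),
        )

    # -- file output ------------------------------------------------------

    def write(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}

        fasta = outdir / "reference.fa"
        with open(fasta, "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        paths["reference"] = str(fasta)

        for caller, cs in sorted(self.callsets.items()):
            p = outdir / f"calls_{caller}.vcf"
            write_callset_vcf(cs, p, self.contigs)
            paths[f"calls_{caller}"] = str(p)

        truth_path = outdir / "truth.vcf"
        write_truth_vcf(self.truth, truth_path, self.contigs, self.sample_id)
        paths["truth"] = str(truth_path)

        ev_path = outdir / "evidence.tsv"
        self.evidence.to_tsv(ev_path)
        paths["evidence"] = str(ev_path)

        rep_path = outdir / "repeats.bed"
        with open(rep_path, "w") as fh:
            for chrom, start, end in sorted(self.repeats):
                fh.write(f"{chrom}\t{start - 1}\t{end}\trepeat\n")
        paths["repeats"] = str(rep_path)

        ed_path = outdir / "editing_sites.bed"
        with open(ed_path, "w") as fh:
            for chrom, pos in sorted(self.editing_annotation):
                fh.write(f"{chrom}\t{pos - 1}\t{pos}\tediting\n")
        paths["editing_sites"] = str(ed_path)

        ex_path = outdir / "exons.bed"
        with open(ex_path, "w") as fh:
            for chrom in sorted(self.exons):
                for start, end, gene in sorted(self.exons[chrom]):
                    fh.write(f"{chrom}\t{start - 1}\t{end}\t{gene}\n")
        paths["exons"] = str(ex_path)

        jn_path = outdir / "junctions.tsv"
        with open(jn_path, "w") as fh:
            fh.write("contig\tintron_start\tintron_end\n")
            for chrom, istart, iend in sorted(self.junctions):
                fh.write(f"{chrom}\t{istart}\t{iend}\n")
        paths["junctions"] = str(jn_path)

        manifest = self.manifest()
        man_path = outdir / "manifest.json"
        with open(man_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["manifest"] = str(man_path)
        return paths

    def manifest(self) -> dict:
        def keylist(keys) -> list[str]:
            return [f"{k.chrom}:{k.pos}:{k.ref}:{k.alt}" for k in sorted(keys)]

        cfg = dataclasses.asdict(self.config)
        cfg["callers"] = {k: dataclasses.asdict(v) for k, v in self.config.callers.items()}
        return {
            "config": cfg,
            "sample_id": self.sample_id,
            "n_truth": len(self.truth),
            "truth_keys": keylist(self.truth.records),
            "germline_keys": keylist(self.germline_keys),
            "editing_keys": keylist(self.editing_keys),
            "fp_keys": {c: keylist(v) for c, v in sorted(self.fp_keys.items())},
            "callset_sizes": {c: len(cs) for c, cs in sorted(self.callsets.items())},
            "spike": None
            if self.spike_report is None
            else {
                "attempted": self.spike_report.attempted,
                "succeeded": self.spike_report.succeeded,
                "succeeded_keys": keylist(self.spike_report.succeeded_keys),
            },
        }


def _build_genome(cfg: SimConfig, rng: np.random.Generator):
    genes: list[Gene] = []
    exon_tracks: list[tuple[int, int, str]] = []
    junctions: list[tuple[str, int, int]] = []
    seq_parts: list[np.ndarray] = []
    pos = 1
    for gi in range(cfg.n_genes):
        pos += cfg.intergenic_len
        e1 = int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
        e2 = int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
        exon1 = (pos, pos + e1 - 1)
        intron = (exon1[1] + 1, exon1[1] + cfg.intron_len)
        exon2 = (intron[1] + 1, intron[1] + e2)
        name = f"g{gi:04d}"
        silent = rng.random() < cfg.p_silent
        abundance = 0.0 if silent else float(
            np.exp(rng.normal(cfg.expr_log_mean, cfg.expr_log_sd))
        )
        genes.append(Gene(name, [exon1, exon2], intron, abundance))
        exon_tracks.extend([(exon1[0], exon1[1], name), (exon2[0], exon2[1], name)])
        junctions.append((cfg.contig, intron[0], intron[1]))
        pos = exon2[1] + 1
    genome_len = pos - 1 + cfg.intergenic_len
    base_idx = rng.integers(0, 4, size=genome_len)
    # plant homopolymer runs
    for _ in range(cfg.n_homopolymers):
        run = int(rng.integers(cfg.homopolymer_len_range[0], cfg.homopolymer_len_range[1] + 1))
        start0 = int(rng.integers(0, genome_len - run))
        base_idx[start0 : start0 + run] = rng.integers(0, 4)
    seq = "".join(_BASES[i] for i in base_idx)
    repeats = []
    for _ in range(cfg.n_repeats):
        length = int(rng.integers(cfg.repeat_len_range[0], cfg.repeat_len_range[1] + 1))
        start = int(rng.integers(1, genome_len - length))
        repeats.append((cfg.contig, start, start + length - 1))
    return genes, {cfg.contig: [(s, e, n) for s, e, n in exon_tracks]}, junctions, repeats, {
        cfg.contig: seq
    }


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate one full synthetic sample.

    Identical configs (including seed) produce identical in-memory
    objects and byte-identical files from :meth:`SimulatedDataset.write`.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes, exons, junctions, repeats, genome = _build_genome(cfg, rng)
    contig = cfg.contig
    seq = genome[contig]
    genome_len = len(seq)

    # exonic coordinate pool with gene index
    exonic_pos: list[int] = []
    exonic_gene: list[int] = []
    for gi, gene in enumerate(genes):
        for start, end in gene.exons:
            exonic_pos.extend(range(start, end + 1))
            exonic_gene.extend([gi] * (end - start + 1))
    exonic_pos_arr = np.asarray(exonic_pos)
    exonic_gene_arr = np.asarray(exonic_gene)
    exonic_set = set(exonic_pos)
    nonexonic_pos_arr = np.asarray(
        [p for p in range(1, genome_len + 1) if p not in exonic_set]
    )
    intron_gene: dict[int, int] = {}
    for gi, gene in enumerate(genes):
        for p in range(gene.intron[0], gene.intron[1] + 1):
            intron_gene[p] = gi

    used = np.zeros(len(exonic_pos_arr), dtype=bool)

    def draw_exonic(n: int, base_filter: str | None = None) -> np.ndarray:
        """Sample n unused exonic pool indices, optionally requiring a ref base."""
        avail = np.flatnonzero(~used)
        if base_filter is not None:
            avail = avail[
                np.asarray([seq[exonic_pos_arr[i] - 1] in base_filter for i in avail])
            ]
        if len(avail) < n:
            raise ValueError("infeasible config: exonic site pool exhausted")
        chosen = rng.choice(avail, size=n, replace=False)
        used[chosen] = True
        return chosen

    def alt_base(ref: str) -> str:
        choices = [b for b in _BASES if b != ref]
        return choices[int(rng.integers(0, 3))]

    def rna_dp_for(gene_idx: int) -> int:
        return int(_nb_draw(rng, genes[gene_idx].abundance, cfg.nb_dispersion))

    evidence = EvidenceTable()
    callsets = {c: Callset(c, cfg.sample_id) for c in CALLER_IDS}

    def add_evidence(key: VariantKey, rna_dp: int, rna_vaf: float,
                     dna_dp: int, dna_vaf: float, nor_dp: int, nor_vaf: float) -> SiteEvidence:
        rna_alt = int(rng.binomial(rna_dp, min(rna_vaf, 1.0))) if rna_dp else 0
        dna_alt = int(rng.binomial(dna_dp, min(dna_vaf, 1.0))) if dna_dp else 0
        nor_alt = int(rng.binomial(nor_dp, min(nor_vaf, 1.0))) if nor_dp else 0
        rna_ev = SiteEvidence(TUMOR_RNA, rna_dp, rna_alt)
        evidence.put(key, rna_ev)
        evidence.put(key, SiteEvidence(TUMOR_DNA, dna_dp, dna_alt))
        evidence.put(key, SiteEvidence(NORMAL_DNA, nor_dp, nor_alt))
        return rna_ev

    def caller_calls(key: VariantKey, vaf: float, dp: int,
                     probs: dict[str, float] | None = None) -> None:
        for caller in CALLER_IDS:
            model = cfg.callers[caller]
            p = probs[caller] if probs is not None else model.detection(vaf, dp)
            if rng.random() < p:
                # callers report finite precision; quantize so VCF
                # round-trips are exact
                reported = round(
                    float(np.clip(vaf + rng.normal(0.0, model.vaf_noise_sd), 0.0, 1.0)), 6
                )
                callsets[caller].add(CallerCall(key, caller, reported, dp))

    # ---- somatic truth --------------------------------------------------
    n_non = int(round(cfg.frac_non_exonic * cfg.n_somatic))
    n_exo = cfg.n_somatic - n_non
    rho = _calibrated_copula_rho(
        cfg.rna_dna_vaf_correlation, cfg.dna_vaf_alpha, cfg.dna_vaf_beta
    )
    z1 = rng.standard_normal(cfg.n_somatic)
    z2 = rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(cfg.n_somatic)
    dna_vafs = sps.beta.ppf(sps.norm.cdf(z1), cfg.dna_vaf_alpha, cfg.dna_vaf_beta)
    rna_vafs = sps.beta.ppf(sps.norm.cdf(z2), cfg.dna_vaf_alpha, cfg.dna_vaf_beta)

    truth_records: dict[VariantKey, TruthRecord] = {}
    exo_idx = draw_exonic(n_exo)
    if n_non > len(nonexonic_pos_arr):
        raise ValueError("infeasible config: not enough non-exonic positions")
    non_pos = rng.choice(nonexonic_pos_arr, size=n_non, replace=False) if n_non else np.array([], dtype=int)

    for i in range(cfg.n_somatic):
        if i < n_exo:
            pos = int(exonic_pos_arr[exo_idx[i]])
            gene_idx = int(exonic_gene_arr[exo_idx[i]])
            region = "exonic"
            rna_dp = rna_dp_for(gene_idx)
        else:
            pos = int(non_pos[i - n_exo])
            region = "non_exonic"
            gi = intron_gene.get(pos)
            mu = (
                genes[gi].abundance * cfg.intron_dp_frac
                if gi is not None
                else cfg.nonexonic_dp_mean
            )
            rna_dp = int(_nb_draw(rng, mu, cfg.nb_dispersion))
        ref = seq[pos - 1]
        key = VariantKey(cfg.sample_id, contig, pos, ref, alt_base(ref))
        dvaf, rvaf = round(float(dna_vafs[i]), 6), round(float(rna_vafs[i]), 6)
        dna_dp = int(_nb_draw(rng, cfg.dna_dp_mean, cfg.nb_dispersion))
        nor_dp = int(_nb_draw(rng, cfg.normal_dp_mean, cfg.nb_dispersion))
        add_evidence(key, rna_dp, rvaf, dna_dp, dvaf, nor_dp, 0.0)
        truth_records[key] = TruthRecord(
            region_class=region,
            expression_dp=rna_dp,
            dna_vaf=dvaf,
            rna_vaf=rvaf,
            cosmic_flag=bool(rng.random() < cfg.cosmic_rate),
        )
        if region == "exonic" and rna_dp > 0:
            caller_calls(key, rvaf, rna_dp)

    # ---- germline contaminants -----------------------------------------
    germline_keys: list[VariantKey] = []
    if cfg.n_germline:
        g_idx = draw_exonic(cfg.n_germline)
        for j in range(cfg.n_germline):
            pos = int(exonic_pos_arr[g_idx[j]])
            gene_idx = int(exonic_gene_arr[g_idx[j]])
            ref = seq[pos - 1]
            key = VariantKey(cfg.sample_id, contig, pos, ref, alt_base(ref))
            gvaf = float(np.clip(rng.normal(cfg.germline_vaf_mean, 0.05), 0.05, 0.95))
            rna_dp = rna_dp_for(gene_idx)
            dna_dp = int(_nb_draw(rng, cfg.dna_dp_mean, cfg.nb_dispersion))
            nor_dp = int(_nb_draw(rng, cfg.normal_dp_mean, cfg.nb_dispersion))
            add_evidence(key, rna_dp, gvaf, dna_dp, gvaf, nor_dp, gvaf)
            germline_keys.append(key)
            if rna_dp > 0:
                probs = {c: cfg.callers[c].germline_detection for c in CALLER_IDS}
                caller_calls(key, gvaf, rna_dp, probs)

    # ---- RNA-editing artifacts (dna_vaf = 0, deep everywhere) ----------
    editing_keys: list[VariantKey] = []
    editing_annotation: list[tuple[str, int]] = []
    if cfg.n_editing:
        e_idx = draw_exonic(cfg.n_editing, base_filter="AC")
        n_known = int(round(cfg.editing_known_frac * cfg.n_editing))
        for j in range(cfg.n_editing):
            pos = int(exonic_pos_arr[e_idx[j]])
            ref = seq[pos - 1]
            alt = "G" if ref == "A" else "T"
            key = VariantKey(cfg.sample_id, contig, pos, ref, alt)
            evaf = float(rng.uniform(*cfg.editing_rna_vaf_range))
            # deep coverage in all three specimens is what defines the class
            rna_dp = int(_nb_draw(rng, max(cfg.dna_dp_mean, 50.0), cfg.nb_dispersion))
            dna_dp = int(_nb_draw(rng, cfg.dna_dp_mean, cfg.nb_dispersion))
            nor_dp = int(_nb_draw(rng, cfg.normal_dp_mean, cfg.nb_dispersion))
            add_evidence(key, rna_dp, evaf, dna_dp, 0.0, nor_dp, 0.0)
            editing_keys.append(key)
            if j < n_known:
                editing_annotation.append((contig, pos))
            probs = {c: cfg.callers[c].editing_detection for c in CALLER_IDS}
            caller_calls(key, evaf, rna_dp, probs)

    # ---- per-caller false positives ------------------------------------
    fp_keys: dict[str, list[VariantKey]] = {c: [] for c in CALLER_IDS}
    for caller in CALLER_IDS:
        model = cfg.callers[caller]
        n_fp = int(rng.poisson(model.fp_rate * len(exonic_pos_arr)))
        if n_fp == 0:
            continue
        f_idx = draw_exonic(n_fp)
        for j in range(n_fp):
            pos = int(exonic_pos_arr[f_idx[j]])
            gene_idx = int(exonic_gene_arr[f_idx[j]])
            ref = seq[pos - 1]
            key = VariantKey(cfg.sample_id, contig, pos, ref, alt_base(ref))
            rna_dp = rna_dp_for(gene_idx)
            dna_dp = int(_nb_draw(rng, cfg.dna_dp_mean, cfg.nb_dispersion))
            nor_dp = int(_nb_draw(rng, cfg.normal_dp_mean, cfg.nb_dispersion))
            add_evidence(key, rna_dp, cfg.fp_pileup_vaf, dna_dp, 0.0, nor_dp, 0.0)
            reported = round(
                float(
                    np.clip(
                        rng.beta(cfg.fp_call_vaf_alpha, cfg.fp_call_vaf_beta), 0.001, 1.0
                    )
                ),
                6,
            )
            callsets[caller].add(CallerCall(key, caller, reported, rna_dp))
            fp_keys[caller].append(key)

    dataset = SimulatedDataset(
        config=cfg,
        sample_id=cfg.sample_id,
        genome=genome,
        genes=genes,
        exons=exons,
        junctions=junctions,
        repeats=repeats,
        editing_annotation=editing_annotation,
        truth=TruthSet(truth_records),
        callsets=callsets,
        evidence=evidence,
        germline_keys=germline_keys,
        editing_keys=editing_keys,
        fp_keys=fp_keys,
    )
    if cfg.spike is not None:
        spike_in(dataset, cfg.spike, rng)
    return dataset


def spike_in(
    dataset: SimulatedDataset,
    spike: SpikeConfig,
    rng: np.random.Generator | int | None = None,
) -> SpikeReport:
    """Inject artificial variants at random coding positions.

    An attempted site succeeds only when its RNA depth reaches
    ``min_dp_for_success`` (injection into a transcript needs reads to
    carry the allele).  Succeeded variants are added *in place* to the
    truth set, the evidence table, and the caller inputs according to
    each caller's detection model; the report lists attempted vs
    succeeded.
    """
    cfg = dataset.config
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(0 if rng is None else rng)
    seq = dataset.genome[cfg.contig]
    taken = {k.pos for k in dataset.evidence.keys()}
    pool = []
    gene_of: dict[int, int] = {}
    for gi, gene in enumerate(dataset.genes):
        for start, end in gene.exons:
            for p in range(start, end + 1):
                if p not in taken:
                    pool.append(p)
                    gene_of[p] = gi
    if spike.n_sites > len(pool):
        raise ValueError("infeasible spike config: not enough free coding positions")
    positions = rng.choice(np.asarray(pool), size=spike.n_sites, replace=False)

    attempted, succeeded, failed = [], [], []
    for pos in (int(p) for p in positions):
        ref = seq[pos - 1]
        alts = [b for b in _BASES if b != ref]
        key = VariantKey(cfg.sample_id, cfg.contig, pos, ref, alts[int(rng.integers(0, 3))])
        attempted.append(key)
        vaf = round(float(rng.uniform(*spike.vaf_range)), 6)
        gene = dataset.genes[gene_of[pos]]
        rna_dp = int(_nb_draw(rng, gene.abundance, cfg.nb_dispersion))
        if rna_dp < spike.min_dp_for_success:
            failed.append(key)
            continue
        succeeded.append(key)
        dna_dp = int(_nb_draw(rng, cfg.dna_dp_mean, cfg.nb_dispersion))
        nor_dp = int(_nb_draw(rng, cfg.normal_dp_mean, cfg.nb_dispersion))
        rna_alt = int(rng.binomial(rna_dp, vaf))
        dataset.evidence.put(key, SiteEvidence(TUMOR_RNA, rna_dp, rna_alt))
        dataset.evidence.put(
            key, SiteEvidence(TUMOR_DNA, dna_dp, int(rng.binomial(dna_dp, vaf)))
        )
        dataset.evidence.put(key, SiteEvidence(NORMAL_DNA, nor_dp, 0))
        dataset.truth.records[key] = TruthRecord(
            region_class="exonic",
            expression_dp=rna_dp,
            dna_vaf=vaf,
            rna_vaf=vaf,
        )
        for caller in CALLER_IDS:
            model = cfg.callers[caller]
            if rng.random() < model.detection(vaf, rna_dp):
                reported = round(
                    float(np.clip(vaf + rng.normal(0.0, model.vaf_noise_sd), 0.0, 1.0)), 6
                )
                dataset.callsets[caller].add(CallerCall(key, caller, reported, rna_dp))

    report = SpikeReport(
        attempted=len(attempted),
        succeeded=len(succeeded),
        attempted_keys=attempted,
        succeeded_keys=succeeded,
        failed_keys=failed,
    )
    dataset.spike_report = report
    return report
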