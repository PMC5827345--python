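# tiervar

Tiered consensus integration, hard filtering, weighting and evaluation of
**somatic variant calls made from RNA-seq**.

Calling somatic mutations from tumor RNA instead of tumor DNA is attractive —
it restricts discovery to expressed genes and doubles as orthogonal validation
of DNA calls — but single RNA callers are imprecise: RNA editing, splice
artifacts, allele-specific expression and low expression all generate false
calls or mask true ones. `tiervar` implements the integration layer of a
three-caller workflow (SNPiR, RVBoost, MuTect2 run upstream on tumor RNA):

* **Consensus tiers.** With per-caller call indicators `c_s, c_r, c_m`,
  **Tier 1** = `c_s ∧ c_r ∧ c_m` (highest precision) and
  **Tier 2** = Tier 1 ∪ (`c_s ∧ c_m`) (higher recall at moderate precision).
* **Hard filters.** A germline filter on the matched normal DNA — accept only
  sites with high-quality depth `DP ≥ 5` and `VAF < 3%` in uniquely mapping
  reads (MAPQ ≥ 40) — plus annotation/sequence filters (repeats, known
  RNA-editing sites, intronic positions within 4 bp of a splice junction,
  homopolymer runs, alt support confined to the first 6 read bases, external
  mismap flags). Filters fail closed and every removal carries a
  machine-readable reason.
* **Weighted combination.** Caller weights `w_i = v_i / Σ_j v_j` with `v_i`
  on the grid `{0, 0.1, …, 1}`; scores `s = Σ w_i c_i` (binary) or
  `s = Σ w_i (vaf_i − mean_i)/sd_i` (z-scored VAF); the decision threshold is
  chosen to minimize the **evalue = FP + FN** (threshold searched over
  achievable scores, or over `[−3, 3]` in the VAF mode), with precision,
  recall and AUPRC reported per weight vector.
* **Evaluation & triage.** Concordance against a DNA truth set (variants
  supported by ≥ 2 DNA callers) with the *callable* restriction (RNA depth
  ≥ 10) for false negatives; priority-ordered explanations for missed and
  discordant variants; detection of putative RNA-editing sites (A>G / C>T
  with zero DNA VAF despite deep coverage in all three specimens); RNA↔DNA
  VAF Pearson correlation by depth stratum; generic two-callset comparison.
* **Synthetic data.** A callset-level simulator with expression-dependent
  negative-binomial RNA depth, a Gaussian-copula DNA↔RNA VAF correlation
  (target Pearson r, default 0.74), per-caller logistic detection and
  false-positive models, germline contaminants, recurrent editing artifacts,
  and a spike-in experiment — so the whole pipeline is testable end to end
  without sequencing data.

## Worked example

Everything below is reproducible (fixed seeds, byte-identical outputs):

```sh
tiervar simulate --seed 7 --out demo/sim
tiervar integrate --snpir demo/sim/calls_snpir.vcf \
    --rvboost demo/sim/calls_rvboost.vcf --mutect2 demo/sim/calls_mutect2.vcf \
    --sample S1 --out demo/int
# -> union 557, tier1 106, tier2 143
tiervar filter --calls demo/int/tier1.vcf --sample S1 \
    --evidence demo/sim/evidence.tsv --repeats demo/sim/repeats.bed \
    --editing demo/sim/editing_sites.bed --junctions demo/sim/junctions.tsv \
    --reference demo/sim/reference.fa --out demo/filt
# -> 89 of 106 calls pass
tiervar evaluate --calls demo/filt/passing.vcf --truth demo/sim/truth.vcf \
    --evidence demo/sim/evidence.tsv --sample S1 --out demo/eval
```

prints

```
calls: 89
truth (full): 500
truth (callable): 231
concordant (TP): 86
discordant (FP): 3
missed callable (FN): 152
precision: 96.6%
recall (callable): 36.1%
FN rate: 63.9%
evalue: 155
vaf correlation [dp_gt10_all]: r=0.749 n=223
```

Reading: of 106 Tier 1 consensus calls, 17 are removed by the hard filters
(germline evidence, repeats, known editing sites, …). Of the 89 survivors, 86
are present in the DNA truth set (precision 96.6%). Recall is judged against
the *callable* truth only — the 231 truth variants with RNA depth ≥ 10 —
because unexpressed mutations are invisible to any RNA caller. In the
deepest stratum (DP > 10 in tumor RNA, tumor DNA and normal DNA) the RNA and
DNA allele fractions correlate strongly (r = 0.749), the regime in which an
RNA VAF can stand in for the DNA VAF.

The `weights` and `triage` subcommands sweep the caller-weight grid and
explain missed/discordant calls; the same functionality is available as a
library (`tiervar.consensus`, `tiervar.filters`, `tiervar.weighting`,
`tiervar.evaluate`, `tiervar.simulate`).

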