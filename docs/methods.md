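# Methods

## Variant identity and coordinates

All matching uses the full substitution key `(sample, chrom, pos, ref, alt)`.
A caller reporting a *different* alternate allele at the same position counts
as "not called" — the conservative choice for concordance counting.
Coordinates are 1-based fully closed (VCF convention); BED inputs are
converted from 0-based half-open on read. VCF records are normalized per alt
allele: multiallelic split, alleles uppercased, shared trailing bases trimmed
with the position and first base fixed. Symbolic alleles are dropped (and
counted), malformed records are hard errors with file/line context. Indels
are parsed but excluded from consensus and evaluation by default
(`include_indels=True` to keep them); the analysis is SNV-centric.

Only records with FILTER `PASS` or `.` are loaded by default: each upstream
caller's own filtering is part of its published behaviour.

## Consensus tiers

Tier 1 is the three-way intersection; Tier 2 is implemented directly as
`c_s ∧ c_m`, which provably equals Tier 1 ∪ (SNPiR ∩ MuTect2) since Tier 1 is
a subset of that pair intersection (a unit test asserts the equivalence).
Tier 2 is deliberately asymmetric in RVBoost vs SNPiR.

## Hard filters

* **Germline filter.** Pass iff normal-DNA `dp_hq ≥ 5` and `vaf < 0.03`,
  where `dp_hq`/`alt_hq` count uniquely mapping reads, operationalized as
  mapping quality ≥ 40. Boundary semantics are exact: depth 5 passes the
  depth clause, VAF exactly 0.03 fails the VAF clause. Missing normal
  evidence is treated as zero depth (fail closed): without germline coverage
  a somatic assignment cannot be supported. The VAF used is pileup-derived
  (the evidence table), not caller-reported.
* **Interval filters** (repeats, known editing sites): fail iff the position
  lies in any interval of the track; an absent contig means no overlap.
* **Splice-junction filter**: fail iff the position is intronic and among the
  first `window` (default 4) intronic bases at either intron boundary.
  Exonic positions adjacent to a junction pass — the artifact the filter
  targets is intronic misalignment.
* **Homopolymer filter**: fail iff a mononucleotide run of length ≥ 5
  (default) overlaps `pos ± 4`. Run length and flank are unspecified
  upstream conventions; both are exposed in `FilterConfig`. An unavailable
  sequence window fails closed with a logged warning.
* **First-6-bp filter**: fail unless at least `min_remaining` (default 1)
  alt reads mismatch outside the first 6 bases of the read. Raising the
  threshold is monotone (never converts fail to pass).
* **Mismap flag**: the re-alignment (PBLAT-style) check is not re-implemented;
  an externally computed per-variant boolean is honored when supplied.

Every filter always runs when enabled, so the passing set is the
intersection of per-filter passing sets and is order-independent and
idempotent. Each removed variant carries at least one reason from a fixed
vocabulary. The default chain is the resource-light set (germline, repeat,
editing-site, splice-junction, homopolymer); the read-level filters activate
only when their inputs exist. Enabling a filter whose annotation track is
not loaded is a fatal configuration error, distinct from a loaded-but-empty
track.

## Weighting and evalue optimization

Raw values `v_i ∈ {0, 0.1, …, 1.0}` give 11³ − 1 = 1330 usable triples;
normalization `w_i = v_i / Σv_j` collapses these to fewer distinct weight
vectors (scaling all `v` leaves everything unchanged), and the sweep keeps
the raw triples as provenance per collapsed row. Scoring:

* binary: `s = Σ w_i c_i ∈ [0, 1]`;
* VAF mode: `s = Σ w_i (vaf_i − mean_i)/sd_i`. A variant a caller did not
  call contributes the z-score of VAF 0 — this keeps every variant in the
  union scoreable. Caller VAF means/sds are computed by default from each
  caller's reported VAFs on the variants it called within the evaluation
  universe (`population="union_zero"` imputes zeros instead). A zero sd for
  a positively weighted caller is an error.

The decision rule is `call := s ≥ threshold`. Binary mode searches the
finite set of achievable scores; VAF mode a fixed 0.01-step grid on
[−3, 3] (the interval is prescribed, the step is ours). Minimal-evalue ties
break to the smallest threshold. The evaluation universe defaults to the
union of all called variants and the truth set, so truth variants called by
nobody are false negatives at any positive threshold; with equal weights and
a threshold just below 1 the rule reproduces Tier 1 exactly, which anchors
the grid to the consensus analysis. AUPRC uses right-constant step
integration (the average-precision form), not trapezoids, to avoid
optimistic interpolation.

## Evaluation and triage

True and false positives are counted against the full truth set; false
negatives against the *callable* truth — truth variants whose tumor-RNA
high-quality depth is ≥ 10 ("below 10" removed). These asymmetric
denominators reproduce the published contingency construction; restricting
the callable truth can only lower FN and never changes TP or FP.

Triage assigns each variant to exactly one category by a fixed priority
order. Missed truth variants: not expressed (`DP = 0`) → low expression
(`DP ≤ 10`) → non-exonic → low DNA VAF (< 0.20) → low RNA VAF (< 0.20) →
filtered (a caller called it, a hard filter removed it) → uncalled.
Discordant calls: RNA `DP < 10` → DNA `DP < 10` → DNA `VAF > 0` →
editing candidate → unexplained. An editing candidate has zero DNA VAF,
depth ≥ 10 in tumor RNA, tumor DNA and normal DNA, and substitution class
A>G or C>T *as written on the reference strand* — no strand complementing is
attempted, so the same biological event on a minus-strand gene appears as
T>C/G>A and lands in "unexplained". Candidates are aggregated by site
across samples with recurrence counts.

Report percentages are rounded half-up at the printed precision (e.g.
68/125 → 54.40%). VAF correlations are Pearson r per depth stratum — the
four standard strata range from any coverage to DP > 10 in all three
specimens — flagged undefined below n = 3 or at zero variance. A plain
pooled-variance two-sample t-test on per-sample mutation counts is provided
as a convenience wrapper only.

## Synthetic data generator

The generator operates at the callset/evidence level (no reads or BAMs):
the integration stages consume variant-level summaries, so read-level
simulation would add cost without test power. One contig carries `n_genes`
two-exon genes with planted homopolymer runs and repeat/editing annotation
tracks, so every filter has positive and negative cases.

Defaults (one synthetic "sample" under the study conditions): 500 somatic
SNVs, 25% non-exonic; 30% of genes silent, the rest log-normal abundance
(median 30) mapped to negative-binomial RNA depth (dispersion 5); intronic
positions of expressed genes keep 15% of the mature-transcript coverage
(pre-mRNA), so some non-exonic truth is "expressed"; tumor/normal DNA depth
NB with means 80/60. DNA VAFs are Beta(2, 5); RNA VAFs come from a Gaussian
copula with the same marginal, calibrated numerically (fixed internal seed,
common random numbers) so the **attained Pearson r on the transformed
margins** equals the configured target (default 0.74), not merely the latent
normal correlation. Caller detection is `logistic(−3 + 6·vaf +
0.6·log(1+dp))` — recall rises with allele fraction and expression — with
per-caller false-positive rates ordered SNPiR > RVBoost > MuTect2
(10⁻³, 6·10⁻⁴, 2.5·10⁻⁴ per exonic base); 25 germline contaminant sites
(VAF ≈ 0.5 in all specimens) and 12 editing artifacts (A>G / C>T, zero DNA
VAF, deep coverage, half present in the known-editing track) are injected.
A constant `detection_prob` per caller overrides the logistic model for
controlled experiments. The spike-in experiment attempts 200 coding sites
with uniform VAFs; a site succeeds only if its RNA depth reaches 10, and
succeeded variants are injected into truth, evidence and the caller inputs
through the same detection models. `spike_in` mutates the dataset in place
and returns the attempted/succeeded report.

Reported caller VAFs are quantized to 6 decimals so VCF round-trips
(binary32 INFO floats) are exact. Identical configs (including seed) yield
byte-identical output files.

**What the simulator does not emulate** — and hence what green tests do not
show about real data: read-level error profiles and mapping artifacts
(filters are exercised by construction, not by realistic artifact rates),
tumor subclone structure (VAF heterogeneity is only the Beta marginal),
strand/gene orientation, linkage between nearby sites, and any real
genome's repeat or editing landscape. Tests demonstrate the correctness of
the integration arithmetic and the statistical calibration of the
generator, not caller performance on real tumors.

## Numerical and design choices

* Problem sizes in the test suite and acceptance script (hundreds of genes,
  500–2000 truth variants, one weight-grid sweep) were chosen as the
  smallest sizes at which binomial/Fisher sampling error is well inside the
  asserted tolerances.
* Threshold rule is `≥`; grid step 0.01 on [−3, 3]; evalue ties break to the
  smallest threshold; weight vectors are deduplicated at 10-decimal
  rounding.
* Percent formatting uses decimal half-up rounding; one upstream prose
  figure (a 74.5% FN rate whose ratio computes to 74.59%) appears to be
  truncated rather than rounded and is intentionally not chased.
* Duplicate VCF records for one key keep the maximum reported VAF.
* The evidence-table convention `vaf = alt_hq / dp_hq` defines `vaf = 0` at
  zero depth.

## Known limitations

The exact subset of hard-filter steps applied to the MuTect2 stream in the
original workflow is not fully specified upstream; the chain here is fully
configurable with the interval-based steps as defaults. Specificity over a
genome-wide universe is not reported (true negatives are ill-defined);
precision/recall/evalue are the operative metrics. The two-callset
comparison is a generic partition — no re-implementation of any external
DNA+RNA caller is included.
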