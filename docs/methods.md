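# Methods

## The analysis model

The pipeline operates on Infinium-450K-style beta-values: per-CpG
methylation levels β = M/(M+U) in [0,1], two biological samples per
condition (non-decidualized and decidualized endometrial stromal cells,
ESCs). All inference is deliberately simple, mirroring how such array
studies are analysed in practice:

* **Condition summaries** are per-probe means across that condition's
  samples. The pooling rule matters only in the presence of noise; it is
  applied uniformly before any thresholding, averaging or profiling.
* **Differential methylation** is pure thresholding on
  Δβ = β_decidualized − β_non-decidualized with a strict inequality
  (|Δβ| > cutoff; cutoffs 0.15 and 0.30 by default). There is no
  moderated statistic — the method's claim is about effect sizes, not
  significance, and the package reproduces exactly that. "Hypomethylated"
  means β decreased from the reference (non-decidualized) condition.
* **Promoter methylation** per gene is the mean of condition-mean betas
  over CpGs in the half-open TSS window [−300, +700) bp, strand-aware.
  Genes with no CpG in the window are *absent* (NaN), never zero.
* **Group comparisons** (promoter betas across expression classes,
  region betas between conditions, z-scores across cell types) use plain
  unpaired Student *t* tests (pooled variance, not Welch) with Holm
  step-down adjustment over each family of pairwise contrasts. Holm
  adjustment is delegated to `statsmodels.stats.multitest.multipletests`;
  the test suite checks it against an independent textbook step-down
  implementation.

## Coordinate and boundary conventions

* Internally everything is 0-based half-open (BED-compatible). Probe
  annotation files are declared 1-based on disk and converted on read;
  writers restore the disk convention, so read∘write is the identity.
* Strand is resolved at read time (TSS = start for `+`, end for `-`);
  signed TSS distances are negative upstream for both strands.
* Metagene regions: upstream covers signed distances [−1500, 0), the
  body [0, L] with TSS ↦ 0 and TES ↦ 1 exactly (r = d/L), the
  downstream flank (L, L + 1000]. A TSS-coincident CpG is body position
  0. A CpG inside several genes' spans contributes one assignment per
  gene — region counts are multiplicities, not partitions of the CpG
  set.
* Beta-distribution bins follow the printed inequalities exactly:
  β < 0.2 strict, 0.2 ≤ β ≤ 0.7 inclusive, β > 0.7 strict.
* Bin resolution of metagene profiles (40 body bins, 100-bp flank bins)
  is a package default, configurable; quantiles use numpy's
  linear-interpolation convention so profiles are bit-reproducible.
* Promoter-centred profiles over a fixed signed window (default
  −1500..+4000 bp) profile the literal window without truncation at
  gene ends.
* Gene association of differential CpGs uses a closed TSS-relative
  window, default [−1500, +4000] bp, chosen to match the span profiled
  around promoters; it is exposed as a parameter since no canonical rule
  exists.

## Numerical choices

* Threshold comparisons on Δβ round the difference to 12 decimals
  first, so a difference that equals the cutoff up to float
  representation (e.g. 0.40 − 0.10 vs 0.30) does not spuriously clear a
  strict inequality. This changes no genuine call.
* Fold changes with a zero denominator: a gene with both FPKM below the
  silent floor (0.01) is silent regardless of ratio; otherwise
  FPKM_a = 0 yields an infinite ratio (up) and FPKM_b = 0 a zero ratio
  (down). A ratio exactly at the 1.5 cutoff is unchanged (strict).
* Filtering uses the conservative any-sample rule: a probe failing
  detection (p > 0.05) in any sample is removed. The alternative
  (all-sample) rule would retain slightly more probes; the choice is a
  documented package decision, matching common array practice.
* The candidate filter "ESC promoter β < 0.2" uses the mean of the two
  ESC-condition promoter values; requiring both conditions individually
  below the cutoff is available as `rule="both"`. The same pooled ESC
  value is the reference in the cross-cell-type Δβ comparison.
* z-scores across cell types use the sample SD (n−1); genes with zero
  variance are excluded with a warning rather than propagating NaN.
* Genes absent from a cell-type panel are *unclassifiable*, never
  assumed hypermethylated.

## The synthetic-data generator

The generator emits every input the pipeline consumes, with recorded
ground truth. Its defaults are the study conditions at laptop scale:
100,000 CpGs, 5,000 genes on 4 synthetic autosomes, 2 samples per
condition, an 8-cell-type methylation panel and a 5-tissue expression
panel.

* **Beta mixture.** Baseline betas come from a three-component mixture
  with fractions (0.39, 0.21, 0.40): low ~ Beta(1.5, 20) truncated to
  [0, 0.2), mid ~ 0.2 + 0.5·Beta(4, 4) (support exactly [0.2, 0.7]),
  high ~ Beta(20, 1.5) truncated to (0.7, 1]. Components are truncated
  to their bins and planted as an exact integer multiset, so the
  realized bin counts equal the targets up to measurement noise.
* **Promoter dips.** Each gene carries 6 promoter CpGs uniform in
  [−300, +700); promoter CpGs of expressed genes are drawn from the low
  component (hypomethylated promoters), while silent genes' promoters
  draw from the leftover mixture and are therefore mostly methylated.
  Background CpGs are sampled uniformly outside all promoter windows so
  promoter summaries are governed by the planted CpGs alone.
* **Planted differential CpGs.** Default 15 gaining and 8 losing CpGs
  (Δβ = ±0.5) drawn from background CpGs whose baseline leaves room for
  the shift, applied to the decidualized condition and clipped to [0,1].
* **Expression.** Baseline FPKM is log-normal (log₂ mean 3, sd 1.5,
  floored at 0.02 so expressed genes cannot collide with the silent
  rule). Planted classes: 800 up and 700 down genes at 2.0-fold (safely
  beyond the 1.5 cutoff so recovery is exact), 1000 silent genes
  (both FPKM < 0.01), the rest with ratios inside (1/1.5, 1.5). The
  up/down counts are sized so the planted specificity tiers (below) fit
  inside the up-regulated candidate set at this scale.
* **Histone peaks.** Differential-peak BEDs are promoter windows of
  sampled up-regulated (increased, 346) and down-regulated (decreased,
  284) genes — hence hypomethylated regions, reproducing the marked
  vs mark-free methylation contrast.
* **Specificity tiers.** Among up-regulated genes, 63 are planted
  cell-specific (promoter shifted +0.5 in all 8 other cell types) and
  318 partial (shifted in a random proper subset); among down-regulated
  genes, 43 and 279. The expression panel gives cell-specific genes low
  expression in every non-ESC tissue.
* **Noise and QC bait.** Per-sample measurement noise is additive
  Gaussian on the logit scale (default sd 0.1 — small enough that
  threshold calls behave as in the noise-free analysis; set 0 for exact
  closed-loop checks). Extra probes beyond the CpG budget exercise QC:
  a fraction with a failing detection p-value in one random sample and a
  fraction on chrY, so the post-filter matrix has exactly the configured
  CpG count.

**What the generator does not emulate:** probe-type (I/II) chemistry
differences, spatial autocorrelation of methylation along the genome,
CpG-island structure, batch effects, biological variability between
individuals beyond i.i.d. logit noise, and realistic gene-length or
CpG-density distributions. Passing closed-loop tests therefore
demonstrates correctness of the pipeline's logic under the stated
statistical structure, not robustness to artefacts of real arrays.

## Known limitations

* Differential calling is threshold-only by design; no variance
  moderation or replicate-level testing is offered.
* Gene bodies are modelled as single intervals; exon structure is
  ignored in the body rescaling.
* The percentage of differential CpGs is computed from the package's own
  denominator (retained CpGs). Published tallies at the 0.15 cutoff
  round differently (582/482,005 = 0.1207%, sometimes printed 0.1203%);
  the package reports the arithmetic value to 4 decimals.
* Region-level methylation reports per-CpG betas by default; per-region
  aggregation (mean per interval) is available but the boxplot unit in
  published figures of this kind is often unstated.
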