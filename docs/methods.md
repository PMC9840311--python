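# Methods

This note documents the models behind `ocscore`: what the simulator
generates and why, how each feature family is defined, the numerical
choices inside selection/modeling, and what the synthetic results do and
do not say about real plasma data.

## Synthetic cohort model

The simulator is the package's study-condition definition: its defaults
are the conditions under which all shipped results are computed.

**Genome.** Three 30-Mb chromosomes (no chrY — the pipeline excludes it
throughout).  Base composition follows a smoothed per-2-kb GC target
(mean 0.41, sd 0.05, clipped to [0.25, 0.65]) so that GC correction has
real structure to remove; the stored `gc_track` is the *realized* GC of
each window.  100 TSSs per chromosome are placed quasi-evenly (±30 %
jitter, ≥ 2 kb from chromosome ends so every ±2-kb window fits), with
random strands.  Planted truth: two CNV segments (chr1:10–15 Mb gain at
copy ratio 1.5, chr2:5–8 Mb loss at 0.6 — each ≥ 2 Mb, disjoint), 40
NDR-altered genes at depletion depth 0.9, and 32 biased cleavage 4-mers
(16 up-weighted ×1.3, 16 down ×0.75 in the tumor class).

**Fragment length laws.** Healthy: a discretized two-component Gaussian
mixture — mono-nucleosome mode 167 bp (sd 12, weight 0.85) and
di-nucleosome mode 334 bp (sd 25, weight 0.15) — multiplied, at and below
the mono mode, by a cosine ladder `1 + 0.6·cos(2π(L−167)/10.4)`.  The
ladder reproduces the ~10.4-bp sub-peaks of real cfDNA and, importantly,
gives the law a *sharply defined* 1-bp mode: a plain Gaussian with sd 12
differs by only ~0.3 % between neighbouring bins, so its empirical mode at
n = 100k would be a coin flip among 166–168; with the ladder the modal
length is 167 across seeds.  The tumor law is the same shape shifted
shorter (modes 150/300).  A cancer sample with tumor fraction f draws each
fragment from the tumor law with probability f.

**Fragment placement.** Candidate fragments (uniform start, law-drawn
length) are thinned by rejection with weight

    w = occupancy(midpoint) × [tumor only:] copy_ratio(window) × w4(5' end) × w4(3' end)

* `occupancy` is 1 outside TSS neighbourhoods; within ±2 kb of the nearest
  TSS it is a 190-bp-period sinusoid (amplitude 0.25) with a floor of 0.5
  inside the strand-aware NDR (−150..+50).  Tumor-law fragments at the
  altered genes see the NDR floor multiplied by (1 − depletion), i.e. less
  protection, hence less coverage, hence a higher NF score.
* `copy_ratio` multiplies tumor-law sampling inside planted CNV segments.
  Because the mixture is applied at the candidate level, the expected
  count enrichment inside a gain is exactly `1 + f·(r−1)`.
* `w4` re-weights tumor-law cut sites by the genomic 4-mer at each 5'
  terminus.

Fragments that would cross a chromosome end are resampled, never clipped.
Every stage is driven by `numpy` Generators seeded from the master seed
via fixed spawn keys (genome: key 0; sample i: key (1, i); split: key 2),
so outputs are byte-identical per seed and samples can be regenerated in
isolation.

**Cohort.** 100 HC / 59 OC at 300,000 fragments per sample (~0.55×
genome-equivalent coverage — the low-pass WGS regime), tumor fraction 0.3.
The train split takes `ceil(2/3 · n_OC)` cancer cases (40/19 for 59) and
half the controls (50/50), by seeded random partition.

## Feature definitions and conventions

* **Motifs** — both 5' termini per fragment are counted (each
  double-stranded fragment has two); windows that leave the chromosome or
  contain non-ACGT bases are skipped, not imputed.  Frequencies have no
  pseudocount; zeros are handled downstream.
* **Fragmentation** — midpoint bin assignment (`floor((start+end)/2)`), so
  boundary-straddling fragments count exactly once; 0.5 pseudocount on
  both short and long counts keeps empty bins finite (ratio 1); mean
  insert size averages *all* lengths, not just 90–220.
* **NF** — depth is per-base fragment coverage (overlapped bases / region
  length), the background excludes the NDR interval to avoid
  self-contamination, and the minus-strand NDR is the exact reflection of
  the plus-strand window about the TSS.  `(bg − ndr)/bg` is used rather
  than a raw difference so the score is sequencing-depth-independent and
  "NF = 0" doubles as the no-coverage flag the prefilter keys on.
* **CNV** — fragment counts per 2-kb window (midpoint rule) are normalized
  to mean 1, divided by their GC-decile median depth (deciles under 10
  windows merge with a neighbour; a zero median falls back to the mean),
  renormalized, then smoothed by a 10-window (20-kb) rolling mean.
  Smoothing trades ~5 windows of boundary resolution for a √10 noise
  reduction — without it, single-2-kb-window counts at low-pass depth are
  Poisson-dominated and a 15 % depth shift can never reach |z| > 3.  The
  baseline panel stores per-window mean/sd over ≥ 5 healthy *training*
  samples, with sd floored at `max(sd, 0.03·mean, 1e-3)`; the floor bounds
  z inflation in near-constant windows while keeping a 15 % shift (the
  smallest planted effect, copy ratio 1.5 at f = 0.3) detectable — a 0.05
  floor would place that effect exactly at the significance boundary.
  z-scores are re-centred by their genome-wide median before thresholding:
  mean-1 normalization shifts copy-neutral windows whenever an aberration
  occupies a non-trivial genome fraction, and the median (robust up to
  ~40 % aberrant genome) restores the neutral baseline; in the null it is
  a no-op.  Significant windows (|z| > 3) merge into same-sign runs
  bridging ≤ 10 non-significant windows (the smoothing correlation
  length); runs spanning > 2 Mb are segments.  The burden score
  `Σ |mean z| × span_Mb / 100` is zero exactly when no segment is called,
  increases with amplitude and extent, and the 1/100 scale keeps typical
  scores O(0.1–1) so the additive OC score is not CNV-dominated.

## Selection and modeling

* The Wilcoxon rank-sum test uses the exact null distribution for small
  tie-free samples (both n ≤ 8) and the normal approximation with tie and
  continuity corrections otherwise; degenerate input returns p = 1.
* The NF zero-fraction filter is a label-free missingness filter and so
  uses the whole cohort ("more than 10 %" is strict: exactly 10 % is
  kept); every label-dependent quantity — rank tests, the L1 penalty path,
  SVM fits, calibration, integration, cutoffs, the CNV baseline panel —
  sees training rows only.  A dedicated audit perturbs test rows and
  asserts bit-identical models.
* L1 selection: features standardized on train; inverse penalty chosen on
  a 50-point log grid (10⁻⁴–10⁴) at minimum mean cross-validated deviance
  with seeded stratified folds (liblinear, seeded).  Min-deviance rather
  than 1-SE keeps selection permissive, matching the intent of a
  feature-screening step rather than a sparsest-model step.
* Per-family SVMs are linear-kernel (high-dimension/low-n regime;
  deterministic and calibratable), C from a 13-point log grid by
  stratified 10-fold CV on accuracy (ties → smaller C).  Calibration is a
  1-D logistic fit on out-of-fold decision values (mild ridge, C = 10, so
  a separable fold set cannot push the slope to infinity).  The per-family
  cutoff maximizes train accuracy, ties resolved toward the higher cutoff
  (higher specificity).  An empty selection degrades to a constant-0.5
  scorer with a warning, and the pipeline continues.
* Integration: unpenalized 3-covariate logistic regression on the train
  family scores (covariates centred during optimization — the MLE is
  unchanged but degenerate constant covariates stay at exactly zero
  weight), with a small ridge fallback (C = 10³) under perfect separation.
  The fixed reference coefficient mode (−2.48, 2.84, 2.01, 0.56) is
  provided for formula fidelity; it is illustrative, because the scale of
  the scores those coefficients were originally fit on is not defined —
  refit mode is the default for actual classification.
* OC score = logistic + CNV, classified at the train Youden cutoff
  (ties → higher cutoff).  Candidate cutoffs are the observed scores, so
  under perfect train separation the cutoff sits at the smallest train OC
  score; on very small cohorts the test scores of true positives can fall
  just below it — an inherent property of this cutoff convention, visible
  in the examples, not a bug.

## What the defaults can and cannot show

At the default ~0.55× coverage, per-gene promoter windows receive only a
handful of fragments, so per-gene NF estimates are noisy and essentially
no gene reaches the p < 0.001 prefilter at n = 90; the NF block is then
legitimately empty and the integration leans on motifs and fragmentation
(the CNV score is likewise near-zero for the default planted effects at
this depth — consistent with copy number being a high-specificity,
low-sensitivity channel).  NF selection power, NF monotonicity in
depletion depth, and CNV segment recovery are therefore demonstrated on
dedicated high-coverage configurations (a 5-Mb genome at ~45× promoter
coverage; a 20-Mb genome at ~300 fragments per 2-kb window), where the
planted effects are recovered with the documented accuracy.  Problem
sizes in the test suite were chosen as the smallest where the targeted
effect is statistically unambiguous.

The simulator emulates: the 167-bp chromatosome peak with its 10.4-bp
ladder and di-nucleosome shoulder; shorter tumor fragments; promoter
NDRs with class-dependent depth; cleavage-motif bias; megabase-scale
copy-ratio changes diluted by tumor fraction; and GC-dependent depth
structure.  It does not emulate mappability/blacklist regions, paired-end
artifacts, duplicate reads, inter-individual germline variation,
chromatin heterogeneity between tissues, or batch effects — so passing
tests demonstrate the correctness and internal consistency of the
pipeline, not clinical performance.  Headline clinical metrics from real
cohorts are not reproducible from synthetic data and are not targeted.

## Known limitations

* The CNV significance/merging parameters (z threshold, sigma floor, gap
  tolerance, smoothing width, score scale) are package choices; the
  burden score is a declared stand-in for unpublished scoring equations
  in the literature.
* Per-window z-scoring needs high per-window depth for boundary-accurate
  segment calls; at true low-pass depth only high-amplitude events are
  detectable.
* The 1-Mb bin count of a real reference differs from naive ceiling
  tiling when mappability filters are applied; this package tiles naively
  and makes no claim about any specific published bin count.
* In fixed-coefficient integration mode the input scale is nominal (the
  calibrated [0, 1] family scores), so downstream performance of that
  mode is illustrative only.
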