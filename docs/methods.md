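# Methods

This note documents the models and procedures implemented in `methpanel`,
the parameter choices that matter, and the limits of what the synthetic
validation shows.

## Reactivation screen

The screen assumes linear-scale, strictly positive expression intensities
on array elements (probes) that map many-to-one onto gene symbols.

- **Up-regulation filter.** An element passes when treated/untreated ≥
  `min_fold` (default 2) in at least `min_lines` (default 6) of the
  treated/untreated cell-line pairs; both bounds inclusive. A gene passes
  when any of its elements passes. Pairing is explicit via `pair_id`; an
  unmatched member is an error, not a silent drop.
- **Down-regulation filter.** Element-wise strict inequality
  median(tumor) < median(control); gene-level collapse again by "any
  element".
- **Ranking.** Candidates (the intersection) are scored by
  log₂(median tumor / median control) of each gene's most-downregulated
  element, sorted ascending (most negative = strongest silencing signal),
  ties broken lexicographically by gene symbol for reproducibility, and
  truncated to `top_n` (default 30). The log scale matches array
  convention; the original workflow states a ranking by degree of
  downregulation without naming a metric, so the metric here is a package
  choice.

No normalisation, batch correction or differential-expression testing is
performed: the screen is a deterministic filter on the given matrix.

## Promoter CpG-island detection

Promoter windows are 1000 bp upstream + 500 bp downstream of the TSS
(0-based half-open coordinates); minus-strand promoters are
reverse-complemented before scanning, so coordinates always read
upstream→downstream of the gene.

Detection uses the Takai–Jones composition criteria: GC ≥ 55 %, CpG
observed/expected = (#CpG·L)/(#C·#G) ≥ 0.65, length ≥ 500 bp, assessed in
200-bp windows. GC content excludes N from numerator and denominator; any
ambiguous base disqualifies a segment outright (conservative behaviour on
masked sequence).

The extension/trim schedule of the legacy searcher is under-documented, so
this detector pins down the output semantically instead of reproducing a
particular schedule: 200-bp seed windows localise candidate neighbourhoods
(`merge_gap`, default 100 bp, only groups seeds), and the reported islands
are the *maximal* segments on which both criteria hold over the full
extent. This makes every reported island re-satisfy all thresholds on its
own extent, makes the detector equal to an exhaustive-substring oracle
(tested), and makes the result independent of scan order. When two maximal
segments overlap, the longer one wins with a leftmost tie-break; in the
rare case of equally long overlapping segments the reported boundary can
therefore shift by a few bases between strands, while island count, length
and composition are strand-invariant.

Boundary comparisons use integer prefix counts (100·(#G+#C) ≥ gc_min·L and
#CpG·L ≥ oe_min·#C·#G), so windows sitting exactly on a threshold are
included without floating-point ambiguity.

## Bisulfite tools

In-silico conversion turns each unmethylated C into T with probability
`efficiency`; methyl-cytosines never convert. The per-site methylation
ratio is C/(C+T) peak height. Classification rounds the ratio to two
decimals (ties away from zero) and then bands it: ≤ 0.20 unmethylated,
0.21–0.80 partially methylated, ≥ 0.81 methylated. The rounding convention
closes the nominal gap between 0.20 and 0.21 — the bands are stated at
two-decimal resolution, and how exact in-between values were handled
originally is unrecorded, so the convention is a package decision and
borderline sites are visible in reports. Zero-signal sites are flagged
unevaluable rather than aborting a report. Conversion QC is the fraction
of non-CpG-context cytosines (context judged on the original forward
strand) reading as T.

## qMSP and PMR

- **Censoring.** Amplification strictly after cycle 35 and non-amplifying
  wells are censored. Censored gene wells quantify to 0 (absence of
  methylated template); a fully censored ALU-C4 reference invalidates the
  sample, because input normalisation is then impossible — this mirrors
  per-sample assay failure in real cohorts.
- **Standard curve.** Ct = slope·log₁₀(q) + intercept by least squares on
  the dilution series of universally methylated control DNA (≥ 2 distinct
  points, slope must be negative). Standards are fitted before censoring
  so the low end of the series anchors the line. One curve per assay.
- **PMR.** Replicates are aggregated as the median of replicate
  quantities per assay, then PMR = 100 · ratio-of-medians(sample) /
  ratio-of-medians(positive control). "Median GENE:ALU ratio" is ambiguous
  between this and the median of per-replicate ratios; ratio-of-medians is
  robust to unpaired censoring (a censored gene replicate does not delete
  an ALU replicate). The positive control against itself is exactly 100.
- **Thresholds and scoring.** Per-gene threshold = maximum PMR across the
  healthy controls; scoring is strict (PMR > threshold) by default so the
  threshold-defining control itself stays negative and control specificity
  is 100 % by construction. An inclusive (≥) rule is available via
  configuration; values exactly on a positive threshold are flagged in
  output either way.

## Panel statistics

Panel call = logical OR over the panel genes (missing gene → negative,
logged). Sensitivity and specificity are reported in integer percent with
ties rounded away from zero (54/61 → 89 %). The threshold-free score is
the sum of panel-gene PMRs; the empirical ROC is traced over all distinct
scores and its AUC is computed as the tie-aware Mann–Whitney statistic via
midranks. The trapezoidal area under the point set equals that statistic
identically; the implementation asserts agreement to 1e-12 as an internal
consistency check, and tests additionally compare against O(n²) pair
counting and scikit-learn. Per-gene ROC uses the same orientation (higher
PMR = more disease-like).

## Synthetic data: what it emulates

Defaults mirror the study design: 11 treated/untreated cell-line pairs, a
37-tumor test series (7 BL, 10 DLBCL ABC, 10 DLBCL GCB, 10 FL), 10 healthy
controls, triplicate qMSP wells, a −3.32 cycles/log₁₀ standard curve
(perfect PCR efficiency) with intercept 40. Desk-scale element counts
(200 elements, 10 planted targets) replace the genome-wide arrays, whose
per-sample measurements are not available; the screen's published
genome-scale set sizes are therefore not reproduction targets.

- **Expression** is simulated on the log₂ scale — baseline N(8, 1) per
  element, planted effects (+log₂ fold for reactivation, −log₂ fold for
  tumor downregulation) added, N(0, 0.5) measurement noise, then
  exponentiated. This guarantees positivity and makes noise-free fold
  changes exact. The noise magnitude is a free parameter (no assay noise
  magnitudes are published); 0.5 log₂ units is a realistic array-scale
  spread and is not calibrated to any test outcome.
- **Promoters** use first-order Markov sequence models: island segments
  (GC ≈ 68 %, obs/exp ≈ 1.3) embedded in CpG-depleted background
  (GC ≈ 46 %, obs/exp ≈ 0.09, comfortably below the 0.65 criterion).
  Generated sequences are verified against the composition criteria and
  resampled on the rare failure, so flags are guaranteed by construction.
- **qMSP plates** derive each well's Ct from the planted methylation
  fraction f through quantity = f · DNA input and the linear curve, plus
  N(0, 0.15) cycles of Ct noise (a typical real-time PCR replicate spread;
  free parameter). Fraction 0 yields non-amplifying wells, so healthy
  controls produce PMR = 0 for every gene — control cleanliness is a
  model assumption here, matching the all-negative control series of the
  study design.
- **Electropherograms** emit per-site C/T heights with the planted ratio
  in expectation; chromatogram artefacts (dye blobs, baseline drift,
  neighbouring-peak interference) are not modelled.

**PMR recovery metric.** Error propagation of 0.15-cycle well noise
through triplicate medians and the two quantity ratios gives a per-sample
PMR spread of roughly 15–20 % of the PMR value, so recovery is assessed as
estimator bias: the mean signed deviation from 100f across 200 simulated
runs, each run carrying its own standards and positive control so that
run-level calibration noise averages out. The acceptance suite requires
|mean deviation| ≤ 2 PMR units at 0.15-cycle noise and exact recovery in
the noise-free limit.

What passing synthetic tests does **not** show: robustness to array
platform artefacts, PCR inhibitors, DNA-quality variation, or
between-plate drift; nor that real cohorts separate as cleanly as planted
ones (the simulated panel AUC of 1.0 reflects the planted
all-controls-zero structure, not an empirical claim).

## Problem sizes and numerical choices

Simulated problem sizes (200 elements, 10 targets, 37 + 52-sample cohorts,
200 recovery runs) are chosen so the full suite runs in well under a
minute while keeping every statistical check several standard deviations
away from its bound. Percent rounding is half-away-from-zero via decimal
arithmetic (0.205 → 0.21, 88.52 → 89), applied only at the reporting
boundary; all comparisons (e.g. the strict 70 % filter) use unrounded
values. Degenerate inputs fail loudly: all-N sequences, empty cohorts,
single-point standard curves, zero-variance dilutions, zero-signal peaks
and unmatched cell-line pairs all raise typed errors.

## Known limitations

- The MSP stage consumes consensus call matrices; duplicate-PCR
  reconciliation and gel interpretation are upstream of this package.
- Published per-gene AUC values below 0.5 in the source setting are not
  emulated; with all-zero controls and the documented orientation, a
  per-gene AUC below 0.5 cannot arise from these formulas, and the
  underlying per-sample scores are not available to investigate.
- The CLI's `run-all` is a synthetic-data demonstration harness; real
  cohorts enter through the per-stage commands and the documented TSV/CSV
  interfaces.
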