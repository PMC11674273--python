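# Methods

This note documents the models, rules and numerical choices behind
`rthclat`, and what the synthetic-data generators do and do not emulate.

## Assay model

The assay uses THP-1 cells (a human monocytic line standing in for
dendritic cells) as a biosensor: exposure to a skin sensitizer induces
stress-response genes — HMOX1 through the Keap1/Nrf2 electrophile-response
axis, JUN as an AP-1 component — within a few hours. Expression is read
out by singleplex real-time PCR against a GAPDH internal control, in
triplicate, alongside solvent-control cultures.

### Comparative-Cq quantification

Fold change is `2^−ΔΔCq` with `ΔCq = Cq(target) − Cq(GAPDH)` and
`ΔΔCq = ΔCq(treated) − ΔCq(control)`. Amplification efficiency is assumed
to be 2.0 per cycle for every primer pair (no Pfaffl-style correction);
this matches the plain comparative-Cq convention and keeps the
transformation parameter-free. Cq inputs must be finite and positive;
non-finite values are rejected rather than propagated.

How the control ΔCq enters the contrast is not uniquely defined by the
comparative-Cq convention, so both common readings are implemented:
**paired** (control replicate *i* against treated replicate *i*; the
default) and **mean** (all treated replicates against the mean control
ΔCq). With noiseless inputs the two coincide; with noise they differ
slightly in variance but not in expectation on the log scale.

### Decision rule

`DecisionRule(threshold=2.0, quorum=2, n_replicates=3, panel=(HMOX1, JUN),
inclusive=True)`. A gene is positive when at least `quorum` replicates
reach `threshold`; the chemical is a sensitizer when any panel gene is
positive. Two boundary choices matter and are explicit:

* **Inclusive comparison** (`≥ 2.0`) is the default. The packaged
  screening panel forces it: saccharin's HMOX1 triplicate (2.0, 1.1, 2.2)
  is published as a sensitizer call, which requires a replicate exactly at
  2.0 to count. `inclusive=False` is available for sensitivity analysis.
* **Down-regulation never contributes.** The rule is phrased purely in
  terms of increase; a strongly suppressed gene is simply negative.

Fold changes are compared at the precision supplied — the packaged
fixtures carry one decimal, as published — and no internal re-rounding is
applied.

## RNA-Seq marker discovery

The study design behind the discovery stage: 11 treatments (6 sensitizers,
3 non-sensitizers, 2 controls), n = 3 cultures each.

* **Low-count filter.** A "test segment" is one treatment; a gene is kept
  when its per-segment statistic (mean over replicates by default, sum
  optional) reaches `min_count = 10` in at least one segment. The boundary
  (≥ vs >) is configurable because the two natural phrasings of the filter
  disagree exactly at the cutoff; the default is ≥.
* **TPM.** `TPM_g = (count_g/length_g) / Σ_h (count_h/length_h) × 10^6`
  per sample; gene lengths are an input column, no annotation parsing.
* **Differential test.** Deliberately simple and self-contained, an
  approximation of the DESeq2-style analysis rather than a reimplementation
  of it: median-of-ratios size factors (library-size fallback when no gene
  is ubiquitously expressed); gene-wise method-of-moments dispersion from
  the pooled within-group variance, clipped to [1e-4, 10], with no
  empirical-Bayes shrinkage toward a trend; a Wald statistic on
  `log2((μ_a + ½)/(μ_b + ½))` with delta-method standard errors, referenced
  against a **t distribution with the pooled residual degrees of freedom**;
  Benjamini–Hochberg adjustment across tested genes. The t reference is the
  load-bearing small-sample choice: at n = 3 per group the gene-wise
  variance estimate is noisy, and a normal reference lets genes with
  accidentally tiny within-group spread produce extreme z-statistics — a
  3-vs-3 null simulation then flags ~3% of genes at BH 0.05, while the t
  reference keeps it well under 1% without shrinkage machinery. A test
  cross-checks the whole procedure against pydeseq2 on a simulated design
  (log2FC correlation > 0.95, near-identical significant sets); exact
  numerical agreement with that package is not a goal.
* **Selection.** Sensitizer-specific = passes |log2FC| > 1 and adjusted
  p < 0.05 in sensitizer-vs-control AND fails that joint cut in
  non-sensitizer-vs-control. The sensitizer-vs-non-sensitizer contrast can
  be computed but does not enter the predicate, since the selection is
  defined by sensitizer-only alteration. Treatments are pooled by group
  label; per-treatment contrasts are possible by relabelling.
* **Ranking.** Among candidates with mean TPM ≥ 10 in sensitizer-treated
  samples, the 10 largest up- and 2 most negative down-regulated log2 fold
  changes; ties break toward higher TPM, then gene id. The TPM floor is a
  configuration default, not a published value. Note that computing the
  floor over sensitizer-treated samples penalizes down-regulated genes
  (their expression is suppressed exactly there); the warning emitted when
  fewer candidates qualify than requested makes this visible.

## Platform concordance

A PCR replicate is *discrepant* from the RNA-Seq fold change when
`max(a,b)/min(a,b) ≥ 2` — a symmetric, scale-invariant ratio criterion,
inclusive at exactly 2.0. A chemical×gene cell is a mismatch on ≥ 2 of 3
discrepant replicates; a gene is retained only when all nine reference
chemicals' cells match (this strict reading reproduces the published
five-marker set). Values rounded to 0.0 occur in the published table for
near-silent genes: two zeros count as agreement, a zero against a positive
value as a discrepancy, which reproduces every published zero-bearing
verdict. Recomputing the full 108-cell panel agrees with the published
verdicts in 106 cells; both deviating cells (4-aminobenzoic acid × SAT1,
glycerol × ULBP2) involve one-decimal rounding at or near the two-fold
boundary, where the unrounded source values could legitimately fall on
either side. Neither affects the retained set.

## Accuracy accounting

LLNA potency classes {extreme, strong, moderate, weak} all binarize to
*sensitizer*; ND (no data) chemicals are counted in `n_total` but excluded
from every accuracy denominator, which each report states explicitly.
h-CLAT comparisons use the p/n judgments carried in the chemical metadata
verbatim; no CD86/CD54 computation is performed. Threshold sweeps
re-apply the decision rule per gene and per panel at each cutoff;
lowering the threshold is monotone in the number of sensitizer calls.

## Synthetic data

* **qPCR generator.** Treated target Cq = baseline − log2(trueFC) + ε,
  control and reference wells at baseline + ε, ε ~ N(0, sd) per well on
  the cycle scale (log2-normal on the ratio scale — the standard qPCR
  error model, which makes fold-change error analytically tractable: a
  recovered log2 ratio has sd `2·sd` under paired controls). Deterministic
  given the seed.
* **RNA-Seq generator.** Negative-binomial counts via a gamma–Poisson
  mixture over the 11-treatment design; per-gene expected counts scale
  with transcript length (lengths log-uniform in [500, 1e5] bases) and are
  renormalized per sample to a target library size (±15% uniform jitter),
  so TPM expectations are invariant to library scaling. 60 up- and 2
  down-regulated genes are planted with |log2FC| ~ U[1.5, 6], shifted only
  in sensitizer-treated samples. Default dispersion 0.05.
* **Not emulated:** sequencing-read level artefacts (GC bias, mapping),
  batch effects, cytotoxicity/dose (CV75), correlated noise across genes,
  and chemical-specific response heterogeneity within the sensitizer
  group. Passing recovery tests therefore show that the filter cascade and
  test are correct and calibrated under the stated model, not that the
  pipeline would recover the same genes from real cultures.

## Problem sizes and defaults in tests

The recovery and calibration checks run the generators at their default
design (≈8000 genes × 33 samples) or at a 5000-gene null, which keeps the
whole suite fast while exercising the full cascade; fixed seeds make every
stochastic assertion reproducible. Monte-Carlo qPCR checks use 500
simulated chemicals at true FC 2.5 and cycle noise 0.1, where the
analytic per-chemical detection probability (~0.99) comfortably exceeds
the asserted 95% floor.

## Known limitations

* The differential test is gene-wise; it borrows no information across
  genes and will be less powerful than shrinkage-based packages at very
  small n, especially for low-count genes.
* The decision rule evaluates printed one-decimal fold changes exactly;
  conclusions at the 2.0 boundary inherit the rounding of the input.
* Chemical metadata beyond names and reference labels (CAS, solvent,
  CV75) is carried opaquely and mostly blank in the packaged fixtures;
  no dose computation is attempted.
* The binary call carries no potency information: the assay cannot grade
  extreme/strong/moderate/weak.
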