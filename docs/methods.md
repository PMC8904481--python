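# Methods

## The comparative-Ct model

A qPCR well reports the cycle number Ct at which fluorescence crosses a
threshold; under (assumed) perfect per-cycle doubling, template abundance
is proportional to 2^−Ct. The pipeline estimates expression of a target
gene in treatment *t* relative to a control treatment:

1. **ΔCt** = Ct(target) − Ct(reference), paired within one sample. Any
   per-sample offset (RNA quantity, loading) adds equally to both Cts and
   cancels exactly.
2. **ΔΔCt** = ΔCt − mean(ΔCt over control replicates), computed per
   (target, reference) pair. This puts each sample on a log2 scale
   relative to the control mean.
3. **fold** = b^(−ΔΔCt) with amplification base b = 2 by default. The base
   is configurable but no efficiency estimation from dilution curves is
   attempted: the model's premise is complete PCR efficiency, and an
   efficiency-corrected (Pfaffl-style) model is out of scope.

With several reference genes the pipeline runs once per reference and the
per-replicate fold profiles are averaged (`combine_mode="mean-fold"`). The
report always carries the Pearson correlation between the references'
treatment-mean profiles — the usual stability check before pooling — but
never blocks a run on it. An alternative `mean-ct` mode pools reference
Cts within each sample first, as much instrument software does; the two
modes agree when references behave identically and differ slightly
otherwise (arithmetic vs geometric flavour of pooling).

### Summaries, control pinning and standard errors

Per (treatment, gene), the summary is the arithmetic mean of replicate
folds with SE = sd/√n on the fold scale, matching how such tables are
printed. Published tables show the control as exactly "1 ± 0", which is
only possible if the control row is pinned after normalization — raw
control replicates scatter around 1, with geometric mean exactly 1 because
normalization subtracts their own mean ΔCt. Pinning is therefore the
default; `pin_control=False` exposes the raw scatter. A `scale="log2"`
option averages log2 folds instead, giving symmetric intervals.

One subtlety matters for inference: the control-mean ΔCt is estimated
from finitely many control replicates, and that error is *shared* by every
replicate of a treatment, so it is invisible to the within-treatment SE.
Confidence statements about a fold difference from control should use
√(SE_t² + SE_c²) (`se_vs_control`), with the control summarized unpinned
on the log2 scale. Simulation shows mean ± 2·SE intervals built this way
cover the true log2 fold at roughly nominal rates at n = 3, whereas the
naive within-group SE under-covers badly (≈ 0.67).

## Design statistics

The experiment is a two-factor completely randomized design. ANOVA is the
classical balanced fixed-effects decomposition (computed through an OLS
fit with interaction; Type-I sums equal the definitional sums for balanced
data, which the brute-force oracle in the test suite confirms). Unbalanced
tables are rejected rather than silently reinterpreted. A constant
response reports all sums of squares as exactly zero with F and p missing.

Mean comparison follows the agronomic convention: the 15 treatment cells
are compared as a one-way layout using the factorial model's MS_error and
df_error, with Fisher's LSD = t(1−α/2, df_E)·√(2·MS_E/n) at α = 0.05 and
no further multiplicity correction. A pair is significant iff
|mean_i − mean_j| > LSD — the boundary case is non-significant. Marginal
(single-factor) comparison sits behind a flag.

Compact letters assign one letter per maximal clique of the
non-significance graph. Because LSD verdicts are a threshold rule on
ordered means, those cliques are consecutive runs of the descending-mean
order, giving the familiar minimal "a, ab, b" patterns; soundness (sharers
never differ significantly), completeness (non-differing pairs always
share) and minimality are checked against an exhaustive clique-cover
oracle in the tests. Ties in means keep input order.

## Multivariate mining

All multivariate views run on treatment means by default (15 observation
rows), since that is how such figures are drawn; replicate-level tables
work identically.

* **Correlation**: pairwise Pearson on complete rows; two-sided p from the
  t transform with n − 2 df; per-pair α = 0.05 with no multiplicity
  correction. Zero-variance features give NaN with a warning.
* **Clustering**: Ward's minimum-variance criterion on Euclidean distances
  (the ward.D2-style variant), after z-scoring features — trait tables mix
  units (enzyme activity, weight, oil %), so raw distances would be
  dominated by the largest-scaled feature. Raw mode is a flag. Ties break
  by scipy's deterministic lowest-index rule; the dendrogram exports as
  Newick.
* **PCA**: eigendecomposition of the feature correlation matrix (again the
  mixed-units choice); scores are z-scored data projected on unit
  eigenvectors; biplot arrows are loadings scaled by √eigenvalue. Signs
  are fixed by making each component's largest-magnitude loading positive.
* **CCA**: canonical correlations are the singular values of
  R_xx^(−1/2) R_xy R_yy^(−1/2) on standardized variables. With 15
  observations against 11 + 6 variables the fit is heavily overdetermined
  (leading canonical correlations saturate near 1), so the default for the
  fixture analysis adds ridge λ = 10⁻³ to both within-set correlation
  matrices; a genuinely singular within-set matrix (p ≥ n) raises unless
  ridge > 0. Bartlett's chi-square approximation of Wilks' Λ is reported
  per dimension only when unregularized — under ridge the null
  distribution no longer applies, so significance is suppressed rather
  than misreported.

## The synthetic generator

`SynthSpec` emulates the study design: 3 × 5 factor levels, control at
(0, 0), three replicates, two reference genes. The generative model is
Gaussian on the cycle scale — the standard qPCR noise model — and matches
the estimator's assumptions by construction:

* a shared per-sample offset ~ N(0, `sample_effect_sd`), default 0.5
  cycles, models RNA-quantity/loading variation; ΔCt cancels it exactly,
  which is the point of the reference-gene design. (The field list of the
  generator needs this spread even though only the ΔCt-invariance matters;
  0.5 cycles is a realistic loading spread.)
* reference Ct = baseline + offset + N(0, stability sd) (defaults: actin
  18.0, EF1 20.0, sd 0.15 cycles);
* target Ct = baseline (25.0) + offset − log2(true fold) + N(0,
  `well_noise_sd`), default 0.2 cycles;
* optional dropout turns wells into missing-Ct sentinels to exercise the
  missing-data paths (default 0).

Same spec + seed gives byte-identical output. Because noise is Gaussian in
Ct and folds enter through −log2(fold), the estimator's log2 output is
unbiased; with a single reference the error variance is exactly
(σ_t² + σ_r²)(1/n + 1/n_c), which the Monte-Carlo tests confirm.

What the generator does *not* emulate: amplification-efficiency variation
between wells or genes, technical-vs-biological replicate structure,
melt-curve artifacts, inhibitor kinetics, or non-Gaussian heavy-tailed
outliers. Passing recovery tests therefore validate the arithmetic and the
statistical calibration under the model's own assumptions, not robustness
to real-world assay pathologies.

## Numerical and interface choices

* Ct parsing treats case-insensitive {"undetermined", "na", "nan", ""} as
  missing (configurable); rows are never silently dropped — every input
  row becomes either a well or a named error. Long layout (one Ct per row)
  is canonical; a wide layout (genes as columns) is accepted.
* Fixture values are transcribed at printed precision (two decimals);
  their SEs are stored alongside and never re-derived.
* Problem sizes in the validation suite: 500 simulated experiments for
  bias/coverage, 200 random instances for the letter-display oracle, all
  factor grids up to 3 × 3 with ≤ 3 replicates for the ANOVA oracle —
  small enough to brute-force, large enough to exercise every branch.
* Plots always write image + sidecar CSV atomically (temp-then-rename);
  sidecar values are bit-identical to the input summaries.
* Groups with one replicate report SE as missing with a warning, never 0.

## Known limitations

* No efficiency correction, standard-curve fitting, or well-level outlier
  rejection.
* Unbalanced ANOVA is rejected (a harmonic-mean LSD fallback is
  deliberately not the default path and marked approximate).
* CCA significance under regularization is unavailable by design.
* The letter display is exact for threshold (LSD-type) verdict structures;
  for arbitrary symmetric verdict matrices it remains sound and complete
  but the letter count may exceed the theoretical minimum.
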