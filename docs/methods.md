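# Methods

## The calibration model

Let x<sub>ig</sub> be the logcontrast expression of gene g in individual i:
the mean of the triplicate Ct values minus the mean reference-gene
(40S ribosomal protein S7) Ct of the same individual. Ct is, under full
amplification efficiency, −log₂ of the starting template, so this ΔCt is a
log-scale contrast of target against reference abundance; additive
per-sample shifts of all Ct values (RNA input, pipetting) cancel exactly.
No amplification-efficiency correction is applied — none is available
without per-assay standard curves — but the logcontrast is an extension
hook for one.

Columns are z-scored with training means μ<sub>g</sub> and SDs s<sub>g</sub>
(ddof = 1). With a univariate response, redundancy analysis (canonical
correlation against a single variable) has a closed form: the weight vector
w maximizing |corr(Σ w<sub>g</sub> z<sub>g</sub>, age)| is the least-squares
direction of the regression of centred age on the standardized matrix Z.
We solve the normal equations exactly (no iterative optimizer), rescale w so
the training variate v has unit sample variance and zero mean, and fix the
sign so corr(v, age) ≥ 0. The achieved correlation is the multiple
correlation R of age on the genes; the tests verify this identity against an
independent normal-equations oracle to 1e-10.

The calibration line v = α + β·age is fitted by OLS (β > 0 under the sign
convention; R² = R²). Age prediction inverts it: âge = (v − α)/β, deliberately
unclipped — negative estimates near age zero are information, not errors.

Standardizing before weighting is a genuine design choice: whether the
original SAS implementation standardized is unknowable, but "larger absolute
loading = more informative" is only meaningful on a common scale, and the
fitted values, R² and predictions are invariant to the choice (per-gene
affine invariance is asserted exactly in the tests); only the printed
loadings differ.

## Uncertainty: pairs bootstrap and LOOCV

The 95% CI of a prediction is the 2.5th–97.5th percentile of B plug-in ages
obtained by resampling the n training individuals with replacement and
refitting the *entire* chain — standardization constants, loadings, and
calibration line — per resample (B defaults to 1000; a pairs bootstrap was
chosen over residual resampling for heteroscedasticity tolerance). The
reported predicted age is the bootstrap median, which necessarily lies
inside the percentile interval. Resamples with constant age, a constant gene
column, or a zero-variance variate are rejected and redrawn; more than B/2
redraws is an error. BCa intervals are not implemented.

Validation is leave-one-out: each individual is predicted by a chain fitted
to the others. Bootstrap seeds are derived per sample from
(master seed, sample id) via CRC-32, and the training rows are put in
canonical (sample-id) order before resampling, so results are invariant to
the order rows arrive in.

**Known limitation — CI coverage.** The pairs bootstrap quantifies
*calibration* uncertainty (how the fitted chain varies under resampling of
the training set). It does not include the new individual's own biological
deviation from the population line, which at a population R² of 0.82 has SD
√(τ²/S) ≈ 4.7 days — the dominant error source. Measured coverage of the
true age by these 95% CIs is therefore ~55–60%, not 95%, even though the CI
halfwidth (≈ 4.2 days at study scale) matches what such assays report. A
genuine 95% prediction interval would need the new-sample noise added
(e.g. residual-augmented resampling); that is future work, and users should
read the CIs as model-stability intervals, not prediction intervals.

**Known subtlety — bias diagnostics.** Regressing LOOCV residuals on
*predicted* age has a mechanical positive slope ≈ Var(e)/Var(âge) (≈ 0.18 at
study scale) for a perfectly specified model — a shrinkage artefact of
inverse regression, not bias. Conversely, OLS calibration forces residuals
orthogonal to *true* age, so the true-age axis is the null check and the
predicted-age axis is the curvature probe. `bias_diagnostic` exposes both.

## Microarray screening

Raw fluorescence is filtered at the pooled 20th percentile (a gene is kept
if it exceeds the cutoff in at least one array — the least aggressive
reading of a one-line filter description; the arrays-above count is a
config knob), then normalized: clamp to 1.0, log₂, per-array
75th-percentile shift, per-gene median baseline. Per gene, a fixed-effects
two-way ANOVA (age, sex, interaction) is computed by the classical
sums-of-squares decomposition, vectorized across genes for balanced designs;
unbalanced inputs fall back to type-II SS via statsmodels. Zero-variance
genes return p = 1 by convention so downstream set operations stay total.
P-values are asymptotic (F distribution). Benjamini–Hochberg correction is
applied per effect across tested genes (joint correction across the three
effect lists is the plausible alternative; per-effect is the default).
Age-only genes satisfy q_age ≤ 0.01 < q_sex, q_interaction. Candidate calls
use the correlation of per-age mean profiles with age (r > 0.8 up,
r < −0.4 down, strict); with four age classes this is a monotonicity screen,
and a per-array variant is available. The fourfold-change mark is recorded
as an annotation, not a gate. Feature-extraction flags are accepted as an
optional boolean matrix only; generating them is instrument-side.

## Synthetic data: what it emulates and what it does not

The qRT-PCR generator reproduces the study design: ages 0, 5, …, 30 days,
both sexes, five individuals per age × sex cell with one random female
dropped (n = 34 F / 35 M), triplicate wells, a stable reference gene, and
candidate genes with linear logcontrast–age profiles of either sign
(up-regulated genes have negative ΔCt slopes). Noise has three components,
all Normal and in cycles: a shared per-individual shift b_i
(`sigma_individual`, default 0.5) that cancels in the logcontrast — it
exists to exercise exactly the invariance that motivates reference-gene
normalization; a per-individual, per-gene biological deviation
(`sigma_biological`) that is the accuracy-limiting noise; and well-to-well
technical noise (`sigma_technical`, default 0.15, a typical replicate SD).

Default slopes for the four-gene panel are −0.08, −0.06, −0.07 and
+0.05 cycles/day with baselines 2–5 cycles above reference — magnitudes
consistent with severalfold expression changes over 30 days. Because the
best linear combination of p genes with slopes s_g against i.i.d. noise τ²
achieves a population R² = S·Var(age)/(S·Var(age) + τ²) with S = Σ s_g²,
`biological_sigma_for_r2` inverts this to set the noise for a target R²;
the study-scale configuration targets R² = 0.82 (σ_b ≈ 0.61 cycles). At
that setting, 50-cohort averages give a fitted R² ≈ 0.83 (small-sample
optimism over the population 0.82), LOOCV mean |residual| ≈ 4.1 days and
mean CI halfwidth ≈ 4.2 days.

The microarray generator plants four gene classes on a log₂ scale over a
balanced 2-sex × 4-age × n-rep design: age-only (random-sign linear trend
across age classes, total span `effect_size`, centred on the gene baseline
so up- and down-regulated genes face the signal filter symmetrically),
sex-only (offset), interaction (sex-antisymmetric trend with zero marginal
effects), and null. Raw fluorescence is baseline_mu·2^(log₂ signal). The
per-cell replication of the original pooled hybridizations is not stated
anywhere recoverable, so `n_reps` is exposed (default 3, the minimum giving
a comfortable interaction test).

What the generators do **not** emulate: amplification-efficiency variation,
probe-level artifacts (saturation, flags), batch and dye effects, nonlinear
or plateauing age profiles, and census-population age structure. Passing
tests therefore demonstrate correctness of the estimators under the stated
model, not field performance of the assay.

## Numerical choices and degenerate inputs

- `fit_redundancy` raises a collinearity error naming the dependent columns
  (pivoted QR) by default; the bootstrap/LOOCV chain instead uses the
  minimum-norm pseudoinverse solution, which coincides with OLS for
  full-rank data and remains exact for perfectly collinear noise-free data
  (where every gene is an affine function of age). This is why noise-free
  LOOCV returns the true age with zero-width CIs.
- Bootstrap refits are batched: B Gram matrices (p × p) are inverted per
  prediction via stacked pseudoinverse, keeping a 34-fold LOOCV at B = 1000
  under a second.
- Inversion requires |β| > 1e-8 (in units of the unit-variance training
  variate SD).
- Gene ranking breaks |loading| ties lexicographically for determinism.
- Replicate-SD QC threshold 0.5 cycles flags, never drops.
- Ct values must lie in (0, 45], the thermal-cycling budget.

## Problem sizes

Simulation-backed checks use the study-scale cohort (n = 34, 4 genes) with
50 seeds at B = 500 for residual/R² recovery, 200 simulated out-of-sample
predictions for CI coverage, and a 1000-gene array (100/50/50/800 planted
classes, σ = 0.25, 3 reps) for screening recovery — sizes at which each
quantity's Monte-Carlo error is small relative to the bands being checked
while the whole battery completes in well under a minute.
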