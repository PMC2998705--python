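# agegrade

Transcriptional age-grading of adult *Anopheles gambiae* mosquitoes.

The age distribution of female malaria vectors is one of the most sensitive
inputs to vectorial capacity: *Plasmodium* needs an extrinsic incubation
period of roughly 9–15 days inside the mosquito, so only the older fraction
of a population ever transmits. Yet field methods for estimating mosquito age
(ovariole dissection) are laborious and indirect. An alternative is to read
age off the transcriptome: a handful of genes whose expression rises or falls
steadily over adult life, measured by qRT-PCR, can be combined into a
calibrated molecular clock.

`agegrade` implements that workflow end to end, for entomologists and
quantitative epidemiologists who want to build or evaluate such an assay:

1. **Candidate screening** (`agegrade.screen`) — factorial microarray data
   (age × sex) are signal-filtered, normalized (threshold to 1.0, log₂,
   per-array 75th-percentile shift, per-gene median baseline), and tested
   gene-by-gene with a two-way ANOVA; Benjamini–Hochberg-corrected q ≤ 0.01
   for age with no sex or interaction effect defines the age-only set, gated
   by the correlation of the per-age profile with age (r > 0.8 up,
   r < −0.4 down).
2. **qRT-PCR normalization** (`agegrade.qpcr`) — triplicate Ct values are
   averaged and expressed as logcontrasts against the stable 40S ribosomal
   protein S7 reference: x<sub>ig</sub> = C̄t<sub>ig</sub> − C̄t<sub>i,ref</sub>,
   cancelling per-sample template-amount shifts.
3. **Calibration** (`agegrade.calibrate`) — with univariate age, redundancy
   analysis reduces to the linear combination v = Σ w<sub>g</sub> z<sub>ig</sub>
   of standardized logcontrasts maximizing corr(v, age) (the canonical =
   multiple correlation R); the calibration line v = α + β·age is fitted by
   least squares, and genes are ranked by |w<sub>g</sub>|.
4. **Prediction and validation** (`agegrade.predict`) — a new individual's
   age is the inverted line âge = (v − α)/β, with a 95% CI from a
   nonparametric pairs bootstrap that refits the whole chain on resampled
   training individuals; leave-one-out cross-validation and a
   residual-vs-predicted bias table quantify assay accuracy.
5. **Synthetic data** (`agegrade.simulate`) — generators for both platforms
   with planted ground truth (linear logcontrast–age gene profiles;
   age-only / sex-only / interaction array classes), so the whole pipeline is
   testable without any laboratory data.

## Worked example

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_screen_microarray.py
python analysis/03_fit_calibration.py
python analysis/04_validate_predictions.py
```

prints (abridged):

```
microarray: 1000 genes x 24 arrays, 200 genes with planted effects
qpcr cohort: 34 females + 35 males, 5 genes incl. reference, sigma_biological=0.606 cycles
947 genes passed the signal filter
100 age-only genes; recall of planted age genes 100.0%
100 candidates (57 up, 43 down); contamination 0.0%
F: n=34, R^2=0.8238, top gene AGAP012936-RA
M: n=35, R^2=0.8048, top gene AGAP012936-RA
LOOCV over 34 females:
  mean |residual|      3.72 days
  mean 95% CI halfwidth 4.02 days
```

Reading the numbers: the screen recovers every planted age-only gene with no
false candidates; the female calibration explains R² ≈ 0.82 of age variance
(the simulated cohorts are calibrated to that population value); and
held-out females are predicted to within ~4 days on average, with bootstrap
CIs of about ±4 days. Negative predicted ages can occur for newly eclosed
individuals and are reported as-is.

The same stages are available as a CLI (`agegrade simulate|screen|calibrate|
predict|validate`), each writing a JSON run manifest beside its outputs.

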