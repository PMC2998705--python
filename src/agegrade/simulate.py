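"""Synthetic-data generators with known ground truth.

Two generators emulate the two measurement platforms of the age-grading
study design:

* :func:`simulate_qpcr` — individual mosquitoes of known age and sex,
  measured by qRT-PCR in replicate for a panel of candidate genes plus a
  stably expressed reference gene (40S ribosomal protein S7).  Candidate
  genes follow linear logcontrast–age relationships of either sign.

* :func:`simulate_microarray` — pooled-sample expression arrays over a
  factorial age × sex design with planted age-only, sex-only, interaction
  and null genes, used to exercise the candidate-gene screening stage.

Both are deterministic given their config seed and share no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

DEFAULT_REFERENCE_GENE = "AGAP010592-RA"

#: Default candidate panel: the four age-informative transcripts carried by the
#: assay.  Up-regulated genes (expression rises with age) have *negative*
#: logcontrast slopes, because lower Ct means more transcript; one gene is
#: down-regulated (positive slope).  Slopes are in cycles/day, baselines in
#: cycles above the reference gene.
DEFAULT_QPCR_GENES: tuple[tuple[str, float, float], ...] = (
    ("AGAP006187-RA", 3.0, -0.08),
    ("AGAP010398-RA", 5.0, -0.06),
    ("AGAP012936-RA", 4.0, -0.07),
    ("AGAP007963-RA", 2.0, 0.05),
)

STUDY_AGES: tuple[int, ...] = (0, 5, 10, 15, 20, 25, 30)
ARRAY_AGES: tuple[int, ...] = (0, 10, 20, 30)


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class QpcrSimConfig:
    """Simulation parameters for the qRT-PCR cohort.

    Ages, per-cell counts and triplicate measurement mirror the study design:
    cohorts sampled at 0, 5, 10, 15, 20, 25 and 30 days post-eclosion, both
    sexes, five individuals per age × sex cell, each reaction in triplicate.
    ``drop_one_female`` removes one randomly chosen female so the totals are
    n=34 females / n=35 males.

    Noise model (all in cycles):

    * ``sigma_individual`` — SD of a per-individual shift shared by every
      well of that individual (template amount / extraction efficiency);
      cancels exactly in the logcontrast.
    * ``sigma_biological`` — SD of per-individual, per-gene biological
      deviation on the logcontrast (ΔCt) scale; the noise that limits
      calibration accuracy.
    * ``sigma_technical`` — between-replicate (well-to-well) SD.
    """

    ages: tuple[int, ...] = STUDY_AGES
    n_per_cell: int = 5
    genes: tuple[tuple[str, float, float], ...] = DEFAULT_QPCR_GENES
    ref_gene: str = DEFAULT_REFERENCE_GENE
    ref_mu: float = 16.0
    sigma_individual: float = 0.5
    sigma_biological: float = 0.6
    sigma_technical: float = 0.15
    n_replicates: int = 3
    drop_one_female: bool = True
    seed: int = 0

    def validate(self) -> None:
        _check(len(self.ages) > 0, "ages", "must be non-empty")
        _check(all(a >= 0 for a in self.ages), "ages", "must be non-negative")
        _check(
            all(b < a for b, a in zip(self.ages, self.ages[1:])),
            "ages",
            "must be strictly increasing",
        )
        _check(self.n_per_cell >= 1, "n_per_cell", "must be >= 1")
        _check(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _check(self.sigma_individual >= 0, "sigma_individual", "must be >= 0")
        _check(self.sigma_biological >= 0, "sigma_biological", "must be >= 0")
        _check(self.sigma_technical >= 0, "sigma_technical", "must be >= 0")
        _check(len(self.genes) > 0, "genes", "must list at least one gene")
        ids = [g[0] for g in self.genes]
        _check(len(set(ids)) == len(ids), "genes", "gene ids must be unique")
        _check(self.ref_gene not in ids, "genes", "must not include the reference gene")


def age_variance(ages: Sequence[float]) -> float:
    """Population variance of age under uniform sampling over the design ages."""
    a = np.asarray(ages, dtype=float)
    return float(np.mean((a - a.mean()) ** 2))


def biological_sigma_for_r2(
    target_r2: float,
    genes: Sequence[tuple[str, float, float]] = DEFAULT_QPCR_GENES,
    ages: Sequence[int] = STUDY_AGES,
    sigma_technical: float = 0.15,
    n_replicates: int = 3,
) -> float:
    """Biological SD that sets the *population* calibration R² to ``target_r2``.

    With independent logcontrast noise of total variance τ² per gene, the best
    linear combination of p genes with slopes s_g achieves

        R² = S·Var(age) / (S·Var(age) + τ²),   S = Σ_g s_g²,

    and τ² decomposes as σ_b² + 2σ_t²/m for m replicates of both target and
    reference wells.  Inverts for σ_b; raises if the technical term alone
    already exceeds the required τ².
    """
    _check(0 < target_r2 < 1, "target_r2", "must be in (0,1)")
    s2 = sum(g[2] ** 2 for g in genes)
    tau2 = s2 * age_variance(ages) * (1.0 - target_r2) / target_r2
    tech = 2.0 * sigma_technical**2 / n_replicates
    _check(tau2 >= tech, "sigma_technical", "technical noise alone exceeds the target τ²")
    return float(np.sqrt(tau2 - tech))


def female_study_config(seed: int = 0, target_r2: float = 0.82) -> QpcrSimConfig:
    """Study-scale female cohort: n=34, seven age classes, four genes, noise
    calibrated so the population calibration R² equals ``target_r2``."""
    sigma_b = biological_sigma_for_r2(target_r2)
    return QpcrSimConfig(sigma_biological=sigma_b, seed=seed)


@dataclass(frozen=True)
class ArraySimConfig:
    """Simulation parameters for the factorial microarray experiment.

    Fractions partition genes into planted classes (remainder = null).  The
    age-only effect is a per-gene random-sign linear trend across the age
    classes with total span ``effect_size`` (log2 units), centred on the gene
    baseline; sex-only is a sex offset of the same size; interaction is a
    sex-antisymmetric age trend (no marginal age or sex effect).  Noise is
    i.i.d. Normal on the log2 scale; raw fluorescence is
    ``baseline_mu · 2^(log2 signal)``.
    """

    n_genes: int = 1000
    ages: tuple[int, ...] = ARRAY_AGES
    sexes: tuple[str, ...] = ("F", "M")
    n_reps: int = 3
    frac_age_only: float = 0.10
    frac_sex_only: float = 0.05
    frac_interaction: float = 0.05
    effect_size: float = 2.0
    sigma: float = 0.25
    baseline_mu: float = 64.0
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_genes >= 1, "n_genes", "must be >= 1")
        _check(len(self.ages) >= 2, "ages", "need >= 2 age classes")
        _check(
            all(b < a for b, a in zip(self.ages, self.ages[1:])),
            "ages",
            "must be strictly increasing",
        )
        _check(len(self.sexes) >= 2, "sexes", "need >= 2 sex levels")
        _check(self.n_reps >= 2, "n_reps", "interaction ANOVA needs >= 2 arrays per cell")
        for name in ("frac_age_only", "frac_sex_only", "frac_interaction"):
            _check(getattr(self, name) >= 0, name, "must be >= 0")
        total = self.frac_age_only + self.frac_sex_only + self.frac_interaction
        _check(total <= 1.0 + 1e-12, "fractions", "must sum to <= 1")
        _check(self.sigma >= 0, "sigma", "must be >= 0")
        _check(self.baseline_mu > 0, "baseline_mu", "must be > 0")
        _check(self.effect_size >= 0, "effect_size", "must be >= 0")


def simulate_qpcr(config: QpcrSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a qRT-PCR cohort.

    Returns ``(ct_table, meta, truth)``:

    * ``ct_table`` — long format with columns sample_id, gene_id, replicate, ct;
    * ``meta`` — sample_id, sex, age_days;
    * ``truth`` — gene_id, slope (cycles/day), intercept (baseline ΔCt).

    Generative model: individual *i* of age *a* carries a shared Ct shift
    b_i ~ N(0, σ_ind²) and per-gene biological deviations d_ig ~ N(0, σ_bio²).
    Reference-gene wells are N(ref_mu + b_i, σ_tech²); candidate-gene wells are
    N(ref_mu + b_i + δ_g + slope_g·a + d_ig, σ_tech²).  The expected
    logcontrast is therefore δ_g + slope_g·a, independent of b_i.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    individuals: list[tuple[str, str, int]] = []  # (sample_id, sex, age)
    for sex in ("F", "M"):
        for age in config.ages:
            for k in range(config.n_per_cell):
                individuals.append((f"{sex}{age:02d}_{k}", sex, age))

    if config.drop_one_female:
        female_idx = [i for i, (_, s, _) in enumerate(individuals) if s == "F"]
        drop = rng.choice(female_idx)
        individuals = [ind for i, ind in enumerate(individuals) if i != drop]

    gene_ids = [g[0] for g in config.genes]
    deltas = np.array([g[1] for g in config.genes])
    slopes = np.array([g[2] for g in config.genes])
    n_ind = len(individuals)
    p = len(gene_ids)
    m = config.n_replicates

    b = rng.normal(0.0, config.sigma_individual, size=n_ind)
    d = rng.normal(0.0, config.sigma_biological, size=(n_ind, p))

    rows = []
    for i, (sid, _sex, age) in enumerate(individuals):
        ref_wells = rng.normal(config.ref_mu + b[i], config.sigma_technical, size=m)
        for r in range(m):
            rows.append((sid, config.ref_gene, r + 1, ref_wells[r]))
        means = config.ref_mu + b[i] + deltas + slopes * age + d[i]
        wells = rng.normal(means[None, :], config.sigma_technical, size=(m, p))
        for g, gid in enumerate(gene_ids):
            for r in range(m):
                rows.append((sid, gid, r + 1, wells[r, g]))

    ct_table = pd.DataFrame(rows, columns=["sample_id", "gene_id", "replicate", "ct"])
    meta = pd.DataFrame(
        [(sid, sex, age) for sid, sex, age in individuals],
        columns=["sample_id", "sex", "age_days"],
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "slope": slopes, "intercept": deltas}
    )
    return ct_table, meta, truth


def simulate_microarray(
    config: ArraySimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a raw fluorescence matrix over a balanced age × sex design.

    Returns ``(raw, meta, truth)``: ``raw`` is genes × arrays (index gene_id,
    columns array ids, raw fluorescence), ``meta`` has one row per array
    (array_id, age_days, sex), ``truth`` labels each gene with its planted
    class (age_only | sex_only | interaction | null).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_genes
    n_age = int(round(config.frac_age_only * n))
    n_sex = int(round(config.frac_sex_only * n))
    n_int = int(round(config.frac_interaction * n))
    classes = np.array(
        ["age_only"] * n_age
        + ["sex_only"] * n_sex
        + ["interaction"] * n_int
        + ["null"] * (n - n_age - n_sex - n_int)
    )
    gene_ids = [f"G{i:05d}" for i in range(n)]

    ages = np.array(config.ages, dtype=float)
    k = len(ages)
    # centred linear ramp over age index, total span 1
    ramp = (np.arange(k) / (k - 1)) - 0.5

    arrays = []
    for sex in config.sexes:
        for ai, age in enumerate(config.ages):
            for r in range(config.n_reps):
                arrays.append((f"A_{sex}{age:02d}_{r}", age, sex, ai))
    array_ids = [a[0] for a in arrays]
    meta = pd.DataFrame(
        [(aid, age, sex) for aid, age, sex, _ in arrays],
        columns=["array_id", "age_days", "sex"],
    )

    baseline = rng.uniform(0.0, 4.0, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)

    age_idx = np.array([ai for _, _, _, ai in arrays])
    sex_sign = np.array([1.0 if s == config.sexes[0] else -1.0 for _, _, s, _ in arrays])

    log2 = np.tile(baseline[:, None], (1, len(arrays)))
    es = config.effect_size
    for g in range(n):
        if classes[g] == "age_only":
            log2[g] += sign[g] * es * ramp[age_idx]
        elif classes[g] == "sex_only":
            log2[g] += sign[g] * es * (sex_sign > 0) * 1.0
        elif classes[g] == "interaction":
            log2[g] += sign[g] * sex_sign * es * ramp[age_idx]
    if config.sigma > 0:
        log2 += rng.normal(0.0, config.sigma, size=log2.shape)

    raw = pd.DataFrame(
        config.baseline_mu * np.exp2(log2), index=pd.Index(gene_ids, name="gene_id"),
        columns=array_ids,
    )
    truth = pd.DataFrame({"gene_id": gene_ids, "class": classes})
    return raw, meta, truth
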