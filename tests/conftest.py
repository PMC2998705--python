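"""Shared fixtures: simulated cohorts at the study's design points."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import agegrade as ag


def split_by_sex(ct: pd.DataFrame, meta: pd.DataFrame, sex: str = "F"):
    """Logcontrast matrix and known ages for one sex."""
    x, _ = ag.ct_to_logcontrast(ct)
    m = meta.set_index("sample_id").loc[x.index]
    keep = (m["sex"] == sex).to_numpy()
    return x[keep], m.loc[keep, "age_days"].to_numpy(float)


@pytest.fixture(scope="session")
def noise_free_females():
    """n=34 females, 4 genes, all noise terms zero: every gene column is an
    exact affine function of age."""
    cfg = ag.QpcrSimConfig(
        sigma_individual=0.0, sigma_biological=0.0, sigma_technical=0.0, seed=2
    )
    ct, meta, truth = ag.simulate_qpcr(cfg)
    x, ages = split_by_sex(ct, meta, "F")
    return x, ages, truth


@pytest.fixture(scope="session")
def study_scale_females():
    """n=34 females, noise calibrated so the population calibration R² = 0.82."""
    ct, meta, _ = ag.simulate_qpcr(ag.female_study_config(seed=3))
    return split_by_sex(ct, meta, "F")


@pytest.fixture(scope="session")
def planted_array():
    """1000-gene factorial array simulation with planted effect classes
    (100 age-only, 50 sex-only, 50 interaction, 800 null)."""
    cfg = ag.ArraySimConfig(
        n_genes=1000,
        frac_age_only=0.10,
        frac_sex_only=0.05,
        frac_interaction=0.05,
        effect_size=2.0,
        sigma=0.25,
        n_reps=3,
        seed=5,
    )
    return ag.simulate_microarray(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
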