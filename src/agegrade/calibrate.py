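"""Redundancy-variate calibration of gene expression against known age.

With a univariate response (age), redundancy analysis reduces to finding the
linear combination of standardized logcontrast measures that maximizes the
Pearson correlation with age — equivalently, the fitted values of the
least-squares regression of age on the standardized gene matrix, rescaled to
unit variance.  The achieved correlation is the canonical (multiple)
correlation R, and the regression of the variate on age,

    v = α + β·age,

is the calibration model, later inverted ("inverse regression") to convert a
new individual's variate score into an age estimate.

Conventions: gene columns are z-scored with training statistics so the
loadings w_g are comparable across genes (larger |w_g| = more informative);
the variate has mean 0 and sample variance 1 on the training data; its sign
is fixed so that corr(v, age) >= 0, hence β > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr

from .errors import CollinearityError, DataError, InputError, ModelError


@dataclass(frozen=True)
class RedundancyModel:
    """Standardization constants and loadings of the redundancy variate."""

    gene_ids: tuple[str, ...]
    mu: np.ndarray  # training means, cycles
    sd: np.ndarray  # training SDs (ddof=1), cycles
    weights: np.ndarray  # loadings on standardized values
    canonical_correlation: float

    def __post_init__(self):
        for name in ("mu", "sd", "weights"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass(frozen=True)
class CalibrationModel:
    """Calibration line of the redundancy variate on age."""

    redundancy: RedundancyModel
    alpha: float  # intercept, variate units
    beta: float  # slope, variate units per day
    r_squared: float
    n: int
    sex_label: str | None = None


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(str(c) for c in X.columns)
    arr = np.asarray(X, dtype=float)
    return arr, tuple(f"g{j}" for j in range(arr.shape[1]))


def fit_redundancy(
    X, ages, *, on_collinear: str = "raise"
) -> RedundancyModel:
    """Fit the redundancy variate maximizing |corr(variate, age)|.

    ``X`` is a samples × genes DataFrame (or array) of logcontrast values;
    ``ages`` the known ages in days.  The maximizer over linear combinations
    of the z-scored columns is the least-squares direction of the regression
    of centred age on the standardized matrix; the loadings are rescaled so
    the training variate has unit sample variance, with sign fixed so the
    variate increases with age.

    ``on_collinear='raise'`` (default) raises :class:`CollinearityError`
    naming the linearly dependent columns; ``'least_norm'`` takes the
    minimum-norm solution instead, which is well defined even for exactly
    collinear (e.g. noise-free) data.
    """
    Z, gene_ids, mu, sd, a = _standardize(X, ages)
    n, p = Z.shape
    if n <= p + 1:
        raise ModelError(f"need n > p + 1 samples (got n={n}, p={p})")

    if on_collinear not in ("raise", "least_norm"):
        raise InputError(f"on_collinear must be 'raise' or 'least_norm', not {on_collinear!r}")
    if on_collinear == "raise":
        _, R, piv = qr(Z, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.size else 0.0
        rank = int((diag > tol).sum())
        if rank < p:
            dependent = sorted(gene_ids[j] for j in piv[rank:])
            raise CollinearityError(
                f"collinear gene columns: {', '.join(dependent)}"
            )

    ac = a - a.mean()
    c, *_ = np.linalg.lstsq(Z, ac, rcond=None)
    raw = Z @ c
    sd_raw = raw.std(ddof=1)
    if sd_raw <= 0:
        raise ModelError("genes carry no linear age signal (zero-variance variate)")
    w = c / sd_raw
    v = raw / sd_raw
    r = float(v @ ac / ((n - 1) * ac.std(ddof=1)))
    return RedundancyModel(gene_ids, mu, sd, w, canonical_correlation=r)


def _standardize(X, ages):
    M, gene_ids = _as_matrix(X)
    a = np.asarray(ages, dtype=float)
    if M.ndim != 2:
        raise InputError("X must be two-dimensional (samples x genes)")
    if len(a) != M.shape[0]:
        raise InputError("ages length must match the number of samples")
    if not np.all(np.isfinite(M)):
        raise InputError("X contains non-finite values")
    if np.ptp(a) == 0:
        raise ModelError("constant age: calibration needs age variation")
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd <= 0)
    if zero.size:
        raise ModelError(f"constant gene column: {gene_ids[zero[0]]!r}")
    return (M - mu) / sd, gene_ids, mu, sd, a


def score_variate(model: RedundancyModel, x) -> float | np.ndarray:
    """Redundancy-variate score of one sample (or a matrix of samples),
    using the *training* standardization constants."""
    if isinstance(x, pd.DataFrame):
        missing = [g for g in model.gene_ids if g not in x.columns]
        if missing:
            raise DataError(f"sample missing gene value(s): {', '.join(missing)}")
        arr = x[list(model.gene_ids)].to_numpy(dtype=float)
    elif isinstance(x, pd.Series):
        missing = [g for g in model.gene_ids if g not in x.index]
        if missing:
            raise DataError(f"sample missing gene value(s): {', '.join(missing)}")
        arr = x[list(model.gene_ids)].to_numpy(dtype=float)
    else:
        arr = np.asarray(x, dtype=float)
        if arr.shape[-1] != len(model.gene_ids):
            raise DataError(
                f"expected {len(model.gene_ids)} gene values, got {arr.shape[-1]}"
            )
    if not np.all(np.isfinite(arr)):
        raise DataError("missing/non-finite gene value in sample")
    z = (arr - model.mu) / model.sd
    out = z @ model.weights
    return float(out) if np.ndim(out) == 0 else out


def fit_calibration(
    variates, ages, redundancy: RedundancyModel, sex_label: str | None = None
) -> CalibrationModel:
    """Least-squares line v = α + β·age of the training variates on age.

    R² is the squared Pearson correlation of variate and age; when the
    variates come from ``redundancy`` on the same training data it equals the
    squared canonical correlation.
    """
    v = np.asarray(variates, dtype=float)
    a = np.asarray(ages, dtype=float)
    if np.ptp(a) == 0:
        raise ModelError("constant age: calibration needs age variation")
    ac = a - a.mean()
    beta = float(v @ ac / (ac @ ac))
    alpha = float(v.mean() - beta * a.mean())
    vc = v - v.mean()
    denom = np.sqrt((vc @ vc) * (ac @ ac))
    r2 = float((vc @ ac) ** 2 / denom**2) if denom > 0 else 0.0
    return CalibrationModel(
        redundancy=redundancy,
        alpha=alpha,
        beta=beta,
        r_squared=r2,
        n=len(v),
        sex_label=sex_label,
    )


def fit_age_model(
    X, ages, sex_label: str | None = None, *, on_collinear: str = "raise"
) -> CalibrationModel:
    """Full chain: redundancy variate then calibration line."""
    red = fit_redundancy(X, ages, on_collinear=on_collinear)
    v = score_variate(red, X if not isinstance(X, pd.DataFrame) else X)
    return fit_calibration(v, ages, red, sex_label=sex_label)


def rank_genes(model: RedundancyModel) -> list[str]:
    """Genes ordered by |loading| descending; ties broken lexicographically."""
    order = sorted(
        range(len(model.gene_ids)),
        key=lambda j: (-abs(model.weights[j]), model.gene_ids[j]),
    )
    return [model.gene_ids[j] for j in order]


def select_informative_genes(
    X, ages, k: int, sex_label: str | None = None
) -> tuple[list[str], CalibrationModel]:
    """Top-k genes by |loading| of the full fit, with the model refitted on
    that subset (mirrors the assay's reduction from nine candidates to four)."""
    M, gene_ids = _as_matrix(X)
    p = M.shape[1]
    if not (1 <= k <= p):
        raise InputError(f"k must lie in [1, {p}], got {k}")
    full = fit_redundancy(X, ages)
    top = rank_genes(full)[:k]
    idx = [gene_ids.index(g) for g in top]
    if isinstance(X, pd.DataFrame):
        sub = X[top]
    else:
        sub = M[:, idx]
    return top, fit_age_model(sub, ages, sex_label=sex_label)
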