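"""Inverse-regression age prediction, bootstrap confidence intervals, and
leave-one-out cross-validation.

A new individual's age estimate is the calibration line solved for age:
age = (v − α)/β with v the individual's redundancy-variate score.  Estimates
are deliberately unclipped — near age zero the calibration error can produce
negative estimates, which are reported as-is.

Uncertainty comes from a nonparametric pairs bootstrap: the n training
individuals are resampled with replacement, the *whole* estimation chain
(standardization, redundancy loadings, calibration line) is refitted on each
resample, and the held-out individual's plug-in age is recomputed.  The 95%
CI is the 2.5th–97.5th percentile of the bootstrap distribution and the
reported predicted age is its median (which necessarily lies inside the CI).
Resamples with constant age, a constant gene column, or a zero-variance
variate are rejected and redrawn.

Validation is leave-one-out: each individual is predicted by a model trained
on the others, with per-sample bootstrap seeds derived deterministically from
(master seed, sample id) so results are independent of sample order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import CalibrationModel, fit_age_model, score_variate
from .errors import ConfigError, DataError, InvertibilityError, ModelError

BETA_TOLERANCE = 1e-8  # relative to the (unit) SD of training variates


@dataclass(frozen=True)
class AgePrediction:
    sample_id: str
    plug_in_age: float
    predicted_age: float  # median of the bootstrap distribution
    ci_low: float
    ci_high: float
    n_bootstrap: int
    seed: int
    n_redraws: int = 0


def predict_age(model: CalibrationModel, x) -> float:
    """Plug-in inverse-regression age estimate (days), unclipped."""
    if abs(model.beta) <= BETA_TOLERANCE:
        raise InvertibilityError(
            f"calibration slope {model.beta:.3g} too close to zero to invert"
        )
    v = score_variate(model.redundancy, x)
    return (v - model.alpha) / model.beta


def _chain_plug_in(Xb: np.ndarray, ab: np.ndarray, xnew: np.ndarray) -> np.ndarray:
    """Batched full-chain plug-in ages.

    ``Xb``: (B, n, p) resampled training matrices; ``ab``: (B, n) resampled
    ages; ``xnew``: (p,) the individual to predict.  Uses the minimum-norm
    least-squares direction (pseudoinverse of the p×p Gram matrix), which
    coincides with the unique OLS solution whenever the standardized matrix
    has full column rank and remains well defined for exactly collinear
    (noise-free) data.  Returns (B,) ages; NaN marks degenerate resamples.
    """
    B, n, p = Xb.shape
    mu = Xb.mean(axis=1)
    Zc = Xb - mu[:, None, :]
    sd = np.sqrt((Zc**2).sum(axis=1) / (n - 1))
    bad = (sd <= 0).any(axis=1)
    sd_safe = np.where(sd <= 0, 1.0, sd)
    Z = Zc / sd_safe[:, None, :]

    abar = ab.mean(axis=1)
    ac = ab - abar[:, None]
    bad |= (ac**2).sum(axis=1) <= 0

    A = np.einsum("bnp,bnq->bpq", Z, Z)
    rhs = np.einsum("bnp,bn->bp", Z, ac)
    c = np.einsum("bpq,bq->bp", np.linalg.pinv(A, hermitian=True), rhs)

    var_raw = np.einsum("bp,bpq,bq->b", c, A, c) / (n - 1)
    bad |= var_raw <= 0
    sd_raw = np.sqrt(np.where(var_raw <= 0, 1.0, var_raw))
    w = c / sd_raw[:, None]

    v = np.einsum("bnp,bp->bn", Z, w)  # training variates, mean 0, var 1
    beta = np.einsum("bn,bn->b", v, ac) / (ac**2).sum(axis=1)
    alpha = -beta * abar  # variate mean is 0
    bad |= np.abs(beta) <= BETA_TOLERANCE

    znew = (xnew[None, :] - mu) / sd_safe
    vnew = np.einsum("bp,bp->b", znew, w)
    age = (vnew - alpha) / np.where(bad, 1.0, beta)
    return np.where(bad, np.nan, age)


def bootstrap_predict(
    X,
    ages,
    x,
    B: int = 1000,
    seed: int = 0,
    sample_id: str = "",
    model: CalibrationModel | None = None,
) -> AgePrediction:
    """Bootstrap age prediction for one individual.

    ``X``/``ages`` are the training logcontrasts and known ages; ``x`` the
    individual's logcontrast values.  Resamples the training individuals with
    replacement ``B`` times, refits the whole chain per resample, and returns
    the bootstrap median with the 95% percentile CI.  Deterministic given
    ``seed``.  Raises :class:`DataError` when more than half the draws are
    degenerate.
    """
    if B < 100:
        raise ConfigError(f"B must be >= 100 (got {B})")
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    a = np.asarray(ages, dtype=float)
    n = Xm.shape[0]

    if model is None:
        model = fit_age_model(X, ages, on_collinear="least_norm")
    if isinstance(x, (pd.Series, pd.DataFrame)):
        xv = (
            x[list(model.redundancy.gene_ids)].to_numpy(dtype=float).reshape(-1)
        )
    else:
        xv = np.asarray(x, dtype=float).reshape(-1)
    plug_in = predict_age(model, xv)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    est = _chain_plug_in(Xm[idx], a[idx], xv)

    redraws = 0
    passes = 0
    while np.isnan(est).any():
        bad = np.flatnonzero(np.isnan(est))
        redraws += bad.size
        if redraws > B // 2:
            raise DataError(
                f"bootstrap for {sample_id or 'sample'}: >{B // 2} degenerate "
                "resamples; data too degenerate to bootstrap"
            )
        idx_new = rng.integers(0, n, size=(bad.size, n))
        est[bad] = _chain_plug_in(Xm[idx_new], a[idx_new], xv)
        passes += 1
        if passes > 1000:  # pragma: no cover - safety valve
            raise DataError("bootstrap redraw did not converge")

    lo, hi = np.percentile(est, [2.5, 97.5])
    return AgePrediction(
        sample_id=sample_id,
        plug_in_age=float(plug_in),
        predicted_age=float(np.median(est)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_bootstrap=B,
        seed=seed,
        n_redraws=redraws,
    )


def child_seed(master_seed: int, sample_id: str) -> int:
    """Deterministic, order-invariant per-sample seed (< 2^31)."""
    return int((master_seed * 2654435761 + zlib.crc32(sample_id.encode())) % (2**31))


@dataclass
class ValidationReport:
    """Leave-one-out validation summary."""

    predictions: pd.DataFrame  # per-sample table
    mean_abs_residual: float
    mean_ci_halfwidth: float
    bias_slope: float
    bias_intercept: float


def loocv(X: pd.DataFrame, ages, B: int = 1000, seed: int = 0) -> ValidationReport:
    """Leave-one-out cross-validated age predictions with bootstrap CIs.

    For each individual, the redundancy variate and calibration line are
    refitted on the remaining n−1 individuals and the held-out individual is
    predicted by :func:`bootstrap_predict`.  Residuals are bootstrap-median
    predictions minus true age.  Per-sample failures are recorded in the
    table (``error`` column), not fatal to the whole run.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, float))
        X.index = [f"s{i}" for i in range(len(X))]
    a = np.asarray(ages, dtype=float)
    n, p = X.shape
    if n < p + 3:
        raise ModelError(f"LOOCV needs n >= p + 3 (got n={n}, p={p})")

    # canonical row order: resampling then depends only on sample ids, not on
    # the order the caller happened to pass the rows in
    order = np.argsort(X.index.astype(str))
    X = X.iloc[order]
    a = a[order]

    rows = []
    for i, sid in enumerate(X.index):
        keep = np.arange(n) != i
        try:
            pred = bootstrap_predict(
                X.iloc[keep],
                a[keep],
                X.iloc[i],
                B=B,
                seed=child_seed(seed, str(sid)),
                sample_id=str(sid),
            )
            rows.append(
                {
                    "sample_id": str(sid),
                    "true_age": a[i],
                    "plug_in_age": pred.plug_in_age,
                    "predicted_age": pred.predicted_age,
                    "ci_low": pred.ci_low,
                    "ci_high": pred.ci_high,
                    "residual": pred.predicted_age - a[i],
                    "n_redraws": pred.n_redraws,
                    "error": "",
                }
            )
        except (DataError, ModelError, InvertibilityError) as exc:
            rows.append(
                {
                    "sample_id": str(sid),
                    "true_age": a[i],
                    "plug_in_age": np.nan,
                    "predicted_age": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "residual": np.nan,
                    "n_redraws": 0,
                    "error": str(exc),
                }
            )
    table = pd.DataFrame(rows)
    ok = table["error"] == ""
    mar = float(table.loc[ok, "residual"].abs().mean())
    mch = float(((table.loc[ok, "ci_high"] - table.loc[ok, "ci_low"]) / 2).mean())
    slope, intercept = _bias_fit(
        table.loc[ok, "predicted_age"].to_numpy(),
        table.loc[ok, "residual"].to_numpy(),
    )
    return ValidationReport(
        predictions=table,
        mean_abs_residual=mar,
        mean_ci_halfwidth=mch,
        bias_slope=slope,
        bias_intercept=intercept,
    )


def _bias_fit(predicted: np.ndarray, residuals: np.ndarray) -> tuple[float, float]:
    if len(predicted) < 2 or np.ptp(predicted) == 0:
        return float("nan"), float("nan")
    fit = stats.linregress(predicted, residuals)
    return float(fit.slope), float(fit.intercept)


def bias_diagnostic(
    report: ValidationReport, x_axis: str = "predicted"
) -> tuple[float, float, float, pd.DataFrame]:
    """Regression of signed residuals on predicted (default) or true age.

    Returns (slope, intercept, p_value_slope, table); the table is the
    diagnostic scatter for external plotting.

    Caveat for interpreting the default: even for a perfectly specified
    model, residuals correlate *mechanically* with the predicted age that
    contains them (slope ≈ Var(e)/Var(â)); a slope of that size is expected,
    not evidence of bias.  Against true age (``x_axis='true'``) a correctly
    specified inverse-regression model has slope ≈ 0, so that axis is the
    sharper misspecification probe.
    """
    ok = report.predictions["error"] == ""
    if x_axis not in ("predicted", "true"):
        raise ModelError(f"x_axis must be 'predicted' or 'true', not {x_axis!r}")
    col = "predicted_age" if x_axis == "predicted" else "true_age"
    pred = report.predictions.loc[ok, col].to_numpy(dtype=float)
    resid = report.predictions.loc[ok, "residual"].to_numpy(dtype=float)
    if len(pred) < 3:
        raise ModelError("bias diagnostic needs >= 3 predictions")
    if np.ptp(pred) == 0:
        raise ModelError(f"constant {x_axis} ages: bias diagnostic undefined")
    fit = stats.linregress(pred, resid)
    table = pd.DataFrame({col: pred, "residual": resid})
    return float(fit.slope), float(fit.intercept), float(fit.pvalue), table
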