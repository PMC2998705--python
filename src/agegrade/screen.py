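"""Microarray candidate-gene screening.

Pipeline: low-signal filtering on raw fluorescence, the one-colour
normalization chain (threshold to 1.0 → log2 → per-array 75th-percentile
shift → per-gene median baseline), per-gene two-way fixed-effects ANOVA
(age, sex, age × sex) with Benjamini–Hochberg correction per effect, then
selection of genes significant for age only, annotated with the correlation
of their per-age mean profile with age and their maximal fold change.

Candidate calls: an age-only gene is an up-candidate when its profile
correlation exceeds ``r_up`` (default 0.8) and a down-candidate when it falls
below ``r_down`` (default −0.4); a fourfold-change annotation is recorded but
is not a hard gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DesignError, InputError


def filter_low_signal(
    raw: pd.DataFrame,
    percentile: float = 20.0,
    min_arrays_above: int = 1,
    flags: pd.DataFrame | None = None,
) -> list[str]:
    """Genes retained by the raw-signal filter (order preserved).

    The cutoff is the given percentile of all raw values pooled across the
    whole matrix; a gene is retained iff its raw value strictly exceeds the
    cutoff in at least ``min_arrays_above`` arrays.  If a boolean ``flags``
    matrix (same shape; True = feature uniform/present) is supplied, a gene
    must additionally be flagged in at least one array.
    """
    if raw.size == 0:
        raise InputError("expression matrix is empty")
    if not (0 < percentile < 100):
        raise InputError("percentile must lie strictly between 0 and 100")
    values = raw.to_numpy(dtype=float)
    if np.any(values < 0):
        raise InputError("raw fluorescence must be >= 0")
    cutoff = np.percentile(values, percentile)
    keep = (values > cutoff).sum(axis=1) >= min_arrays_above
    if flags is not None:
        keep &= flags.reindex(index=raw.index, columns=raw.columns).to_numpy(bool).any(axis=1)
    return [g for g, k in zip(raw.index, keep) if k]


def normalize_signals(raw: pd.DataFrame) -> pd.DataFrame:
    """One-colour normalization chain on a genes × arrays matrix.

    Values below 1.0 are clamped to 1.0; log2 is applied; each array is
    shifted by its own 75th percentile of log2 values; each gene is then
    centred on its median across arrays.  After the last step every gene's
    median across arrays is zero, and arrays differing only by a
    multiplicative constant become identical.
    """
    if raw.size == 0:
        raise InputError("expression matrix is empty")
    values = raw.to_numpy(dtype=float)
    if np.any(values < 0):
        raise InputError("raw fluorescence must be >= 0 (negative value found)")
    log2 = np.log2(np.maximum(values, 1.0))
    log2 = log2 - np.percentile(log2, 75, axis=0, keepdims=True)
    log2 = log2 - np.median(log2, axis=1, keepdims=True)
    return pd.DataFrame(log2, index=raw.index, columns=raw.columns)


def _design_arrays(meta: pd.DataFrame, columns) -> tuple[np.ndarray, np.ndarray]:
    meta = meta.set_index("array_id").loc[list(columns)]
    return meta["age_days"].to_numpy(), meta["sex"].to_numpy()


def two_way_anova(
    normalized: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene two-way fixed-effects ANOVA with interaction.

    Factors are age (categorical) and sex; every gene is tested for the age
    main effect, sex main effect and age × sex interaction.  Balanced designs
    use the closed-form sums-of-squares decomposition (all classical SS types
    coincide); unbalanced designs fall back to type-II SS via statsmodels.

    Returns a frame indexed by gene with columns p_age, p_sex, p_interaction
    (and the F statistics).  Genes with zero total variance return p = 1 for
    every effect.
    """
    if not set(meta["array_id"]) >= set(normalized.columns):
        missing = sorted(set(normalized.columns) - set(meta["array_id"]))
        raise DataError(f"arrays missing from metadata: {missing[:5]}")
    age, sex = _design_arrays(meta, normalized.columns)
    age_levels = np.unique(age)
    sex_levels = np.unique(sex)
    if len(age_levels) < 2 or len(sex_levels) < 2:
        raise DesignError("need >= 2 levels of both age and sex")

    cell_of = {(a, s): [] for a in age_levels for s in sex_levels}
    for j, (a, s) in enumerate(zip(age, sex)):
        cell_of[(a, s)].append(j)
    counts = {c: len(idx) for c, idx in cell_of.items()}
    for cell, cnt in counts.items():
        if cnt == 0:
            raise DesignError(f"empty design cell age={cell[0]}, sex={cell[1]}")
        if cnt < 2:
            raise DesignError(
                f"single replicate in cell age={cell[0]}, sex={cell[1]}; "
                "interaction term requires >= 2"
            )
    balanced = len(set(counts.values())) == 1

    if balanced:
        return _anova_balanced(normalized, age, sex, age_levels, sex_levels)
    return _anova_type2(normalized, age, sex)


def _anova_balanced(normalized, age, sex, age_levels, sex_levels):
    """Vectorised classical SS decomposition for balanced designs."""
    y = normalized.to_numpy(dtype=float)
    n_genes, n_arrays = y.shape
    a_n, s_n = len(age_levels), len(sex_levels)
    r = n_arrays // (a_n * s_n)

    grand = y.mean(axis=1, keepdims=True)
    age_masks = [age == a for a in age_levels]
    sex_masks = [sex == s for s in sex_levels]

    m_age = np.stack([y[:, m].mean(axis=1) for m in age_masks], axis=1)
    m_sex = np.stack([y[:, m].mean(axis=1) for m in sex_masks], axis=1)
    ss_age = r * s_n * ((m_age - grand) ** 2).sum(axis=1)
    ss_sex = r * a_n * ((m_sex - grand) ** 2).sum(axis=1)

    ss_int = np.zeros(n_genes)
    ss_res = np.zeros(n_genes)
    for ai, am in enumerate(age_masks):
        for si, sm in enumerate(sex_masks):
            cm = am & sm
            cell_mean = y[:, cm].mean(axis=1)
            dev = cell_mean - m_age[:, ai] - m_sex[:, si] + grand[:, 0]
            ss_int += r * dev**2
            ss_res += ((y[:, cm] - cell_mean[:, None]) ** 2).sum(axis=1)

    df = {
        "age": a_n - 1,
        "sex": s_n - 1,
        "interaction": (a_n - 1) * (s_n - 1),
    }
    df_res = a_n * s_n * (r - 1)
    ss_tot = ((y - grand) ** 2).sum(axis=1)
    degenerate = ss_tot <= 1e-12 * np.maximum(1.0, np.abs(grand[:, 0]))

    out = {}
    ms_res = ss_res / df_res
    for name, ss in (("age", ss_age), ("sex", ss_sex), ("interaction", ss_int)):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / df[name]) / ms_res
            p = stats.f.sf(f, df[name], df_res)
        p = np.where(np.isnan(f), 1.0, p)  # 0/0: no effect, no residual
        p = np.where(degenerate, 1.0, p)
        f = np.where(degenerate | np.isnan(f), 0.0, f)
        out[f"F_{name}"] = f
        out[f"p_{name}"] = p
    return pd.DataFrame(out, index=normalized.index)


def _anova_type2(normalized, age, sex):
    """Per-gene type-II ANOVA via statsmodels for unbalanced designs."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rows = []
    base = pd.DataFrame({"age": pd.Categorical(age), "sex": pd.Categorical(sex)})
    for gene in normalized.index:
        d = base.copy()
        d["y"] = normalized.loc[gene].to_numpy(dtype=float)
        if np.ptp(d["y"].to_numpy()) <= 1e-12:
            rows.append((0.0, 1.0, 0.0, 1.0, 0.0, 1.0))
            continue
        fit = smf.ols("y ~ C(age) * C(sex)", data=d).fit()
        tab = anova_lm(fit, typ=2)
        rows.append(
            (
                tab.loc["C(age)", "F"],
                tab.loc["C(age)", "PR(>F)"],
                tab.loc["C(sex)", "F"],
                tab.loc["C(sex)", "PR(>F)"],
                tab.loc["C(age):C(sex)", "F"],
                tab.loc["C(age):C(sex)", "PR(>F)"],
            )
        )
    return pd.DataFrame(
        rows,
        index=normalized.index,
        columns=["F_age", "p_age", "F_sex", "p_sex", "F_interaction", "p_interaction"],
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in the input order.

    q_(i) = min_{j >= i} p_(j)·m/j, clipped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InputError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_age_only(result: pd.DataFrame, alpha: float = 0.01) -> list[str]:
    """Genes significant for age and for neither sex nor interaction,
    at BH-adjusted level ``alpha``."""
    needed = {"q_age", "q_sex", "q_interaction"}
    if not needed <= set(result.columns):
        raise DataError("q-values not computed; run the screen first")
    mask = (
        (result["q_age"] <= alpha)
        & (result["q_sex"] > alpha)
        & (result["q_interaction"] > alpha)
    )
    return list(result.index[mask.fillna(False)])


def profile_stats(
    normalized: pd.DataFrame, meta: pd.DataFrame, per: str = "age_means"
) -> pd.DataFrame:
    """Per-gene age-profile correlation and maximal fold change.

    ``r_age`` is the Pearson correlation between the per-age mean normalized
    expression and age (one point per age class; ``per='arrays'`` correlates
    individual arrays instead).  ``max_fold_change`` is 2^(max − min of the
    per-age means) on the linear scale.  A gene whose age profile has zero
    variance gets r_age = 0 (and fold change 1).
    """
    age, _ = _design_arrays(meta, normalized.columns)
    ages = np.unique(age)
    if len(ages) < 3:
        raise DesignError("profile correlation needs >= 3 distinct ages")
    y = normalized.to_numpy(dtype=float)
    means = np.stack([y[:, age == a].mean(axis=1) for a in ages], axis=1)

    if per == "age_means":
        xs = ages.astype(float)
        prof = means
    elif per == "arrays":
        xs = age.astype(float)
        prof = y
    else:
        raise InputError(f"per must be 'age_means' or 'arrays', not {per!r}")

    xc = xs - xs.mean()
    pc = prof - prof.mean(axis=1, keepdims=True)
    denom = np.sqrt((pc**2).sum(axis=1) * (xc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc @ xc) / denom
    r = np.where(denom <= 0, 0.0, r)
    fc = np.exp2(means.max(axis=1) - means.min(axis=1))
    return pd.DataFrame({"r_age": r, "max_fold_change": fc}, index=normalized.index)


@dataclass(frozen=True)
class ScreenParams:
    """Thresholds of the screening stage (defaults are the study settings)."""

    signal_percentile: float = 20.0
    min_arrays_above: int = 1
    alpha: float = 0.01
    r_up: float = 0.8
    r_down: float = -0.4
    fc_min: float = 4.0


def select_candidates(
    result: pd.DataFrame,
    r_up: float = 0.8,
    r_down: float = -0.4,
    fc_min: float = 4.0,
) -> pd.DataFrame:
    """Annotate age-only genes as up/down candidates by profile correlation.

    Strict inequalities: r_age must exceed ``r_up`` (up) or fall below
    ``r_down`` (down).  ``fc_ge_min`` records whether the maximal fold change
    reaches ``fc_min``; it is an annotation, not a filter.
    """
    res = result.copy()
    age_only = res["age_only"].fillna(False).astype(bool)
    res["candidate_up"] = age_only & (res["r_age"] > r_up)
    res["candidate_down"] = age_only & (res["r_age"] < r_down)
    res["fc_ge_min"] = res["max_fold_change"] >= fc_min
    return res


def screen(
    raw: pd.DataFrame,
    meta: pd.DataFrame,
    params: ScreenParams = ScreenParams(),
    flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the full screening pipeline on a raw fluorescence matrix.

    Returns one row per input gene with the filter verdict, ANOVA p/q-values
    (NaN for genes failing the signal filter; BH correction is applied per
    effect across tested genes only), profile statistics, and the age_only /
    candidate_up / candidate_down / fc_ge_min flags.
    """
    kept = filter_low_signal(
        raw, params.signal_percentile, params.min_arrays_above, flags=flags
    )
    normalized = normalize_signals(raw)
    tested = normalized.loc[kept]

    anova = two_way_anova(tested, meta)
    for eff in ("age", "sex", "interaction"):
        anova[f"q_{eff}"] = bh_adjust(anova[f"p_{eff}"].to_numpy())
    prof = profile_stats(tested, meta)

    result = anova.join(prof)
    result = result.reindex(raw.index)
    result["passed_signal_filter"] = result.index.isin(set(kept))
    age_only = set(select_age_only(result.loc[kept], alpha=params.alpha))
    result["age_only"] = result.index.isin(age_only)
    result = select_candidates(result, params.r_up, params.r_down, params.fc_min)
    return result
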