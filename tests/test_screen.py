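"""Microarray screening: filtering, normalization, ANOVA, BH, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import agegrade as ag
from agegrade.errors import DesignError, InputError


def matrix(values, genes=None, arrays=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    arrays = arrays or [f"a{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=arrays)


def balanced_meta(ages=(0, 10, 20, 30), sexes=("F", "M"), reps=2):
    rows = []
    for s in sexes:
        for a in ages:
            for r in range(reps):
                rows.append((f"a_{s}{a}_{r}", a, s))
    return pd.DataFrame(rows, columns=["array_id", "age_days", "sex"])


class TestFilterLowSignal:
    def test_all_min_genes_removed(self):
        """Two genes sitting entirely at the matrix minimum fall at/below the
        pooled 20th-percentile cutoff and are removed (brute-force oracle)."""
        rng = np.random.default_rng(0)
        vals = rng.uniform(100, 200, size=(10, 4))
        vals[3] = 5.0
        vals[7] = 5.0
        raw = matrix(vals)
        kept = ag.filter_low_signal(raw, percentile=20)
        assert set(raw.index) - set(kept) == {"g3", "g7"}
        # independent oracle: pooled percentile + scan
        cutoff = np.percentile(vals, 20)
        oracle = [g for g, row in zip(raw.index, vals) if (row > cutoff).any()]
        assert kept == oracle

    def test_identical_values_give_empty_set(self):
        raw = matrix(np.full((3, 4), 7.0))
        assert ag.filter_low_signal(raw, percentile=20) == []

    def test_percentile_bounds(self):
        with pytest.raises(InputError):
            ag.filter_low_signal(matrix([[1.0]]), percentile=0)


class TestNormalizeSignals:
    def test_threshold_clamp(self):
        raw = matrix([[0.5, 1.0], [4.0, 8.0]])
        log2 = np.log2(np.maximum(raw.to_numpy(), 1.0))
        assert log2[0, 0] == 0.0  # 0.5 clamped to 1.0 before log2
        out = ag.normalize_signals(raw)
        assert out.shape == raw.shape

    def test_scale_invariance_across_arrays(self):
        """Arrays differing only by a multiplicative constant become identical
        after the 75th-percentile shift."""
        rng = np.random.default_rng(1)
        base = rng.uniform(10, 1000, size=20)
        raw = matrix(np.column_stack([base, 3.7 * base, 0.4 * base * 10]))
        out = ag.normalize_signals(raw).to_numpy()
        assert np.allclose(out[:, 0], out[:, 1], atol=1e-10)
        assert np.allclose(out[:, 0], out[:, 2], atol=1e-10)

    def test_gene_median_zero_after_baseline(self):
        rng = np.random.default_rng(2)
        raw = matrix(rng.uniform(5, 500, size=(15, 9)))
        out = ag.normalize_signals(raw)
        assert np.allclose(out.median(axis=1), 0.0, atol=1e-12)

    def test_negative_values_rejected(self):
        with pytest.raises(InputError, match="negative"):
            ag.normalize_signals(matrix([[-1.0, 2.0]]))


def anova_ss_oracle(y, age, sex):
    """Hand-coded balanced two-way sums-of-squares decomposition."""
    y = np.asarray(y, float)
    ages, sexes = np.unique(age), np.unique(sex)
    grand = y.mean()
    r = len(y) // (len(ages) * len(sexes))
    ss_age = r * len(sexes) * sum((y[age == a].mean() - grand) ** 2 for a in ages)
    ss_sex = r * len(ages) * sum((y[sex == s].mean() - grand) ** 2 for s in sexes)
    ss_int, ss_res = 0.0, 0.0
    for a in ages:
        for s in sexes:
            cell = y[(age == a) & (sex == s)]
            dev = cell.mean() - y[age == a].mean() - y[sex == s].mean() + grand
            ss_int += r * dev**2
            ss_res += ((cell - cell.mean()) ** 2).sum()
    df = (len(ages) - 1, len(sexes) - 1, (len(ages) - 1) * (len(sexes) - 1))
    df_res = len(ages) * len(sexes) * (r - 1)
    out = {}
    for name, ss, d in zip(("age", "sex", "interaction"), (ss_age, ss_sex, ss_int), df):
        f = (ss / d) / (ss_res / df_res)
        out[name] = (f, stats.f.sf(f, d, df_res))
    out["ss"] = (ss_age, ss_sex, ss_int, ss_res)
    return out


class TestTwoWayAnova:
    def test_matches_hand_ss_oracle(self):
        meta = balanced_meta()
        rng = np.random.default_rng(3)
        age = meta["age_days"].to_numpy()
        sex = meta["sex"].to_numpy()
        y = 0.1 * age + (sex == "F") * 0.5 + rng.normal(0, 1, len(meta))
        res = ag.two_way_anova(matrix(y[None, :], arrays=list(meta["array_id"])), meta)
        oracle = anova_ss_oracle(y, age, sex)
        for eff in ("age", "sex", "interaction"):
            assert res[f"F_{eff}"].iloc[0] == pytest.approx(oracle[eff][0], abs=1e-10)
            assert res[f"p_{eff}"].iloc[0] == pytest.approx(oracle[eff][1], abs=1e-10)

    def test_ss_conservation(self):
        """Effect SS plus residual SS equals total SS on balanced designs."""
        meta = balanced_meta(reps=3)
        rng = np.random.default_rng(4)
        y = rng.normal(size=len(meta))
        oracle = anova_ss_oracle(y, meta["age_days"].to_numpy(), meta["sex"].to_numpy())
        assert sum(oracle["ss"]) == pytest.approx(((y - y.mean()) ** 2).sum(), abs=1e-8)

    def test_constant_gene_returns_p_one(self):
        meta = balanced_meta()
        res = ag.two_way_anova(
            matrix(np.full((1, len(meta)), 2.5), arrays=list(meta["array_id"])), meta
        )
        assert (res[["p_age", "p_sex", "p_interaction"]].iloc[0] == 1.0).all()

    def test_single_replicate_cell_is_design_error(self):
        meta = balanced_meta(reps=1)
        with pytest.raises(DesignError, match="replicate"):
            ag.two_way_anova(
                matrix(np.arange(len(meta), dtype=float)[None, :],
                       arrays=list(meta["array_id"])), meta
            )

    def test_unbalanced_falls_back_to_type2(self):
        meta = balanced_meta(reps=2)
        meta = pd.concat(
            [meta, pd.DataFrame([("extra", 0, "F")], columns=meta.columns)],
            ignore_index=True,
        )
        rng = np.random.default_rng(5)
        y = rng.normal(size=len(meta))
        res = ag.two_way_anova(matrix(y[None, :], arrays=list(meta["array_id"])), meta)
        assert 0 <= res["p_age"].iloc[0] <= 1

    def test_null_p_values_uniform(self):
        """ANOVA p-values for null genes pass a KS uniformity check."""
        cfg = ag.ArraySimConfig(
            n_genes=500, frac_age_only=0, frac_sex_only=0, frac_interaction=0,
            sigma=0.25, n_reps=3, seed=6,
        )
        raw, meta, _ = ag.simulate_microarray(cfg)
        res = ag.two_way_anova(ag.normalize_signals(raw), meta)
        for eff in ("age", "sex", "interaction"):
            assert stats.kstest(res[f"p_{eff}"], "uniform").pvalue > 0.001


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(ag.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_identities(self):
        assert np.allclose(ag.bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert ag.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            ag.bh_adjust([0.5, 1.2])

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance_and_bounds(self, pvals, rnd):
        """Permuting p permutes q identically; q >= p; q in [0,1]; and the
        result matches the statsmodels BH implementation."""
        p = np.array(pvals)
        q = ag.bh_adjust(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        assert np.allclose(ag.bh_adjust(p[perm]), q[perm], atol=1e-12)
        q_sm = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, q_sm, atol=1e-12)


class TestProfileStatsAndSelection:
    def test_linear_profile_r_one(self):
        meta = balanced_meta(reps=2)
        y = 0.05 * meta["age_days"].to_numpy(dtype=float)
        prof = ag.profile_stats(
            matrix(y[None, :], arrays=list(meta["array_id"])), meta
        )
        assert prof["r_age"].iloc[0] == pytest.approx(1.0)

    def test_fold_change_from_age_means(self):
        """Per-age log2 means {0,1,2,2} over four ages give 2^(2-0) = 4."""
        meta = balanced_meta(reps=2)
        level = {0: 0.0, 10: 1.0, 20: 2.0, 30: 2.0}
        y = np.array([level[a] for a in meta["age_days"]])
        prof = ag.profile_stats(matrix(y[None, :], arrays=list(meta["array_id"])), meta)
        assert prof["max_fold_change"].iloc[0] == pytest.approx(4.0)

    def test_constant_gene_degenerate_convention(self):
        meta = balanced_meta(reps=2)
        prof = ag.profile_stats(
            matrix(np.zeros((1, len(meta))), arrays=list(meta["array_id"])), meta
        )
        assert prof["r_age"].iloc[0] == 0.0
        assert prof["max_fold_change"].iloc[0] == 1.0

    def test_age_only_rule(self):
        res = pd.DataFrame(
            {
                "q_age": [0.005, 0.005, 0.5],
                "q_sex": [0.5, 0.005, 0.5],
                "q_interaction": [0.5, 0.5, 0.5],
            },
            index=["keep", "sexy", "flat"],
        )
        assert ag.select_age_only(res, alpha=0.01) == ["keep"]

    def test_candidate_thresholds_strict(self):
        res = pd.DataFrame(
            {
                "age_only": [True, True, True, False],
                "r_age": [0.85, -0.5, 0.8, 0.95],
                "max_fold_change": [5.0, 2.0, 4.0, 8.0],
            },
            index=["up", "down", "boundary", "not_age"],
        )
        out = ag.select_candidates(res)
        assert out.loc["up", "candidate_up"] and out.loc["up", "fc_ge_min"]
        assert out.loc["down", "candidate_down"] and not out.loc["down", "fc_ge_min"]
        assert not out.loc["boundary", "candidate_up"]  # r = 0.8 exactly
        assert not out.loc["not_age", "candidate_up"]


class TestScreenPipeline:
    def test_order_invariance(self, planted_array):
        """Screening results are invariant to gene-row and array-column order."""
        raw, meta, _ = planted_array
        res = ag.screen(raw, meta)
        rng = np.random.default_rng(8)
        raw2 = raw.iloc[rng.permutation(len(raw)), rng.permutation(raw.shape[1])]
        res2 = ag.screen(raw2, meta)
        joined = res.join(res2, rsuffix="_p")
        for col in ("p_age", "q_age", "r_age", "max_fold_change"):
            pd.testing.assert_series_equal(
                joined[col], joined[f"{col}_p"], check_names=False, atol=1e-10, rtol=0
            )
        assert (joined["age_only"] == joined["age_only_p"]).all()

    def test_recovers_planted_age_genes(self, planted_array):
        raw, meta, truth = planted_array
        res = ag.screen(raw, meta)
        cls = truth.set_index("gene_id")["class"]
        age_genes = set(cls.index[cls == "age_only"])
        selected = set(res.index[res["age_only"]])
        assert len(selected & age_genes) >= 0.9 * len(age_genes)
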