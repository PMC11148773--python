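"""Tests of the linear modeling, moderation, BH, PTM normalization, metagene."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from gicoreg.diffexpr import (
    DesignSpec,
    adjust_bh,
    estimate_variance_prior,
    fit_linear_model,
    metagene_score,
    moderate,
    normalize_ptm,
)
from gicoreg.errors import EmptyInputError, ValidationError


def make_design(n_high, n_low, purity=None, seed=0):
    ids = [f"S{i}" for i in range(n_high + n_low)]
    group = pd.Series(["high"] * n_high + ["low"] * n_low, index=ids)
    if purity is None:
        purity = np.random.default_rng(seed).uniform(0.3, 0.9, len(ids))
    return DesignSpec(group=group, purity=pd.Series(purity, index=ids), mode="groups")


def brute_force_ols(y, X):
    """Independent normal-equations solve on the observed entries."""
    m = np.isfinite(y)
    beta, *_ = np.linalg.lstsq(X[m], y[m], rcond=None)
    resid = y[m] - X[m] @ beta
    df = m.sum() - X.shape[1]
    return beta, resid @ resid / df


class TestFitLinearModel:
    def test_noiseless_group_shift_recovered_exactly(self):
        design = make_design(4, 4, purity=[0.5] * 8)
        y = np.array([3.0] * 4 + [1.0] * 4)
        mat = pd.DataFrame([y], index=["f1"], columns=design.group.index)
        # constant purity is collinear with the intercept, so drop it from the
        # design by using distinct purities with zero effect instead
        design = make_design(4, 4, purity=np.linspace(0.3, 0.9, 8))
        fit = fit_linear_model(mat, design)
        assert fit.coef[0] == pytest.approx(2.0, abs=1e-12)
        assert fit.sigma2[0] == pytest.approx(0.0, abs=1e-20)

    def test_matches_brute_force_normal_equations(self, rng):
        design = make_design(8, 7, seed=1)
        X, ix = design.design_matrix(design.group.index)
        mat = pd.DataFrame(
            rng.normal(size=(30, 15)), columns=design.group.index,
            index=[f"f{i}" for i in range(30)],
        )
        mat.iloc[rng.random(mat.shape) < 0.15] = np.nan
        fit = fit_linear_model(mat, design)
        for i, fid in enumerate(fit.feature_ids):
            beta, s2 = brute_force_ols(mat.loc[fid].to_numpy(), X)
            assert fit.coef[i] == pytest.approx(beta[ix], abs=1e-10)
            assert fit.sigma2[i] == pytest.approx(s2, abs=1e-10)

    def test_purity_adjustment_removes_confounding(self, rng):
        # purity correlates with group and drives expression; group effect is 0
        n = 60
        ids = [f"S{i}" for i in range(n)]
        group = pd.Series(["high"] * 30 + ["low"] * 30, index=ids)
        purity = np.where(np.arange(n) < 30, rng.uniform(0.6, 0.9, n), rng.uniform(0.3, 0.6, n))
        slope = 2.0
        y = slope * (purity - purity.mean()) + rng.normal(0, 0.1, n)
        mat = pd.DataFrame([y], index=["f1"], columns=ids)
        design = DesignSpec(group=group, purity=pd.Series(purity, index=ids), mode="groups")
        fit = fit_linear_model(mat, design)
        naive = y[:30].mean() - y[30:].mean()
        assert abs(naive) > 0.3  # confounded difference is large
        assert abs(fit.coef[0]) < 0.1  # adjusted group effect vanishes

    def test_group_coefficient_antisymmetric_under_label_swap(self, rng):
        design = make_design(6, 6, seed=2)
        mat = pd.DataFrame(
            rng.normal(size=(10, 12)), columns=design.group.index,
            index=[f"f{i}" for i in range(10)],
        )
        fit = fit_linear_model(mat, design)
        swapped = DesignSpec(
            group=design.group.map({"high": "low", "low": "high"}),
            purity=design.purity, mode="groups",
        )
        fit_sw = fit_linear_model(mat, swapped)
        assert np.allclose(fit.coef, -fit_sw.coef, atol=1e-10)

    def test_underobserved_features_dropped_not_fatal(self):
        design = make_design(5, 5, seed=3)
        mat = pd.DataFrame(
            np.ones((2, 10)), columns=design.group.index, index=["ok", "sparse"]
        ) + np.random.default_rng(0).normal(0, 0.1, (2, 10))
        mat.loc["sparse", mat.columns[:8]] = np.nan
        fit = fit_linear_model(mat, design)
        assert list(fit.feature_ids) == ["ok"]
        assert list(fit.dropped["feature"]) == ["sparse"]

    def test_tumor_normal_mode_uses_purity_coefficient(self, rng):
        ids = [f"S{i}" for i in range(20)]
        group = pd.Series(["tumor"] * 10 + ["normal"] * 10, index=ids)
        purity = np.concatenate([rng.uniform(0.3, 0.9, 10), np.zeros(10)])
        y = 1.5 * purity + rng.normal(0, 0.05, 20)
        mat = pd.DataFrame([y], index=["f1"], columns=ids)
        design = DesignSpec(group=group, purity=pd.Series(purity, index=ids), mode="tumor-normal")
        fit = fit_linear_model(mat, design)
        assert fit.coef[0] == pytest.approx(1.5, abs=0.1)


class TestModerate:
    def _random_fit(self, rng, n_features=60, n=14):
        design = make_design(n // 2, n - n // 2, seed=4)
        mat = pd.DataFrame(
            rng.normal(size=(n_features, n)), columns=design.group.index,
            index=[f"f{i}" for i in range(n_features)],
        )
        return fit_linear_model(mat, design)

    def test_zero_prior_df_reproduces_ordinary_t(self, rng):
        fit = self._random_fit(rng)
        res = moderate(fit, prior_df=0.0)
        t_ord = fit.coef / (np.sqrt(fit.sigma2) * fit.stdev_unscaled)
        assert np.allclose(res.table["t_mod"].to_numpy(), t_ord, atol=1e-10)
        p_ord = 2 * stats.t.sf(np.abs(t_ord), fit.df_residual)
        assert np.allclose(res.table["p_mod"].to_numpy(), p_ord, atol=1e-12)

    def test_infinite_prior_df_pools_variances(self, rng):
        fit = self._random_fit(rng)
        res = moderate(fit, prior_df=np.inf)
        t = res.table["t_mod"].to_numpy()
        expected = fit.coef / (np.sqrt(res.s2_prior) * fit.stdev_unscaled)
        assert np.allclose(t, expected, atol=1e-10)

    def test_posterior_variance_between_limits(self, rng):
        fit = self._random_fit(rng, n_features=200)
        res = moderate(fit)
        assert 0 < res.df_prior
        t_none = moderate(fit, prior_df=0.0).table["t_mod"].abs()
        t_full = moderate(fit, prior_df=np.inf).table["t_mod"].abs()
        t_mid = res.table["t_mod"].abs()
        between = (t_mid >= np.minimum(t_none, t_full) - 1e-9) & (
            t_mid <= np.maximum(t_none, t_full) + 1e-9
        )
        assert between.all()

    def test_prior_recovery_on_simulated_variances(self):
        rng = np.random.default_rng(55)
        d0_true, s20_true, d = 4.0, 0.05, 10
        n_features = 5000
        true_var = s20_true * d0_true / rng.chisquare(d0_true, n_features)
        s2 = true_var * rng.chisquare(d, n_features) / d
        d0, s20 = estimate_variance_prior(s2, np.full(n_features, d))
        assert abs(d0 - d0_true) / d0_true < 0.25
        assert abs(s20 - s20_true) / s20_true < 0.25

    def test_identical_variances_take_pooled_branch(self):
        fit = self._random_fit(np.random.default_rng(6))
        fit.sigma2[:] = 0.25
        res = moderate(fit)
        assert np.isinf(res.df_prior)
        # the log-scale moment matching applies the E[log chi2_d/d] correction
        d = fit.df_residual[0]
        expected = 0.25 * np.exp(np.log(d / 2) - special.digamma(d / 2))
        assert res.s2_prior == pytest.approx(expected, rel=1e-9)

    def test_null_moderated_p_uniform(self):
        rng = np.random.default_rng(77)
        design = make_design(10, 10, seed=7)
        mat = pd.DataFrame(
            rng.normal(size=(5000, 20)), columns=design.group.index,
            index=[f"f{i}" for i in range(5000)],
        )
        res = moderate(fit_linear_model(mat, design))
        assert stats.kstest(res.table["p_mod"], "uniform").pvalue > 0.01


class TestAdjustBH:
    def test_single_p_is_unchanged(self):
        assert adjust_bh([0.03])[0] == pytest.approx(0.03)

    def test_hand_evaluated_step_up(self):
        q = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_order_independence(self, rng):
        p = rng.uniform(0.001, 1.0, 50)
        perm = rng.permutation(50)
        assert np.allclose(adjust_bh(p)[perm], adjust_bh(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.5, 0.0])
        with pytest.raises(ValidationError):
            adjust_bh([1.5])


class TestNormalizePtm:
    def _matrices(self, rng, n=12, dependent=True):
        ids = [f"S{i}" for i in range(n)]
        g = pd.DataFrame(rng.normal(size=(2, n)), index=["P1", "P2"], columns=ids)
        if dependent:
            ptm = g.loc[["P1"]].rename(index={"P1": "P1_S10"}) * 1.0
        else:
            ptm = pd.DataFrame(rng.normal(size=(1, n)), index=["P1_S10"], columns=ids)
        return ptm, g

    def test_identical_signal_gives_zero_residuals(self, rng):
        ptm, g = self._matrices(rng, dependent=True)
        out, flags = normalize_ptm(ptm, g, {"P1_S10": "P1"})
        assert np.allclose(out.to_numpy(), 0.0, atol=1e-12)
        assert flags.iloc[0]["status"] == "normalized"

    def test_independent_signal_residuals_are_centered_values(self, rng):
        ptm, g = self._matrices(rng, n=200, dependent=False)
        out, _ = normalize_ptm(ptm, g, {"P1_S10": "P1"})
        y = ptm.iloc[0].to_numpy()
        assert np.corrcoef(out.iloc[0], y - y.mean())[0, 1] > 0.99

    def test_residuals_orthogonal_to_predictor(self, rng):
        ptm, g = self._matrices(rng, n=30, dependent=False)
        ptm.iloc[0, :4] = np.nan
        out, _ = normalize_ptm(ptm, g, {"P1_S10": "P1"})
        both = out.iloc[0].notna()
        r = np.corrcoef(out.iloc[0][both], g.loc["P1"][both])[0, 1]
        assert abs(r) < 1e-10

    def test_invariant_to_constant_shift_of_predictor(self, rng):
        ptm, g = self._matrices(rng, n=30, dependent=False)
        out1, _ = normalize_ptm(ptm, g, {"P1_S10": "P1"})
        out2, _ = normalize_ptm(ptm, g + 5.0, {"P1_S10": "P1"})
        assert np.allclose(out1.to_numpy(), out2.to_numpy(), atol=1e-10)

    def test_unmapped_site_passes_through_flagged(self, rng):
        ptm, g = self._matrices(rng)
        out, flags = normalize_ptm(ptm, g, {"P1_S10": "UNKNOWN"})
        assert np.allclose(out.to_numpy(), ptm.to_numpy())
        assert flags.iloc[0]["status"] == "no_parent"

    def test_missing_values_stay_missing(self, rng):
        ptm, g = self._matrices(rng, n=20, dependent=False)
        ptm.iloc[0, 3] = np.nan
        g.loc["P1", g.columns[5]] = np.nan
        out, _ = normalize_ptm(ptm, g, {"P1_S10": "P1"})
        assert np.isnan(out.iloc[0, 3]) and np.isnan(out.iloc[0, 5])


class TestMetageneScore:
    def test_single_gene_equals_its_z_scores(self, rng):
        mat = pd.DataFrame(rng.normal(size=(3, 8)), index=["a", "b", "c"])
        s = metagene_score(mat, ["a"])
        z = (mat.loc["a"] - mat.loc["a"].mean()) / mat.loc["a"].std(ddof=1)
        assert np.allclose(s, z)

    def test_equivariant_under_sample_permutation(self, rng):
        mat = pd.DataFrame(rng.normal(size=(5, 8)), index=list("abcde"))
        perm = rng.permutation(8)
        s1 = metagene_score(mat, ["a", "c"]).to_numpy()[perm]
        s2 = metagene_score(mat.iloc[:, perm], ["a", "c"]).to_numpy()
        assert np.allclose(s1, s2)

    def test_matches_brute_force_recomputation(self, rng):
        mat = pd.DataFrame(
            rng.normal(size=(20, 10)), index=[f"g{i}" for i in range(20)]
        )
        genes = [f"g{i}" for i in range(10)]
        s = metagene_score(mat, genes)
        sub = mat.loc[genes]
        z = (sub.sub(sub.mean(axis=1), axis=0)).div(sub.std(axis=1, ddof=1), axis=0)
        assert np.allclose(s, z.mean(axis=0))

    def test_empty_intersection_is_error(self, rng):
        mat = pd.DataFrame(rng.normal(size=(2, 4)), index=["a", "b"])
        with pytest.raises(EmptyInputError):
            metagene_score(mat, ["zzz"])
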