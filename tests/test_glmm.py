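"""Poisson random-intercept GLMM: likelihood, inference, diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import gammaln, logsumexp

from callgram.glmm import (PoissonRandomInterceptModel, drop1_interactions,
                           lr_test, pairwise_contrasts)


def gh_loglike(model, params, n_nodes=80):
    """Independent oracle: marginal log-likelihood by (non-adaptive)
    Gauss-Hermite quadrature with many nodes, computed from first
    principles on the raw data."""
    beta, sigma = params[:-1], np.exp(params[-1])
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    xi = model.exog @ beta + model.offset
    ll = 0.0
    for g in range(model.n_groups):
        sel = model.group_codes == g
        y, x = model.endog[sel], xi[sel]
        u = np.sqrt(2.0) * sigma * nodes
        terms = np.array([np.sum(y * (x + ug) - np.exp(x + ug)
                                 - gammaln(y + 1)) for ug in u])
        ll += logsumexp(terms + np.log(weights / np.sqrt(np.pi)))
    return ll


def simulate_counts(rng, n_groups=120, n_levels=2, n_stim=3, beta=None,
                    sigma=0.3, with_offset=True):
    """Crossed category x stimulus layout, one group per trial."""
    rows = []
    stim_of_group = rng.integers(0, n_stim, n_groups)
    for g in range(n_groups):
        for l in range(n_levels):
            rows.append({"trial_id": f"g{g:03d}", "level": f"L{l}",
                         "stimulus": f"S{stim_of_group[g]}"})
    df = pd.DataFrame(rows)
    X, names, _, _ = _design(df)
    if beta is None:
        beta = np.zeros(X.shape[1])
        beta[0] = 0.7
    off = (np.log(rng.integers(2, 8, n_groups)).repeat(n_levels)
           if with_offset else np.zeros(len(df)))
    codes = pd.factorize(df["trial_id"], sort=True)[0]
    u = rng.normal(0, sigma, n_groups)
    mu = np.exp(X @ beta + off + u[codes])
    df["count"] = rng.poisson(mu)
    df["offset_log"] = off
    return df, np.asarray(beta)


def _design(df):
    from callgram.glmm import _build_design
    return _build_design(df, {"level": "L0", "stimulus": "S0"},
                         [("level", "stimulus")])


def fit_df(df, ridge_sd=None):
    model = PoissonRandomInterceptModel.from_dataframe(
        df, "count", {"level": "L0", "stimulus": "S0"},
        [("level", "stimulus")], groups="trial_id", offset="offset_log")
    return model, model.fit(ridge_sd=ridge_sd)


class TestLikelihood:
    def test_laplace_matches_quadrature_oracle(self, rng):
        df, beta = simulate_counts(rng, n_groups=40)
        model, res = fit_df(df)
        for params in (res.params_all,
                       res.params_all + 0.1,
                       np.append(np.zeros_like(res.params), np.log(0.4))):
            lap = model.loglike(params)
            gh = gh_loglike(model, params)
            assert lap == pytest.approx(gh, abs=0.15 + 1e-3 * abs(gh))

    def test_intercept_only_closed_form(self, rng):
        """With no grouping structure to exploit (sigma pinned near 0) the
        intercept estimate is the Poisson MLE log(mean y) exactly."""
        y = rng.poisson(3.0, 150)
        m = PoissonRandomInterceptModel(y, np.ones((150, 1)),
                                        np.arange(150) // 5)
        r = m.fit(fix_log_sigma=-8.0)
        assert r.params[0] == pytest.approx(np.log(y.mean()), abs=1e-6)

    def test_reduces_to_poisson_glm_as_sigma_vanishes(self, rng):
        df, _ = simulate_counts(rng, n_groups=60, sigma=0.0)
        model, _ = fit_df(df)
        res = model.fit(fix_log_sigma=-8.0)
        glm = sm.GLM(model.endog, model.exog, family=sm.families.Poisson(),
                     offset=model.offset).fit()
        assert np.abs(res.params - glm.params).max() < 1e-4
        assert np.abs(res.bse - glm.bse).max() < 1e-3

    def test_huge_ridge_reproduces_unpenalized_fit(self, rng):
        df, _ = simulate_counts(rng, n_groups=80, sigma=0.3)
        _, free = fit_df(df)
        _, ridged = fit_df(df, ridge_sd=1e6)
        assert np.abs(free.params - ridged.params).max() < 1e-4


class TestRecovery:
    def test_estimates_within_three_se(self, rng):
        beta = np.array([0.5, -0.6, 0.4, -0.3, 0.8, 0.2])
        df, beta = simulate_counts(rng, n_groups=500, beta=beta, sigma=0.3)
        _, res = fit_df(df)
        assert res.converged
        assert np.all(np.abs(res.params - beta) < 3 * res.bse)
        assert res.random_intercept_sd == pytest.approx(0.3, abs=0.15)

    def test_wald_ci_coverage_near_nominal(self):
        """~95% coverage of the true coefficients over 60 refits."""
        rng = np.random.default_rng(88)
        beta = np.array([0.6, -0.5, 0.3, -0.2, 0.6, 0.1])
        hits = total = 0
        for _ in range(60):
            df, _ = simulate_counts(rng, n_groups=120, beta=beta, sigma=0.3)
            _, res = fit_df(df)
            ci = res.conf_int()
            hits += int(((ci[:, 0] <= beta) & (beta <= ci[:, 1])).sum())
            total += beta.size
        cover = hits / total
        assert 0.90 <= cover <= 0.99

    def test_separation_finite_under_ridge(self, rng):
        """A level x stimulus cell with all-zero counts sends the MLE to
        -inf; a unit Gaussian ridge keeps every estimate finite and
        moderate."""
        df, _ = simulate_counts(rng, n_groups=90, sigma=0.2)
        kill = (df["level"] == "L1") & (df["stimulus"] == "S2")
        df.loc[kill, "count"] = 0
        with pytest.warns(UserWarning, match="separation"):
            _, free = fit_df(df)
        _, ridged = fit_df(df, ridge_sd=1.0)
        assert np.isfinite(ridged.params).all()
        assert np.abs(ridged.params).max() < 10


class TestLrTest:
    def test_identical_models_give_null_result(self, rng):
        df, _ = simulate_counts(rng, n_groups=40)
        _, res = fit_df(df)
        chi2, df_, p = lr_test(res, res)
        assert chi2 == 0.0 and df_ == 0 and p == 1.0

    def test_non_nested_rejected(self, rng):
        df, _ = simulate_counts(rng, n_groups=40)
        model = PoissonRandomInterceptModel.from_dataframe(
            df, "count", {"level": "L0"}, [], groups="trial_id")
        other = PoissonRandomInterceptModel.from_dataframe(
            df, "count", {"stimulus": "S0"}, [], groups="trial_id")
        with pytest.raises(ValueError):
            lr_test(model.fit(), other.fit())

    def test_strong_interaction_detected(self, rng):
        beta = np.zeros(6)
        beta[0] = 0.8
        beta[-2:] = [1.5, -1.5]  # level x stimulus interaction
        df, _ = simulate_counts(rng, n_groups=150, beta=beta, sigma=0.2)
        model, full = fit_df(df)
        red = model.refit_without_terms([("level", "stimulus")]).fit()
        chi2, df_, p = lr_test(full, red)
        assert df_ == 2 and p < 0.001


class TestDrop1:
    def test_marginality_and_consistency(self, rng):
        beta = np.zeros(6)
        beta[0], beta[-2], beta[-1] = 0.8, 1.2, -1.0
        df, _ = simulate_counts(rng, n_groups=120, beta=beta, sigma=0.2)
        model, full = fit_df(df)
        tab, refit = drop1_interactions(full)
        # interaction significant -> no refit, main effects shielded
        inter_row = tab[tab["term"] == "level:stimulus"].iloc[0]
        assert inter_row["p"] < 0.001 and refit is None
        assert set(tab["term"]) == {"level:stimulus"}
        # chi2 agrees with a manual LRT of the same pair
        red = model.refit_without_terms([("level", "stimulus")]).fit()
        chi2, _, _ = lr_test(full, red)
        assert inter_row["chi2"] == pytest.approx(chi2, abs=1e-6)

    def test_refits_when_interaction_is_null(self, rng):
        beta = np.zeros(6)
        beta[0], beta[1], beta[2] = 0.8, 0.9, -0.6  # mains only
        df, _ = simulate_counts(rng, n_groups=150, beta=beta, sigma=0.2)
        _, full = fit_df(df)
        tab, refit = drop1_interactions(full)
        assert refit is not None  # non-significant interaction removed
        stages = dict(zip(tab["term"], tab["stage"]))
        assert stages["level"] == "refitted"
        assert tab.loc[tab["term"] == "level", "p"].iloc[0] < 0.001


class TestContrasts:
    def test_two_level_factor_single_unadjusted_contrast(self, rng):
        df, _ = simulate_counts(rng, n_groups=60)
        _, res = fit_df(df)
        tab = pairwise_contrasts(res, "level")
        assert len(tab) == 1
        assert tab["p_adj"].iloc[0] == pytest.approx(tab["p"].iloc[0])

    def test_k_level_factor_contrast_count(self, rng):
        df, _ = simulate_counts(rng, n_groups=60)
        _, res = fit_df(df)
        tab = pairwise_contrasts(res, "stimulus")
        assert len(tab) == 3  # k(k-1)/2 with k=3

    def test_equal_cells_contrast_near_zero(self, rng):
        df, _ = simulate_counts(rng, n_groups=200, sigma=0.2)
        _, res = fit_df(df)
        tab = pairwise_contrasts(res, "stimulus", adjust="holm")
        assert np.all(np.abs(tab["estimate"]) < 3 * tab["se"])

    def test_mvt_adjustment_is_conservative(self, rng):
        df, _ = simulate_counts(rng, n_groups=60)
        _, res = fit_df(df)
        tab = pairwise_contrasts(res, "stimulus", adjust="mvt")
        assert np.all(tab["p_adj"] >= tab["p"] - 1e-9)


class TestDiagnostics:
    def test_bootstrap_ci_deterministic_and_brackets(self, rng):
        df, _ = simulate_counts(rng, n_groups=60)
        _, res = fit_df(df)
        ci1 = res.bootstrap_ci(n_boot=60, seed=5)
        ci2 = res.bootstrap_ci(n_boot=60, seed=5)
        pd.testing.assert_frame_equal(ci1, ci2)
        inside = ((ci1["ci_low"] <= res.params)
                  & (res.params <= ci1["ci_high"]))
        assert inside.mean() > 0.8

    def test_ci_width_shrinks_with_huge_counts(self, rng):
        def width(scale):
            df, _ = simulate_counts(rng, n_groups=60, sigma=0.05)
            df["count"] = rng.poisson(scale, len(df))
            _, res = fit_df(df)
            ci = res.bootstrap_ci(n_boot=40, seed=1)
            return float((ci["ci_high"] - ci["ci_low"]).iloc[0])

        assert width(2000.0) < width(2.0)

    def test_stability_runs_one_refit_per_group(self, rng):
        df, _ = simulate_counts(rng, n_groups=25)
        _, res = fit_df(df)
        tab = res.stability_analysis()
        assert np.all(tab["min"] <= tab["estimate"] + 1e-9)
        assert np.all(tab["estimate"] <= tab["max"] + 1e-9)

    def test_duplicate_trial_has_no_leverage(self, rng):
        rows = []
        for g in range(30):
            rows.append({"trial_id": f"g{g}", "level": "L0",
                         "count": 3, "offset_log": 0.0})
            rows.append({"trial_id": f"g{g}", "level": "L1",
                         "count": 1, "offset_log": 0.0})
        df = pd.DataFrame(rows)
        model = PoissonRandomInterceptModel.from_dataframe(
            df, "count", {"level": "L0"}, [], groups="trial_id",
            offset="offset_log")
        res = model.fit()
        tab = res.stability_analysis()
        # all groups identical -> leave-one-out estimates barely move
        assert np.all((tab["max"] - tab["min"]) < 0.05)

    def test_dispersion_calibrated_on_well_specified_data(self, rng):
        df, _ = simulate_counts(rng, n_groups=100, sigma=0.3)
        _, res = fit_df(df)
        ratio, p = res.dispersion_check(n_sim=100, seed=2)
        assert 0.85 < ratio < 1.15
        assert p > 0.05

    def test_dispersion_detects_negative_binomial_noise(self, rng):
        """NB(size=0.5) noise within replicate-rich groups inflates the
        dispersion ratio.  Groups need several rows each: with only one or
        two rows per group the fitted random-intercept SD absorbs the extra
        variance and the simulation test is (correctly) blind to it."""
        G, R, mu0, size = 50, 8, 5.0, 0.5
        y = rng.negative_binomial(size, size / (size + mu0), G * R)
        m = PoissonRandomInterceptModel(
            y.astype(float), np.ones((G * R, 1)), np.repeat(np.arange(G), R))
        res = m.fit()
        ratio, p = res.dispersion_check(n_sim=100, seed=3)
        assert ratio > 1.1
        assert p < 0.05

    def test_dispersion_guard_on_constant_counts(self):
        df = pd.DataFrame({
            "trial_id": [f"g{i}" for i in range(20) for _ in (0, 1)],
            "level": ["L0", "L1"] * 20,
            "count": [2, 2] * 20,
            "offset_log": [0.0] * 40,
        })
        model = PoissonRandomInterceptModel.from_dataframe(
            df, "count", {"level": "L0"}, [], groups="trial_id",
            offset="offset_log")
        res = model.fit()
        ratio, p = res.dispersion_check(n_sim=50, seed=4)
        assert np.isfinite(ratio) and np.isfinite(p)
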