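"""GEE solver: oracle agreement, robust inference, centering, FDR, odds ratios."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Exchangeable, Independence, Unstructured
from statsmodels.genmod.families import Binomial

from comorbtraj import (
    ArchetypeSpec,
    GeeFit,
    ModelSpec,
    SimConfig,
    centered_alpha,
    fdr_adjust,
    fit_trajectory_gee,
    gee_logistic,
    odds_ratio_table,
    simulate_panel,
    wald_p,
)

RICH_ARCHETYPE = (ArchetypeSpec("rich", -1.0, 0.6, 0.05, 0.2, 1),)


def _one_comorbidity_panel(n_pairs=300, seed=3, rho=0.0):
    panel, _ = simulate_panel(
        SimConfig(n_pairs=n_pairs, seed=seed, archetypes=RICH_ARCHETYPE,
                  within_person_corr=rho)
    )
    return panel.indicators[:, 0, :], panel.is_case


def _statsmodels_fit(y, is_case, cov_struct):
    n, T = y.shape
    tc = np.array([5, 4, 3, 2, 1.0]) - 3.0
    df = pd.DataFrame(
        {"y": y.ravel(), "ad": np.repeat(is_case.astype(float), T),
         "t": np.tile(tc, n), "g": np.repeat(np.arange(n), T),
         "time": np.tile(np.arange(T), n)}
    )
    df["adt"] = df["ad"] * df["t"]
    X = sm.add_constant(df[["ad", "t", "adt"]])
    kwargs = {}
    if isinstance(cov_struct, Unstructured):
        kwargs["time"] = df[["time"]].to_numpy(int)
    return sm.GEE(df["y"], X, groups=df["g"], family=Binomial(),
                  cov_struct=cov_struct, **kwargs).fit(maxiter=200)


class TestSolverOracles:
    @pytest.mark.parametrize(
        "corr,cov_struct",
        [("independence", Independence()), ("exchangeable", Exchangeable()),
         ("unstructured", Unstructured())],
    )
    def test_agrees_with_statsmodels_gee(self, corr, cov_struct):
        y, is_case = _one_comorbidity_panel(rho=0.4)
        fit = fit_trajectory_gee(y, is_case, ModelSpec(working_correlation=corr))
        ref = _statsmodels_fit(y, is_case, cov_struct)
        assert np.abs(fit.params - ref.params.to_numpy()).max() < 1e-8
        assert np.abs(fit.se - ref.bse.to_numpy()).max() / fit.se.max() < 1e-8

    def test_single_observation_equals_logistic_mle(self):
        rng = np.random.default_rng(8)
        n = 1500
        X2 = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.normal(size=n)])
        p = 1 / (1 + np.exp(-(X2 @ np.array([-0.5, 0.8, 0.4]))))
        y = (rng.random(n) < p).astype(float)
        params, cov, _, converged, _ = gee_logistic(
            y[:, None], X2[:, None, :], "independence")
        assert converged
        mle = sm.Logit(y, X2).fit(disp=0)
        assert np.abs(params - mle.params).max() < 1e-6

    def test_null_interaction_calibration(self):
        # alpha = gamma = 0: |gamma_hat| < 3 robust SE in >= 99% of replicates
        null = (ArchetypeSpec("null", -1.0, 0.0, 0.05, 0.0, 1),)
        hits = 0
        reps = 500
        for seed in range(reps):
            panel, _ = simulate_panel(SimConfig(n_pairs=300, seed=seed, archetypes=null))
            fit = fit_trajectory_gee(panel.indicators[:, 0, :], panel.is_case)
            hits += abs(fit.gamma) < 3 * fit.se[3]
        assert hits / reps >= 0.99

    def test_working_correlation_insensitivity(self):
        # independently generated outcomes: estimates barely move across structures
        y, is_case = _one_comorbidity_panel(n_pairs=800, seed=5)
        uns = fit_trajectory_gee(y, is_case, ModelSpec(working_correlation="unstructured"))
        ind = fit_trajectory_gee(y, is_case, ModelSpec(working_correlation="independence"))
        assert (np.abs(uns.params - ind.params) < 0.5 * uns.se).all()

    def test_robust_covariance_is_symmetric_psd(self):
        y, is_case = _one_comorbidity_panel()
        fit = fit_trajectory_gee(y, is_case)
        assert np.allclose(fit.cov, fit.cov.T)
        assert np.linalg.eigvalsh(fit.cov).min() >= -1e-12

    def test_degenerate_outcome_flagged(self):
        y = np.zeros((50, 5))
        fit = fit_trajectory_gee(y, np.arange(50) < 25)
        assert not fit.converged
        assert np.isnan(fit.params).all()


class TestCenteredAlpha:
    def test_linear_combination(self):
        fit = GeeFit(label="x", params=np.array([0.0, 1.0, 0.0, 0.2]),
                     cov=np.eye(4) * 0.01, converged=True, correlation="independence",
                     working_R=None, t_bar=0.0, n_members=10, n_obs=50)
        est, se = centered_alpha(fit, t_bar=3.0)
        assert est == pytest.approx(1.6)

    def test_zero_gamma_degenerates_to_alpha(self):
        cov = np.diag([0.01, 0.04, 0.01, 0.0])
        fit = GeeFit(label="x", params=np.array([0.0, 1.0, 0.0, 0.0]),
                     cov=cov, converged=True, correlation="independence",
                     working_R=None, t_bar=0.0, n_members=10, n_obs=50)
        est, se = centered_alpha(fit, t_bar=3.0)
        assert est == pytest.approx(1.0)
        assert se == pytest.approx(0.2)

    @pytest.mark.parametrize("corr", ["independence", "exchangeable", "unstructured"])
    def test_matches_centered_coding_refit(self, corr):
        y, is_case = _one_comorbidity_panel(n_pairs=400, seed=9)
        uncentered = fit_trajectory_gee(
            y, is_case, ModelSpec(working_correlation=corr, t_bar=0.0))
        centered = fit_trajectory_gee(y, is_case, ModelSpec(working_correlation=corr))
        est, se = centered_alpha(uncentered, t_bar=3.0)
        assert est == pytest.approx(centered.alpha, abs=1e-6)
        assert se == pytest.approx(centered.se[1], abs=1e-6)


class TestWaldAndFdr:
    def test_wald_values(self):
        assert wald_p(0.0, 1.0) == pytest.approx(1.0)
        assert wald_p(1.959964, 1.0) == pytest.approx(0.05, abs=1e-6)
        assert wald_p(-3.0, 1.0) == pytest.approx(0.0026997960632602, abs=1e-12)
        with pytest.raises(ValueError):
            wald_p(1.0, 0.0)

    def test_bh_step_up_hand_computed(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(fdr_adjust([0.04]), [0.04])
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        assert fdr_adjust([]).size == 0
        with pytest.raises(ValueError):
            fdr_adjust([-0.1])

    def test_bh_monotone_in_pvalue_order(self):
        rng = np.random.default_rng(0)
        p = rng.random(100)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p).all() and (q <= 1).all()


class TestOddsRatios:
    def test_table_values(self):
        fits = []
        for label, est, se in [("a", 0.0, 0.1), ("b", np.log(2), 0.0), ("c", 0.5, 0.1)]:
            cov = np.zeros((4, 4))
            cov[1, 1] = cov[3, 3] = se**2
            fits.append(GeeFit(label=label, params=np.array([0.0, est, 0.0, est]),
                               cov=cov, converged=True, correlation="independence",
                               working_R=None, t_bar=3.0, n_members=10, n_obs=50))
        table = odds_ratio_table(fits).set_index("comorbidity")
        assert table.loc["a", "or_alpha"] == pytest.approx(1.0)
        assert table.loc["b", "or_alpha"] == pytest.approx(2.0)
        assert table.loc["b", "or_alpha_lo"] == pytest.approx(2.0)
        assert table.loc["c", "or_alpha_lo"] == pytest.approx(1.355, abs=1e-3)
        assert table.loc["c", "or_alpha_hi"] == pytest.approx(2.006, abs=1e-3)
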