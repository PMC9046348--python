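"""GMM engine: FIML likelihood against brute-force oracles, EM behaviour,
fit indices, LMR test, enumeration, coverage, and secondary fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize, stats

from trajmix import synth
from trajmix.gmm import (GMMError, GrowthMixtureFit, GrowthSpec, VisitPanel,
                         covariance_coverage, drop_baseline_refit, em_fit,
                         enumerate_classes, entropy, fit_indices,
                         growth_standard_errors, lmr_test, loglik,
                         select_base_model)


def _quad_spec():
    return GrowthSpec(basis="quadratic", random_effects=("intercept",
                                                         "linear"))


def _manual_fit(pi, alpha, Psi, sigma2, J, posterior=None, K=None):
    K = K or len(pi)
    return GrowthMixtureFit(
        K=K, pi=np.asarray(pi, float), alpha=np.asarray(alpha, float),
        Psi=np.asarray(Psi, float), theta=np.array([sigma2]),
        posterior=posterior if posterior is not None else np.ones((1, K)) / K,
        loglik=0.0, n_params=0, spec=_quad_spec(),
        times=np.arange(J, dtype=float),
    )


class TestLoglik:
    def test_single_class_complete_matches_mvn(self, rng):
        J, n = 5, 40
        t = np.arange(J, dtype=float)
        X = np.column_stack([np.ones(J), t, t * t])
        Z = X[:, :2]
        Psi = np.array([[4.0, 0.3], [0.3, 0.2]])
        alpha = np.array([[45.0, -0.5, 0.05]])
        s2 = 2.5
        V = Z @ Psi @ Z.T + s2 * np.eye(J)
        y = rng.multivariate_normal(X @ alpha[0], V, size=n)
        fit = _manual_fit([1.0], alpha, Psi, s2, J)
        expect = stats.multivariate_normal.logpdf(y, X @ alpha[0], V).sum()
        assert loglik(VisitPanel(y), fit) == pytest.approx(expect, abs=1e-8)

    def test_fiml_equals_explicit_marginalization(self):
        """3-participant toy panel with missing entries: the FIML value must
        match numerical integration of the full-J density over the missing
        coordinates to ~1e-10."""
        J = 3
        t = np.arange(J, dtype=float)
        X = np.column_stack([np.ones(J), t, t * t])
        Z = X[:, :2]
        Psi = np.array([[2.0, 0.1], [0.1, 0.3]])
        s2 = 1.5
        alpha = np.array([[40.0, -1.0, 0.1], [50.0, 0.5, -0.05]])
        pi = np.array([0.4, 0.6])
        V = Z @ Psi @ Z.T + s2 * np.eye(J)
        y = np.array([
            [41.0, 39.5, np.nan],
            [np.nan, 50.2, 51.0],
            [49.0, np.nan, np.nan],
        ])
        fit = _manual_fit(pi, alpha, Psi, s2, J)
        got = loglik(VisitPanel(y), fit)

        def density_obs(yi):
            obs = ~np.isnan(yi)
            miss = np.where(~obs)[0]
            sd = np.sqrt(np.diag(V))
            total = 0.0
            for k in range(2):
                mu = X @ alpha[k]

                def full_pdf(*mvals):
                    yfull = yi.copy()
                    yfull[miss] = mvals
                    return stats.multivariate_normal.pdf(yfull, mu, V)

                # finite integration windows around each missing coordinate's
                # marginal mean (±15 SD captures the mass to << 1e-12)
                lo = mu[miss] - 15 * sd[miss]
                hi = mu[miss] + 15 * sd[miss]
                if len(miss) == 0:
                    dens = full_pdf()
                elif len(miss) == 1:
                    dens, _ = integrate.quad(full_pdf, lo[0], hi[0],
                                             epsabs=1e-14, epsrel=1e-12)
                else:
                    dens, _ = integrate.dblquad(
                        lambda b, a: full_pdf(a, b), lo[0], hi[0],
                        lambda _: lo[1], lambda _: hi[1],
                        epsabs=1e-14, epsrel=1e-12,
                    )
                total += pi[k] * dens
            return np.log(total)

        expect = sum(density_obs(y[i]) for i in range(3))
        assert got == pytest.approx(expect, abs=1e-10)

    def test_duplicating_participants_doubles_loglik(self, rng):
        J = 4
        y = rng.normal(45, 5, size=(6, J))
        y[0, 2] = np.nan
        fit = _manual_fit([1.0], [[45.0, 0.0, 0.0]],
                          [[4.0, 0.0], [0.0, 0.1]], 3.0, J)
        one = loglik(VisitPanel(y), fit)
        two = loglik(VisitPanel(np.vstack([y, y])), fit)
        assert two == pytest.approx(2 * one, abs=1e-9)

    def test_dimension_mismatch_raises(self, rng):
        y = rng.normal(size=(5, 4))
        fit = _manual_fit([1.0], [[45.0, 0.0]], [[4.0, 0.0], [0.0, 0.1]],
                          3.0, 4)
        fit.spec = GrowthSpec(basis="linear")
        fit.alpha = np.array([[45.0, 0.0, 0.0]])
        with pytest.raises(GMMError):
            loglik(VisitPanel(y), fit)

    def test_empty_participant_excluded_with_warning(self, rng):
        y = rng.normal(45, 3, size=(4, 4))
        y[2] = np.nan
        fit = _manual_fit([1.0], [[45.0, 0.0, 0.0]],
                          [[4.0, 0.0], [0.0, 0.1]], 3.0, 4)
        with pytest.warns(UserWarning, match="no observed visits"):
            ll = loglik(VisitPanel(y), fit)
        assert np.isfinite(ll)


class TestEMFit:
    def test_k1_matches_direct_numerical_ml(self, rng):
        """Single-class latent growth fit agrees with an independent direct
        optimizer over the same likelihood surface."""
        J, n = 6, 80
        t = np.arange(J, dtype=float)
        X = np.column_stack([np.ones(J), t, t * t])
        Z = X[:, :2]
        V = Z @ np.diag([3.0, 0.1]) @ Z.T + 2.0 * np.eye(J)
        y = rng.multivariate_normal(X @ [44.0, -0.6, 0.05], V, size=n)
        panel = VisitPanel(y)
        fit = em_fit(panel, _quad_spec(), K=1, n_starts=1, seed=0,
                     tol=1e-10)

        def nll(p):
            alpha = p[:3]
            L = np.array([[np.exp(p[3]), 0.0], [p[4], np.exp(p[5])]])
            Vm = Z @ (L @ L.T) @ Z.T + np.exp(p[6]) * np.eye(J)
            try:
                return -stats.multivariate_normal.logpdf(y, X @ alpha,
                                                         Vm).sum()
            except np.linalg.LinAlgError:
                return 1e12
        res = optimize.minimize(
            nll, np.array([44, -0.5, 0.04, 0.5, 0.0, -1.0, 0.7]),
            method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
        )
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-3)
        np.testing.assert_allclose(fit.alpha[0], res.x[:3], atol=5e-3)

    def test_separable_classes_recovered_exactly(self):
        """Widely separated classes with no within-class overlap give crisp
        posteriors and exact class means."""
        J = 5
        t = np.arange(J, dtype=float)
        means = np.array([[80.0, 1.0, 0.0], [20.0, -1.0, 0.0]])
        X = np.column_stack([np.ones(J), t, t * t])
        rng = np.random.default_rng(5)
        cls = np.repeat([0, 1], 30)
        y = X @ means[cls].T
        y = y.T + 0.5 * rng.standard_normal((60, J))
        fit = em_fit(VisitPanel(y), _quad_spec(), K=2, n_starts=4, seed=2)
        assert np.all((fit.posterior > 0.999999) | (fit.posterior <
                                                    1e-6))
        np.testing.assert_allclose(sorted(fit.alpha[:, 0]),
                                   sorted(means[:, 0]), atol=0.3)

    def test_loglik_monotone_every_iteration(self, small_cohort):
        panel = VisitPanel(small_cohort.panel()).drop_empty()
        fit = em_fit(panel, _quad_spec(), K=2, n_starts=2, seed=3)
        h = np.asarray(fit.history)
        assert np.all(np.diff(h) > -1e-7)

    def test_classes_reported_in_descending_intercept_order(self,
                                                            clean_panel):
        fit = em_fit(clean_panel, _quad_spec(), K=3, n_starts=6, seed=9)
        assert np.all(np.diff(fit.alpha[:, 0]) < 0)

    def test_posterior_rows_sum_to_one(self, clean_panel):
        fit = em_fit(clean_panel, _quad_spec(), K=2, n_starts=2, seed=1)
        np.testing.assert_allclose(fit.posterior.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_psi_psd_and_theta_positive(self, clean_panel):
        fit = em_fit(clean_panel, _quad_spec(), K=2, n_starts=2, seed=1)
        assert np.linalg.eigvalsh(fit.Psi).min() >= -1e-10
        assert np.all(np.asarray(fit.theta) > 0)

    def test_label_permutation_leaves_loglik_invariant(self, clean_panel):
        fit = em_fit(clean_panel, _quad_spec(), K=3, n_starts=4, seed=4)
        base = loglik(clean_panel, fit)
        perm = np.array([2, 0, 1])
        shuffled = _manual_fit(fit.pi[perm], fit.alpha[perm], fit.Psi,
                               float(fit.theta[0]), clean_panel.J,
                               posterior=fit.posterior[:, perm], K=3)
        assert loglik(clean_panel, shuffled) == pytest.approx(base,
                                                              abs=1e-8)

    def test_parameter_recovery_on_generator_output(self, clean_panel,
                                                    clean_cohort):
        cfg = clean_cohort.config
        fit = em_fit(clean_panel, _quad_spec(), K=3, n_starts=8, seed=6)
        true_alpha = np.asarray(cfg.class_growth_means)
        n_k = np.maximum(
            np.bincount(np.asarray(clean_cohort.truth["classes"]) - 1), 1
        )
        se_int = np.sqrt(
            (cfg.random_intercept_sd ** 2 + cfg.residual_sd ** 2) / n_k
        )
        assert np.all(np.abs(fit.alpha[:, 0] - true_alpha[:, 0])
                      < 4 * se_int)
        pi_true = np.asarray(cfg.class_proportions)
        assert np.all(np.abs(fit.pi - pi_true)
                      < 4 * np.sqrt(pi_true * (1 - pi_true) / clean_panel.n)
                      + 0.01)

    def test_aux_correlates_leave_growth_estimates_close(self,
                                                         small_cohort):
        panel = VisitPanel(small_cohort.panel()).drop_empty()
        keep = VisitPanel(small_cohort.panel()).mask.any(axis=1)
        aux = small_cohort.baseline_table.loc[
            keep, ["education", "enroll_date_z"]
        ].to_numpy(float)
        f0 = em_fit(panel, _quad_spec(), K=3, n_starts=6, seed=8)
        f1 = em_fit(panel, _quad_spec(), K=3, n_starts=6, seed=8, aux=aux)
        np.testing.assert_allclose(f1.alpha[:, 0], f0.alpha[:, 0], atol=1.5)

    def test_invalid_arguments(self, clean_panel):
        with pytest.raises(GMMError):
            em_fit(clean_panel, _quad_spec(), K=0)
        with pytest.raises(GMMError):
            em_fit(clean_panel, _quad_spec(), K=1, n_starts=0)


class TestFitIndices:
    def test_closed_forms_for_hand_set_values(self):
        fit = _manual_fit([1.0], [[0, 0, 0]], np.eye(2), 1.0, 4,
                          posterior=np.ones((184, 1)))
        fit.loglik, fit.n_params = -100.0, 10
        out = fit_indices(fit, 184)
        assert out["aic"] == pytest.approx(220.0)
        assert out["bic"] == pytest.approx(200 + 10 * np.log(184))
        assert out["ssbic"] == pytest.approx(200 + 10 * np.log(186 / 24))

    def test_entropy_crisp_is_one(self):
        P = np.zeros((10, 3))
        P[np.arange(10), np.arange(10) % 3] = 1.0
        assert entropy(P) == pytest.approx(1.0)

    def test_entropy_uniform_is_zero(self):
        assert entropy(np.full((12, 4), 0.25)) == pytest.approx(0.0)

    def test_entropy_single_class_is_nan(self):
        assert np.isnan(entropy(np.ones((10, 1))))

    @pytest.mark.parametrize("n", [23, 50, 184, 4000])
    def test_ssbic_below_bic_beyond_n22(self, n):
        fit = _manual_fit([1.0], [[0, 0, 0]], np.eye(2), 1.0, 4,
                          posterior=np.ones((n, 1)))
        fit.loglik, fit.n_params = -500.0, 8
        out = fit_indices(fit, n)
        assert out["ssbic"] < out["bic"]


class TestLMR:
    def _fit_with(self, ll, p, K):
        f = _manual_fit(np.ones(K) / K, np.zeros((K, 3)), np.eye(2), 1.0, 4,
                        posterior=np.ones((5, K)) / K, K=K)
        f.loglik, f.n_params = ll, p
        return f

    def test_identical_logliks_give_p_one(self):
        res = lmr_test(self._fit_with(-100, 14, 3),
                       self._fit_with(-100, 10, 2), n=184)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_worse_larger_model_warns_p_one(self):
        with pytest.warns(UserWarning, match="local maximum"):
            res = lmr_test(self._fit_with(-105, 14, 3),
                           self._fit_with(-100, 10, 2), n=184)
        assert res.p_value == 1.0

    def test_adjustment_shrinks_statistic(self):
        res = lmr_test(self._fit_with(-90, 14, 3),
                       self._fit_with(-100, 10, 2), n=184)
        assert res.statistic_adjusted < res.statistic
        assert 0.0 <= res.p_value <= 1.0
        assert res.p_value >= res.p_unadjusted

    def test_well_separated_classes_detected(self):
        """On clearly 2-class data the 2-vs-1 LMR should reject in nearly
        every replicate."""
        t = np.arange(5, dtype=float)
        X = np.column_stack([np.ones(5), t, t * t])
        rng = np.random.default_rng(17)
        rejections = 0
        reps = 20
        for _ in range(reps):
            cls = rng.random(150) < 0.5
            means = np.where(cls[:, None], [55.0, 0.2, 0.0],
                             [35.0, -0.5, 0.05])
            y = (X @ means.T).T + 2.0 * rng.standard_normal((150, 5))
            y += rng.normal(0, 1.5, size=(150, 1))
            panel = VisitPanel(y)
            f1 = em_fit(panel, _quad_spec(), K=1, n_starts=1, seed=1)
            f2 = em_fit(panel, _quad_spec(), K=2, n_starts=3, seed=1)
            if lmr_test(f2, f1, 150).p_value < 0.05:
                rejections += 1
        assert rejections >= int(0.95 * reps)


class TestBootstrapLRT:
    def test_smoke_returns_valid_p(self):
        from trajmix.gmm import bootstrap_lrt

        t = np.arange(4, dtype=float)
        X = np.column_stack([np.ones(4), t, t * t])
        rng = np.random.default_rng(2)
        y = (X @ [45.0, -0.3, 0.02])[None, :] + \
            rng.normal(0, 1.5, size=(60, 1)) + rng.normal(0, 1.5, (60, 4))
        out = bootstrap_lrt(VisitPanel(y), _quad_spec(), K=2, n_boot=3,
                            n_starts=2, seed=1)
        assert 0.0 < out["p_value"] <= 1.0
        assert out["n_boot_effective"] >= 1


class TestEnumerationAndSelection:
    def test_single_class_data_prefers_k1_information_criteria(self):
        t = np.arange(6, dtype=float)
        X = np.column_stack([np.ones(6), t, t * t])
        rng = np.random.default_rng(23)
        wins = 0
        for _ in range(5):
            y = (X @ [45.0, -0.3, 0.02])[None, :] + \
                rng.normal(0, 1.0, size=(120, 1)) + \
                2.0 * rng.standard_normal((120, 6))
            sol = enumerate_classes(VisitPanel(y), _quad_spec(), Kmax=2,
                                    n_starts=4, seed=int(rng.integers(1e6)))
            tab = sol.table.set_index("K")
            if tab.loc[1, "ssbic"] < tab.loc[2, "ssbic"]:
                wins += 1
        assert wins >= 3

    def test_three_class_recovery_and_adequacy(self, clean_panel):
        sol = enumerate_classes(clean_panel, _quad_spec(), Kmax=3,
                                n_starts=6, seed=5)
        row = sol.table.set_index("K").loc[3]
        shares = np.asarray(row["class_sizes"]) / clean_panel.n
        np.testing.assert_allclose(
            sorted(shares), sorted([31 / 184, 100 / 184, 53 / 184]),
            atol=0.06
        )
        assert row["adequate"]
        assert sol.table["class_pcts"].map(
            lambda p: abs(sum(p) - 100) < 0.5
        ).all()

    def test_small_class_raises_adequacy_flag(self):
        t = np.arange(5, dtype=float)
        X = np.column_stack([np.ones(5), t, t * t])
        rng = np.random.default_rng(31)
        n = 300
        cls = rng.random(n) < 0.04          # a 4% class
        means = np.where(cls[:, None], [70.0, 0.0, 0.0], [40.0, -0.5, 0.05])
        y = (X @ means.T).T + rng.normal(0, 1.0, size=(n, 1)) + \
            1.5 * rng.standard_normal((n, 5))
        sol = enumerate_classes(VisitPanel(y), _quad_spec(), Kmax=2,
                                n_starts=4, seed=3)
        assert not sol.table.set_index("K").loc[2, "adequate"]

    def test_constant_trajectories_select_intercept_only(self):
        rng = np.random.default_rng(41)
        y = 45.0 + rng.normal(0, 2.0, size=(100, 1)) + \
            rng.normal(0, 1.0, size=(100, 6))
        best, table = select_base_model(
            VisitPanel(y), candidates=("intercept-only", "linear",
                                       "quadratic")
        )
        assert best.basis == "intercept-only"

    def test_quadratic_generator_beats_linear(self, clean_panel):
        best, table = select_base_model(
            clean_panel, candidates=("linear", "quadratic")
        )
        tab = table.set_index("basis")
        assert tab.loc["quadratic", "aic"] < tab.loc["linear", "aic"]

    def test_latent_basis_candidate_runs(self, rng):
        t = np.arange(5, dtype=float)
        X = np.column_stack([np.ones(5), t, t * t])
        y = (X @ [45.0, -0.5, 0.05])[None, :] + \
            rng.normal(0, 1.5, size=(80, 1)) + rng.normal(0, 1.5, (80, 5))
        best, table = select_base_model(
            VisitPanel(y), candidates=("linear", "latent-basis")
        )
        assert set(table["basis"]) == {"linear", "latent-basis"}


class TestCoverage:
    def test_complete_data_all_ones(self, rng):
        panel = VisitPanel(rng.normal(size=(20, 4)))
        cov, mn = covariance_coverage(panel)
        np.testing.assert_allclose(cov, 1.0)
        assert mn == 1.0

    def test_hand_built_overlap_counts(self):
        y = np.array([
            [1.0, 1.0, np.nan],
            [1.0, np.nan, 1.0],
            [1.0, 1.0, 1.0],
            [np.nan, 1.0, 1.0],
        ])
        cov, mn = covariance_coverage(VisitPanel(y))
        expect = np.array([
            [3, 2, 2],
            [2, 3, 2],
            [2, 2, 3],
        ]) / 4.0
        np.testing.assert_allclose(cov, expect)
        assert mn == pytest.approx(0.5)

    def test_warning_below_threshold(self):
        y = np.full((10, 3), np.nan)
        y[:, 0] = 1.0
        y[0, 1] = 1.0
        y[1, 2] = 1.0
        with pytest.warns(UserWarning, match="coverage"):
            covariance_coverage(VisitPanel(y))


class TestDropBaselineRefit:
    def test_zero_noise_separable_data_zero_shifts(self):
        t = np.arange(6, dtype=float)
        X = np.column_stack([np.ones(6), t, t * t])
        rng = np.random.default_rng(3)
        cls = np.repeat([0, 1], 25)
        means = np.array([[60.0, 0.5, 0.0], [30.0, -0.5, 0.0]])
        y = (X @ means[cls].T).T + 0.3 * rng.standard_normal((50, 6))
        panel = VisitPanel(y)
        fit2, shift = drop_baseline_refit(panel, _quad_spec(), K=2,
                                          n_starts=3, seed=2)
        off_diag = shift.to_numpy().sum() - np.trace(shift.to_numpy())
        assert off_diag == 0

    def test_shift_rows_conserve_primary_sizes(self, clean_panel):
        fit = em_fit(clean_panel, _quad_spec(), K=2, n_starts=3, seed=3)
        fit2, shift = drop_baseline_refit(clean_panel, _quad_spec(), K=2,
                                          n_starts=3, seed=3,
                                          primary_fit=fit)
        primary_sizes = np.bincount(fit.posterior.argmax(axis=1),
                                    minlength=2)
        np.testing.assert_array_equal(shift.sum(axis=1).to_numpy(),
                                      primary_sizes)

    def test_time_codes_preserved(self, clean_panel):
        fit2, _ = drop_baseline_refit(clean_panel, _quad_spec(), K=2,
                                      n_starts=2, seed=1)
        np.testing.assert_array_equal(fit2.times, clean_panel.times[1:])

    def test_too_few_followups_rejected(self, rng):
        panel = VisitPanel(rng.normal(size=(10, 4)))
        with pytest.raises(GMMError):
            drop_baseline_refit(panel, _quad_spec(), K=2)


class TestSerialization:
    def test_fit_json_roundtrip_preserves_loglik(self, clean_panel,
                                                 tmp_path):
        fit = em_fit(clean_panel, _quad_spec(), K=2, n_starts=2, seed=5)
        fit.to_json(tmp_path / "fit.json")
        back = GrowthMixtureFit.from_json(tmp_path / "fit.json")
        assert back.K == fit.K
        np.testing.assert_allclose(back.alpha, fit.alpha)
        # the round-tripped parameters reproduce the same likelihood
        assert loglik(clean_panel, back) == pytest.approx(fit.loglik,
                                                          abs=1e-8)


class TestStandardErrors:
    def test_alpha_se_positive_and_plausible(self, clean_panel):
        fit = em_fit(clean_panel, _quad_spec(), K=3, n_starts=4, seed=2)
        se = growth_standard_errors(clean_panel, fit)
        assert se.shape == fit.alpha.shape
        assert np.all(se > 0)
        # intercept SEs for well-separated classes at n=600 stay below one
        # T-point (the smallest class has ~100 members)
        assert np.all(se[:, 0] < 1.0)
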