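"""Mixed model, LR test, t-tests, beta modes, correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from scission import (
    beta_mode,
    fit_quadratic_lmm,
    lr_test,
    pearson_correlation,
    quadratic_peak,
    t_test,
)
from scission.inference_stats import LmmFit


def _lmm_table(rng, n_subjects=12, beta=(0.2, 0.15, -0.015),
               sigma_subject=0.08, sigma=0.05):
    x = np.tile(np.arange(1, 10, dtype=float), n_subjects)
    subj = np.repeat([f"s{j:02d}" for j in range(n_subjects)], 9)
    b = np.repeat(rng.normal(0, sigma_subject, n_subjects), 9)
    y = beta[0] + beta[1] * x + beta[2] * x**2 + b + rng.normal(0, sigma, x.size)
    return pd.DataFrame(
        {"subject_id": subj, "coded_level": x,
         "proportion_completion": np.clip(y, 0, 1)}
    )


class TestQuadraticLmm:
    def test_collapses_to_ols_without_subject_variance(self, rng):
        df = _lmm_table(rng, sigma_subject=0.0)
        fit = fit_quadratic_lmm(df)
        X = np.column_stack(
            [np.ones(len(df)), df.coded_level, df.coded_level**2]
        )
        beta_ols = np.linalg.lstsq(X, df.proportion_completion, rcond=None)[0]
        assert [fit.beta0, fit.beta1, fit.beta2] == pytest.approx(beta_ols, abs=1e-4)
        assert fit.sigma_subject == pytest.approx(0.0, abs=0.02)

    def test_recovers_generating_coefficients(self, rng):
        # simulation oracle: average estimates over replicates hit the truth
        truth = (0.2, 0.15, -0.015)
        est = np.array(
            [
                [f.beta0, f.beta1, f.beta2]
                for f in (
                    fit_quadratic_lmm(_lmm_table(rng)) for _ in range(60)
                )
            ]
        )
        se = est.std(axis=0, ddof=1) / math.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0) - truth) < 3 * se + 1e-3)

    def test_matches_mixedlm_ml(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        df = _lmm_table(rng)
        fit = fit_quadratic_lmm(df)
        ref = smf.mixedlm(
            "proportion_completion ~ coded_level + I(coded_level**2)",
            df, groups=df["subject_id"],
        ).fit(reml=False)
        assert [fit.beta0, fit.beta1, fit.beta2] == pytest.approx(
            list(ref.params[:3]), abs=1e-4
        )
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_reduced_model_has_lower_loglik(self, rng):
        df = _lmm_table(rng)
        full = fit_quadratic_lmm(df, include_quadratic=True)
        reduced = fit_quadratic_lmm(df, include_quadratic=False)
        assert reduced.loglik < full.loglik

    def test_single_subject_rejected(self, rng):
        df = _lmm_table(rng, n_subjects=1)
        with pytest.raises(ValueError):
            fit_quadratic_lmm(df)

    def test_constant_response_warns(self):
        df = pd.DataFrame(
            {"subject_id": ["a"] * 3 + ["b"] * 3,
             "coded_level": [1.0, 2.0, 3.0] * 2,
             "proportion_completion": [0.5] * 6}
        )
        with pytest.warns(RuntimeWarning):
            fit_quadratic_lmm(df)


class TestLrTest:
    def test_equal_logliks_give_null_result(self, rng):
        df = _lmm_table(rng)
        full = fit_quadratic_lmm(df, include_quadratic=True)
        fake_reduced = LmmFit(
            beta0=0, beta1=0, beta2=None, sigma_subject=0, sigma_resid=1,
            loglik=full.loglik, includes_quadratic=False, n_obs=full.n_obs,
            n_subjects=full.n_subjects, n_params=full.n_params - 1,
            data_fingerprint=full.data_fingerprint,
        )
        chi2, df_, p = lr_test(full, fake_reduced)
        assert chi2 == 0.0 and df_ == 1 and p == 1.0

    def test_chi2_reference_value(self, rng):
        # chi2 = 3.84 on 1 df sits at the 5% point
        assert sps.chi2.sf(3.84, 1) == pytest.approx(0.050, abs=0.001)
        df = _lmm_table(rng)
        full = fit_quadratic_lmm(df, True)
        reduced = fit_quadratic_lmm(df, False)
        chi2, df_, p = lr_test(full, reduced)
        assert chi2 >= 0 and df_ == 1
        assert p == pytest.approx(float(sps.chi2.sf(chi2, 1)))

    def test_different_data_rejected(self, rng):
        full = fit_quadratic_lmm(_lmm_table(rng), True)
        reduced = fit_quadratic_lmm(_lmm_table(rng), False)
        with pytest.raises(ValueError):
            lr_test(full, reduced)

    def test_recoding_invariance(self, rng):
        df = _lmm_table(rng)
        shifted = df.assign(coded_level=df.coded_level + 3.0)
        chi2_a, _, _ = lr_test(
            fit_quadratic_lmm(df, True), fit_quadratic_lmm(df, False)
        )
        chi2_b, _, _ = lr_test(
            fit_quadratic_lmm(shifted, True), fit_quadratic_lmm(shifted, False)
        )
        assert chi2_a == pytest.approx(chi2_b, abs=1e-3)


class TestQuadraticPeak:
    @staticmethod
    def _fit(beta1, beta2):
        return LmmFit(
            beta0=0.2, beta1=beta1, beta2=beta2, sigma_subject=0.1,
            sigma_resid=0.05, loglik=0.0, includes_quadratic=True,
            n_obs=108, n_subjects=12, n_params=5, data_fingerprint="x",
        )

    def test_vertex_at_level_five(self):
        # x* = -0.15 / (2 * -0.015) = 5 -> the level-5 luminance exactly
        assert quadratic_peak(self._fit(0.15, -0.015)) == pytest.approx(34.1)

    def test_midpoint_is_geometric_mean(self):
        # x* = 5.5 -> log-linear midpoint of levels 5 and 6
        fit = self._fit(0.165, -0.015)
        assert -fit.beta1 / (2 * fit.beta2) == pytest.approx(5.5)
        assert quadratic_peak(fit) == pytest.approx(math.sqrt(34.1 * 54.9), rel=1e-6)

    def test_convex_parabola_rejected(self):
        with pytest.raises(ValueError):
            quadratic_peak(self._fit(0.15, 0.01))

    def test_shift_covariance(self):
        # shifting the coded axis by +1 moves the vertex one level up
        f5 = self._fit(0.15, -0.015)
        f6 = self._fit(0.18, -0.015)  # vertex at 6
        assert quadratic_peak(f6) == pytest.approx(54.9)
        assert quadratic_peak(f6) > quadratic_peak(f5)


class TestTTest:
    def test_hand_computed_one_sample(self):
        res = t_test([0.2, 0.4, 0.6], mu0=0.0)
        assert res.t == pytest.approx(3.464, abs=1e-3)
        assert res.df == 2
        assert res.p == pytest.approx(0.0742, abs=1e-3)

    def test_all_zero_differences(self):
        res = t_test([0.3, 0.3, 0.3], [0.3, 0.3, 0.3])
        assert res.t == 0.0 and res.p == 1.0

    def test_one_sided_is_half_two_sided_for_positive_t(self):
        x = [0.2, 0.5, 0.4, 0.6]
        two = t_test(x, sidedness="two")
        greater = t_test(x, sidedness="greater")
        assert greater.p == pytest.approx(two.p / 2)

    @given(
        st.lists(st.floats(-1, 1), min_size=3, max_size=10),
        st.lists(st.floats(-1, 1), min_size=10, max_size=10),
    )
    def test_paired_equals_one_sample_on_differences(self, x, y):
        x = (x * 4)[:10]
        d = [a - b for a, b in zip(x, y)]
        if np.std(d, ddof=1) == 0:
            return
        paired = t_test(x, y)
        onesample = t_test(d)
        assert paired.t == pytest.approx(onesample.t, rel=1e-12, abs=1e-12)
        assert paired.p == pytest.approx(onesample.p, rel=1e-12, abs=1e-12)

    def test_cohens_dz_convention(self):
        x = np.array([0.5, 0.6, 0.7, 0.9])
        y = np.array([0.1, 0.3, 0.2, 0.4])
        res = t_test(x, y)
        d = x - y
        assert res.cohens_d == pytest.approx(d.mean() / d.std(ddof=1))
        # d_z relates to t via sqrt(n)
        assert res.cohens_d == pytest.approx(res.t / math.sqrt(len(x)))

    def test_ci_is_two_sided_even_for_one_sided_test(self):
        a = t_test([0.2, 0.5, 0.4, 0.6], sidedness="greater")
        b = t_test([0.2, 0.5, 0.4, 0.6], sidedness="two")
        assert a.ci95 == b.ci95
        assert a.ci95[0] < a.mean_diff < a.ci95[1]

    def test_zero_variance_nonzero_mean_sentinel(self):
        with pytest.warns(RuntimeWarning):
            res = t_test([0.5, 0.5, 0.5], mu0=0.0)
        assert math.isinf(res.t)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            t_test([0.5])


class TestBetaMode:
    def test_large_sample_beta_2_5(self, rng):
        # closed-form mode of Beta(2, 5): (a - 1) / (a + b - 2) = 1/5
        sample = rng.beta(2.0, 5.0, size=100_000)
        res = beta_mode(sample)
        assert res.mode == pytest.approx(0.2, abs=0.02)

    def test_symmetric_sample(self, rng):
        sample = rng.beta(4.0, 4.0, size=20_000)
        res = beta_mode(sample)
        assert res.a == pytest.approx(res.b, rel=0.1)
        assert res.mode == pytest.approx(0.5, abs=0.02)

    def test_mode_matches_grid_argmax(self, rng):
        # closed form vs numeric maximization of the fitted density
        from scipy.stats import beta as beta_dist

        for a0, b0 in [(2, 5), (5, 2), (1.5, 4), (8, 3)]:
            res = beta_mode(rng.beta(a0, b0, size=500))
            grid = np.linspace(1e-3, 1 - 1e-3, 999)
            argmax = grid[np.argmax(beta_dist.pdf(grid, res.a, res.b))]
            assert res.mode == pytest.approx(argmax, abs=1e-3)

    def test_handles_boundary_observations(self):
        res = beta_mode([0.0, 0.0, 0.1, 0.2, 0.05, 1.0])
        assert 0.0 <= res.mode <= 1.0

    def test_order_invariance(self, rng):
        sample = list(rng.beta(2, 5, size=50))
        a = beta_mode(sample)
        b = beta_mode(sample[::-1])
        assert a.a == pytest.approx(b.a) and a.mode == pytest.approx(b.mode)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            beta_mode([0.5, 0.5, 0.5])


class TestPearsonCorrelation:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_correlation(x, [2 * v + 1 for v in x])[0] == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_hand_value(self):
        r, p = pearson_correlation([1, 2, 3], [1, 3, 2])
        assert r == pytest.approx(0.5)

    def test_symmetry_and_bounds(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        r_xy, p_xy = pearson_correlation(x, y)
        r_yx, p_yx = pearson_correlation(y, x)
        assert r_xy == pytest.approx(r_yx) and p_xy == pytest.approx(p_yx)
        assert -1.0 <= r_xy <= 1.0

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
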