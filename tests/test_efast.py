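"""eFAST estimator: spectra, closed-form oracles, estimator consistency."""

import numpy as np
import pytest

from vegftrap.efast import (
    EfastDesign,
    efast,
    indices,
    partial_variance,
    sample_search_curve,
    total_variance,
)


def design(k=3, n=257, m=4, nr=1, lo=0.0, hi=1.0):
    return EfastDesign(ranges=((lo, hi),) * k, n_samples=n, harmonics=m, n_resamples=nr)


class TestSearchCurve:
    def test_marginals_span_their_ranges(self):
        d = EfastDesign(ranges=((2.0, 10.0), (0.1, 0.5)), n_samples=257)
        x, _ = sample_search_curve(d, 0, np.random.default_rng(0))
        for j, (lo, hi) in enumerate(d.ranges):
            width = hi - lo
            assert x[:, j].min() <= lo + 0.02 * width
            assert x[:, j].max() >= hi - 0.02 * width
            assert x[:, j].min() >= lo and x[:, j].max() <= hi

    def test_deterministic_under_fixed_seed(self):
        d = design()
        x1, s1 = sample_search_curve(d, 1, np.random.default_rng(42))
        x2, s2 = sample_search_curve(d, 1, np.random.default_rng(42))
        np.testing.assert_array_equal(x1, x2)
        np.testing.assert_array_equal(s1, s2)

    def test_identity_model_spectrum_concentrates_at_omega_i(self):
        d = design(k=1)
        x, s = sample_search_curve(d, 0, np.random.default_rng(0))
        y = x[:, 0]
        d_i = partial_variance(y, s, d.omega_i, d.harmonics)
        d_tot = total_variance(y, s)
        assert d_i / d_tot > 0.99
        assert d_tot == pytest.approx(y.var(), rel=1e-6)

    def test_log_scale_marginal(self):
        d = EfastDesign(ranges=((1e-2, 1e2),), n_samples=257, log_scale=True)
        x, _ = sample_search_curve(d, 0, np.random.default_rng(0))
        # log-uniform: median near geometric mean
        assert 0.5 < np.median(x[:, 0]) < 2.0

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            EfastDesign(ranges=((0, 1),), n_samples=9, harmonics=4)
        with pytest.raises(ValueError):
            partial_variance(np.zeros(33), np.linspace(-np.pi, np.pi, 33), 16, 4)


class TestPartialVariance:
    def test_constant_output_gives_zero(self):
        d = design(k=2)
        _, s = sample_search_curve(d, 0, np.random.default_rng(0))
        y = np.full(d.n_samples, 3.7)
        assert partial_variance(y, s, d.omega_i, 4) == pytest.approx(0.0, abs=1e-20)
        si, sti = indices(0.0, 0.0, total_variance(y, s))
        assert np.isnan(si) and np.isnan(sti)

    def test_pure_cosine_recovers_half_squared_amplitude(self):
        # y = a cos(w s): variance a^2/2, all of it at frequency w
        d = design(k=1, n=257)
        _, s = sample_search_curve(d, 0, np.random.default_rng(0))
        a, w = 2.5, d.omega_i
        y = a * np.cos(w * s)
        assert partial_variance(y, s, w, 4) == pytest.approx(a * a / 2.0, rel=1e-10)
        assert total_variance(y, s) == pytest.approx(a * a / 2.0, rel=1e-10)

    def test_output_independent_of_parameter_has_zero_index(self):
        d = design(k=2, n=513, nr=2)
        res = efast(lambda x: 3.0 * x[1] ** 2, d, seed=0)
        assert res.s_first.iloc[0, 0] == pytest.approx(0.0, abs=1e-3)
        assert res.s_first.iloc[1, 0] > 0.95


class TestIndices:
    def test_additive_linear_model_matches_analytic_sobol(self):
        c = np.array([1.0, 2.0, 0.5])
        d = EfastDesign(ranges=((0.0, 1.0),) * 3, n_samples=1025, harmonics=4,
                        n_resamples=5)
        res = efast(lambda x: float(c @ x), d, seed=1)
        analytic = c**2 / np.sum(c**2)
        np.testing.assert_allclose(res.s_first.values.ravel(), analytic, atol=0.02)
        # additive model: total index approximately equals first-order index
        np.testing.assert_allclose(
            res.s_total.values.ravel(), res.s_first.values.ravel(), atol=0.03
        )

    def test_ishigami_closed_forms(self):
        a, b = 7.0, 0.1

        def ishigami(x):
            return np.sin(x[0]) + a * np.sin(x[1]) ** 2 + b * x[2] ** 4 * np.sin(x[0])

        v1 = 0.5 * (1.0 + b * np.pi**4 / 5.0) ** 2
        v2 = a * a / 8.0
        v13 = b * b * np.pi**8 * (1.0 / 18.0 - 1.0 / 50.0)
        v = v1 + v2 + v13
        s_true = np.array([v1 / v, v2 / v, 0.0])
        st3_true = v13 / v
        d = EfastDesign(ranges=((-np.pi, np.pi),) * 3, n_samples=1025, harmonics=4,
                        n_resamples=5)
        res = efast(ishigami, d, seed=2)
        np.testing.assert_allclose(res.s_first.values.ravel(), s_true, atol=0.03)
        assert res.s_total.values.ravel()[2] == pytest.approx(st3_true, abs=0.03)

    def test_total_index_at_least_first_order(self):
        def interacting(x):
            return x[0] * x[1] + 0.2 * x[2]

        d = design(k=3, n=513, nr=3)
        res = efast(interacting, d, seed=3)
        assert (res.s_total.values >= res.s_first.values - 1e-6).all()

    def test_interaction_detected_against_monte_carlo_sobol(self):
        # brute-force double-loop Sobol total index for y = x0 * x1
        rng = np.random.default_rng(4)

        def f(x):
            return x[..., 0] * x[..., 1]

        n = 20000
        base = rng.uniform(size=(n, 2))
        resampled = rng.uniform(size=(n, 2))
        var_y = f(base).var()
        # total effect of x0: E_x1[Var_x0(y)] via fixing x1, resampling x0
        mixed = base.copy()
        mixed[:, 0] = resampled[:, 0]
        st0_mc = 0.5 * np.mean((f(base) - f(mixed)) ** 2) / var_y
        d = design(k=2, n=1025, nr=5)
        res = efast(lambda x: x[0] * x[1], d, seed=5)
        gap = res.s_total.iloc[0, 0] - res.s_first.iloc[0, 0]
        gap_mc = st0_mc - 3.0 / 7.0  # analytic S_1 = 3/7 for y = x0 x1 on U(0,1)^2
        assert gap > 0.05
        assert gap == pytest.approx(gap_mc, abs=0.06)

    def test_affine_output_rescaling_invariance(self):
        def f(x):
            return np.sin(x[0]) + x[1] ** 2

        d = design(k=2, n=513, nr=2, lo=-1.0, hi=1.0)
        r1 = efast(f, d, seed=6)
        r2 = efast(lambda x: 5.0 * f(x) - 11.0, d, seed=6)
        np.testing.assert_allclose(r1.s_first.values, r2.s_first.values, atol=1e-10)
        np.testing.assert_allclose(r1.s_total.values, r2.s_total.values, atol=1e-10)

    def test_resample_averaging_reduces_variance(self):
        c = np.array([1.0, 1.0])

        def f(x):
            return float(c @ x) + 0.3 * x[0] * x[1]

        estimates = {nr: [] for nr in (1, 4)}
        for nr in estimates:
            for seed in range(8):
                d = design(k=2, n=257, nr=nr)
                r = efast(f, d, seed=seed)
                estimates[nr].append(r.s_first.iloc[0, 0])
        assert np.var(estimates[4]) <= np.var(estimates[1])


class TestModuleAnalysis:
    def test_module_analysis_on_surrogate_group(self, xenograft_config):
        # tiny group / sample count: structural contract, not precision
        from vegftrap.efast import run_module_analysis

        groups = {
            "secretion": [
                "secretion.q_tumor_molecules_per_cell_s",
                "secretion.q_svegfr1_ec_molecules_per_cell_s",
            ]
        }
        res = run_module_analysis(
            xenograft_config, "secretion",
            outputs=["vegf_human_tumor", "svegfr1_blood"],
            groups=groups, n_samples=65, n_resamples=1, seed=0,
        )
        # tumor secretion drives tumor hVEGF, not plasma sVEGFR1; and vice versa
        assert res.s_first.loc[groups["secretion"][0], "vegf_human_tumor"] > 0.5
        assert res.s_first.loc[groups["secretion"][0], "svegfr1_blood"] < 0.05
        assert res.s_first.loc[groups["secretion"][1], "svegfr1_blood"] > 0.5
        assert (res.s_total.values >= res.s_first.values - 0.05).all()

    def test_empty_group_rejected(self, xenograft_config):
        from vegftrap.efast import run_module_analysis

        with pytest.raises(ValueError):
            run_module_analysis(xenograft_config, "empty", groups={"empty": []})
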