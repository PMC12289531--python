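"""One-compartment model fitting: prediction, recovery, joint fits, errors."""

import math

import numpy as np
import pytest
import scipy.stats

import turnoverkit as tk
from turnoverkit.errors import ContractError, DomainError, InsufficientDataError
from turnoverkit.kinetics import _moments, solve_linear_subproblem


class TestPredict:
    def test_baseline_plateau_midpoint(self):
        p = tk.OneCompartmentParams(e0=0.01, ess=0.11, k=0.2)
        assert tk.predict_labeling(p, 0.0) == pytest.approx(0.01)
        assert tk.predict_labeling(p, 1e6) == pytest.approx(0.11)
        # one half-life: halfway between baseline and plateau
        assert tk.predict_labeling(p, math.log(2) / 0.2) == pytest.approx(0.06)

    def test_negative_time_rejected(self):
        p = tk.OneCompartmentParams(e0=0.0, ess=0.1, k=0.2)
        with pytest.raises(DomainError):
            tk.predict_labeling(p, -1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(DomainError):
            tk.OneCompartmentParams(e0=0.2, ess=0.1, k=0.2)
        with pytest.raises(DomainError):
            tk.OneCompartmentParams(e0=0.0, ess=0.1, k=0.0)


class TestHalfLife:
    def test_analytic_values(self):
        assert tk.half_life(math.log(2)).t_half_days == pytest.approx(1.0)
        assert tk.half_life(math.log(2) / 9.6).t_half_days == pytest.approx(9.6)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(DomainError):
            tk.half_life(0.0)
        with pytest.raises(DomainError):
            tk.half_life(-0.3)


class TestSingleSeriesFit:
    @pytest.mark.parametrize(
        "e0, ess, k",
        [(0.0, 0.10, 0.2), (0.02, 0.08, 0.05), (0.01, 0.30, 1.3), (0.0, 0.95, 0.01)],
    )
    def test_noise_free_recovery(self, six_day_grid, series_factory, e0, ess, k):
        params = tk.OneCompartmentParams(e0=e0, ess=ess, k=k)
        fit = tk.fit_time_course(series_factory(params, six_day_grid))
        assert abs(fit.k_hat - k) / k < 1e-6
        e0_hat, ess_hat = fit.per_peptide_params["pep1"]
        assert e0_hat == pytest.approx(e0, abs=1e-6)
        assert ess_hat == pytest.approx(ess, abs=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.converged

    def test_rss_matches_residuals_at_solution(self, six_day_grid, series_factory, rng):
        params = tk.OneCompartmentParams(e0=0.01, ess=0.1, k=0.25)
        s = series_factory(params, six_day_grid, sigma=0.01, rng=rng)
        fit = tk.fit_time_course(s)
        e0_hat, ess_hat = fit.per_peptide_params["pep1"]
        pred = e0_hat + (ess_hat - e0_hat) * (-np.expm1(-fit.k_hat * s.times))
        assert fit.rss == pytest.approx(float(np.sum((s.values - pred) ** 2)), rel=1e-9)

    def test_two_time_points_rejected(self):
        s = tk.PeptideTimeCourse("p", "x", "PF", [0.0, 7.0], [0.0, 0.05])
        with pytest.raises(InsufficientDataError):
            tk.fit_time_course(s)

    def test_flat_series_flagged_non_identifiable(self, six_day_grid):
        s = tk.PeptideTimeCourse("p", "x", "PF", six_day_grid, np.full(6, 0.03))
        fit = tk.fit_time_course(s)
        assert not fit.converged

    def test_deterministic(self, six_day_grid, series_factory, rng):
        params = tk.OneCompartmentParams(e0=0.0, ess=0.1, k=0.3)
        s = series_factory(params, six_day_grid, sigma=0.005, rng=rng)
        f1 = tk.fit_time_course(s)
        f2 = tk.fit_time_course(s)
        assert f1.k_hat == f2.k_hat and f1.rss == f2.rss

    def test_pin_e0_option(self, six_day_grid, series_factory):
        params = tk.OneCompartmentParams(e0=0.0, ess=0.12, k=0.4)
        fit = tk.fit_time_course(
            series_factory(params, six_day_grid), tk.FitOptions(pin_e0=True)
        )
        assert fit.per_peptide_params["pep1"][0] == 0.0
        assert abs(fit.k_hat - 0.4) / 0.4 < 1e-6


class TestJointFit:
    def test_exact_shared_rate_recovery(self, six_day_grid, series_factory):
        series = [
            series_factory(
                tk.OneCompartmentParams(e0=0.0, ess=ess, k=0.15),
                six_day_grid, pep=f"pep{i}",
            )
            for i, ess in enumerate([0.08, 0.10, 0.12])
        ]
        fit = tk.fit_joint(series)
        assert abs(fit.k_hat - 0.15) / 0.15 < 1e-6
        for i, ess in enumerate([0.08, 0.10, 0.12]):
            assert fit.per_peptide_params[f"pep{i}"][1] == pytest.approx(ess, abs=1e-6)

    def test_single_series_equals_single_fit(self, six_day_grid, series_factory, rng):
        params = tk.OneCompartmentParams(e0=0.01, ess=0.09, k=0.22)
        s = series_factory(params, six_day_grid, sigma=0.004, rng=rng)
        fj = tk.fit_joint([s])
        fs = tk.fit_time_course(s)
        assert fj.k_hat == fs.k_hat
        assert fj.rss == fs.rss

    def test_mixed_parent_ids_rejected(self, six_day_grid, series_factory):
        p = tk.OneCompartmentParams(e0=0.0, ess=0.1, k=0.2)
        a = series_factory(p, six_day_grid, parent="A")
        b = series_factory(p, six_day_grid, parent="B")
        with pytest.raises(ContractError):
            tk.fit_joint([a, b])

    def test_wald_ci_coverage(self, six_day_grid):
        # 95% CI for k from the profiled-RSS curvature should cover the
        # truth about 95% of the time under Gaussian labeling noise.
        rng = np.random.default_rng(42)
        times = six_day_grid[np.arange(9) % 6]
        k_true = 0.15
        mu = tk.predict_labeling(tk.OneCompartmentParams(e0=0.02, ess=0.10, k=k_true), times)
        covered = 0
        n_sim = 1000
        for _ in range(n_sim):
            e = np.clip(mu + 0.005 * rng.standard_normal(times.size), 0, 1)
            fit = tk.fit_time_course(tk.PeptideTimeCourse("p", "x", "PF", times, e))
            q = scipy.stats.t.ppf(0.975, fit.df)
            covered += fit.k_hat - q * fit.se_k <= k_true <= fit.k_hat + q * fit.se_k
        assert 0.93 <= covered / n_sim <= 0.97


class TestVariableProjection:
    def test_profiled_linear_params_are_conditionally_optimal(self, six_day_grid, rng):
        # At any fixed k, the closed-form constrained (E0, Ess) must beat
        # every random feasible candidate pair in RSS.
        params = tk.OneCompartmentParams(e0=0.02, ess=0.1, k=0.3)
        mu = tk.predict_labeling(params, six_day_grid)
        e = np.clip(mu + 0.01 * rng.standard_normal(6), 0, 1)
        for k in [0.05, 0.15, 0.3, 0.8, 2.0]:
            x = -np.expm1(-k * six_day_grid)
            a, b, rss = solve_linear_subproblem(*_moments(x, e))
            assert 0 <= a and 0 <= b and a + b <= 1 + 1e-12
            for _ in range(200):
                a_c = rng.uniform(0, 1)
                b_c = rng.uniform(0, 1 - a_c)
                rss_c = float(np.sum((e - a_c - b_c * x) ** 2))
                assert rss <= rss_c + 1e-12

    def test_rss_never_increases_with_grid_refinement(self, six_day_grid, series_factory, rng):
        params = tk.OneCompartmentParams(e0=0.0, ess=0.1, k=0.18)
        s = series_factory(params, six_day_grid, sigma=0.008, rng=rng)
        rss = [
            tk.fit_time_course(s, tk.FitOptions(n_grid=n)).rss
            for n in (25, 50, 100, 200, 400)
        ]
        assert all(r2 <= r1 + 1e-15 for r1, r2 in zip(rss, rss[1:]))
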