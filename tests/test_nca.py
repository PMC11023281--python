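"""Non-compartmental analysis: terminal fit, areas, derived indices."""

import math

import numpy as np
import pytest

import koalapk as kp
from koalapk.errors import (
    AllBLQError,
    NonDecliningTerminalError,
    NonPositiveResidualError,
    TooFewPointsError,
    ValidationError,
)


def closed_form_bateman(t, scale, ka, ke):
    """Independent closed-form curve used as the oracle throughout."""
    t = np.asarray(t, dtype=float)
    return scale * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))


class TestTerminalFit:
    def test_exact_exponential_recovers_slope(self, exact_exponential_profile):
        fit = kp.fit_terminal_phase(exact_exponential_profile)
        assert fit.ke == pytest.approx(math.log(2) / 4, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert len(fit.points_used) == 3

    def test_bateman_slope_matches_closed_form_ols(self, profile_factory):
        # oracle: explicit least squares on the closed-form curve values
        ka, ke = 0.22, 0.125
        t = np.array([8.0, 12.0, 24.0])
        c = closed_form_bateman(t, 1.0, ka, ke)
        y = np.log(c)
        sxx = ((t - t.mean()) ** 2).sum()
        slope = ((t - t.mean()) * (y - y.mean())).sum() / sxx
        prof = profile_factory(t, c)
        fit = kp.fit_terminal_phase(prof)
        assert fit.ke == pytest.approx(-slope, rel=1e-12)
        # absorption is far from complete at these times (ka/ke = 1.76), so
        # the slope is substantially shallower than the true ke
        assert fit.ke == pytest.approx(0.0945394, abs=1e-6)

    def test_constant_concentrations_rejected(self, profile_factory):
        prof = profile_factory([8, 12, 24], [4.0, 4.0, 4.0])
        with pytest.raises(NonDecliningTerminalError):
            kp.fit_terminal_phase(prof)

    def test_too_few_points(self, profile_factory):
        prof = profile_factory([8, 12], [4.0, 2.0])
        with pytest.raises(TooFewPointsError):
            kp.fit_terminal_phase(prof)

    def test_tail_selection_prefers_clean_late_phase(self, profile_factory):
        # early post-peak points are absorption-contaminated; a late clean
        # tail fits better and must be selected
        ka, ke = 0.22, 0.125
        t = np.array([2.0, 4.0, 8.0, 12.0, 24.0, 48.0, 72.0])
        c = closed_form_bateman(t, 35.0, ka, ke)
        fit = kp.fit_terminal_phase(profile_factory(t, c))
        assert fit.ke == pytest.approx(ke, rel=0.03)
        assert min(fit.points_used) >= 4  # dropped the contaminated points


class TestSimpleOperations:
    def test_half_life(self):
        assert kp.half_life(0.6931) == pytest.approx(1.0, abs=2e-4)
        assert kp.half_life(0.125) == pytest.approx(5.545, abs=1e-3)
        # printed per-animal value: ln2/0.144 within 0.05 of the table's 4.823
        assert abs(kp.half_life(0.144) - 4.823) < 0.05
        with pytest.raises(ValidationError):
            kp.half_life(0.0)

    def test_cmax_tmax_and_ties(self, profile_factory):
        assert kp.cmax_tmax(profile_factory([1, 4, 8], [1, 5, 3])) == (5.0, 4.0)
        # ties broken by the earliest time
        assert kp.cmax_tmax(profile_factory([2, 4, 8], [5, 5, 2])) == (5.0, 2.0)

    def test_all_blq_error(self, profile_factory):
        prof = profile_factory([1, 2, 3], [0.1, 0.2, 0.1], lloq=0.625)
        with pytest.raises(AllBLQError):
            kp.cmax_tmax(prof)

    def test_extrapolations(self):
        assert kp.auc_extrapolate(2.0, 0.1) == pytest.approx(20.0)
        assert kp.auc_extrapolate(0.625, 0.125) == pytest.approx(5.0)
        assert kp.aumc_extrapolate(2.0, 24.0, 0.1) == pytest.approx(680.0)
        assert kp.aumc_extrapolate(5.0, 0.0, 0.5) == pytest.approx(5.0 / 0.25)
        assert kp.aumc_extrapolate(1.0, 1.0, 1.0) == pytest.approx(2.0)
        with pytest.raises(ValidationError):
            kp.auc_extrapolate(0.0, 0.1)

    def test_mrt_and_apparent_parameters_from_printed_indices(self):
        # printed-equation identities among the published table cells
        assert kp.mrt(961.38, 128.87) == pytest.approx(7.460, abs=5e-4)
        assert kp.mrt(2214.62, 197.90) == pytest.approx(11.191, abs=5e-4)
        assert kp.clearance_over_f(15.0, 128.87) == pytest.approx(0.116, abs=5e-4)
        assert kp.clearance_over_f(15.0, 279.05) == pytest.approx(0.054, abs=5e-4)
        assert kp.clearance_over_f(1.0, 1000.0) == pytest.approx(0.001)
        assert abs(kp.volume_over_f(0.1164, 0.144) - 0.810) < 0.01
        assert abs(kp.volume_over_f(0.089, 0.129) - 0.688) < 0.01


class TestAUC:
    def test_flat_segment_linear_rule(self, profile_factory):
        prof = profile_factory([0, 1], [10, 10])
        assert kp.auc_trapezoid(prof, 1.0) == pytest.approx(10.0)

    def test_log_rule_on_decline(self, profile_factory):
        prof = profile_factory([1, 2], [10, 5])
        expected = (10 - 5) / math.log(2) * 1  # 7.2135
        assert kp.auc_trapezoid(prof, 2.0) == pytest.approx(expected, rel=1e-12)

    def test_log_rule_exact_on_exponential_segments(self, profile_factory):
        # on exactly exponential data the log trapezoid equals the analytic
        # integral segment by segment, at machine precision
        k = 0.6931
        t = np.array([0.0, 2.0, 5.0, 12.0])
        c = 10 * np.exp(-k * t)
        prof = profile_factory(t, c)
        analytic = 10 / k * (1 - math.exp(-k * 12))
        assert kp.auc_trapezoid(prof, 12.0) == pytest.approx(analytic, rel=1e-12)

    @pytest.mark.parametrize("step,rtol", [(0.25, 2e-3), (0.05, 1e-4)])
    def test_dense_grid_converges_to_integral(self, profile_factory, step, rtol):
        k = 0.6931
        t = np.arange(0, 12 + step / 2, step)
        prof = profile_factory(t, 10 * np.exp(-k * t))
        analytic = 10 / k * (1 - math.exp(-k * 12))  # = 14.424
        assert kp.auc_trapezoid(prof, 12.0) == pytest.approx(analytic, rel=rtol)

    def test_pure_log_dialect(self, profile_factory):
        # rising exponential segment: log rule integrates it exactly
        t = np.array([0.5, 1.0, 2.0])
        c = 2 * np.exp(0.5 * t)
        prof = profile_factory(t, c)
        analytic = 2 / 0.5 * (math.exp(1.0) - math.exp(0.25))
        assert kp.auc_trapezoid(prof, 2.0, method="log") == pytest.approx(
            analytic, rel=1e-12
        )

    def test_t_end_validation(self, profile_factory):
        prof = profile_factory([0, 1, 2], [1, 2, 1])
        with pytest.raises(ValidationError):
            kp.auc_trapezoid(prof, 3.0)
        with pytest.raises(ValidationError):
            kp.auc_trapezoid(prof, 0.5)

    def test_partial_interval(self, profile_factory):
        prof = profile_factory([0, 1, 3], [10, 10, 10])
        assert kp.auc_trapezoid(prof, 2.0) == pytest.approx(20.0)


class TestAUMC:
    def test_flat_moment(self, profile_factory):
        prof = profile_factory([0, 1], [10, 10])
        assert kp.aumc_trapezoid(prof, 1.0) == pytest.approx(5.0)

    def test_single_interval(self, profile_factory):
        prof = profile_factory([1, 2], [4, 2])
        assert kp.aumc_trapezoid(prof, 2.0) == pytest.approx(4.0)

    def test_dense_exponential_moment(self, profile_factory):
        k = 0.6931
        t = np.arange(0, 20.001, 0.05)
        prof = profile_factory(t, 10 * np.exp(-k * t))
        analytic = 10 / k**2 * (1 - (1 + k * 20) * math.exp(-k * 20))
        assert kp.aumc_trapezoid(prof, 20.0) == pytest.approx(analytic, rel=0.01)


class TestMethodOfResiduals:
    def test_two_exponential_exact(self, profile_factory):
        # A(e^-0.1t - e^-1.0t): residuals of the terminal line are (nearly)
        # exactly the absorption exponential
        t = np.array([0.5, 1, 2, 3, 4, 6, 8, 12, 16, 24], dtype=float)
        c = 10 * (np.exp(-0.1 * t) - np.exp(-1.0 * t))
        prof = profile_factory(t, c)
        fit = kp.fit_terminal_phase(prof)
        assert fit.ke == pytest.approx(0.1, rel=1e-3)
        ka = kp.ka_method_of_residuals(prof, fit)
        assert ka == pytest.approx(1.0, abs=5e-4)

    def test_monotone_rising_prepeak_above_line(self, profile_factory):
        # pre-peak data above the back-extrapolated terminal line
        t = np.array([1.0, 2.0, 4.0, 8.0, 12.0, 24.0])
        c = np.array([50.0, 60.0, 70.0, 10.0, 5.0, 0.6])
        prof = profile_factory(t, c)
        fit = kp.fit_terminal_phase(prof)
        with pytest.raises(NonPositiveResidualError):
            kp.ka_method_of_residuals(prof, fit)

    def test_too_few_prepeak_points(self, profile_factory):
        t = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        c = np.array([5.0, 8.0, 4.0, 2.0, 0.5])
        prof = profile_factory(t, c)
        fit = kp.fit_terminal_phase(prof)
        with pytest.raises(TooFewPointsError):
            kp.ka_method_of_residuals(prof, fit)


class TestRunNCA:
    def test_bateman_auc_infinity(self, profile_factory):
        # AUC0-inf of the one-compartment curve is scale/ke analytically
        scale, ka, ke = 25.0, 0.22, 0.125
        p = kp.SimulationParams(scale=scale, ka=ka, ke=ke, cv=0.0)
        prof = kp.simulate_profile(p)
        with pytest.warns(kp.KoalaPKWarning):
            res = kp.run_nca(prof)
        assert res.auc_0_inf == pytest.approx(scale / ke, rel=0.03)
        # sampled Tmax falls on the grid point bracketing the analytic peak
        assert res.tmax in (4.0, 8.0)
        assert math.log(ka / ke) / (ka - ke) == pytest.approx(5.951, abs=1e-3)

    def test_internal_identities(self, noise_free_profile):
        with pytest.warns(kp.KoalaPKWarning):
            res = kp.run_nca(noise_free_profile)
        assert res.t_half * res.ke == pytest.approx(math.log(2), rel=1e-9)
        assert res.vz_f * res.ke == pytest.approx(res.cl_f, rel=1e-9)
        assert res.mrt * res.auc_0_inf == pytest.approx(res.aumc_0_inf, rel=1e-9)
        assert res.auc_0_inf >= res.auc_0_t
        assert 0 < res.auc_ratio <= 1
        assert res.ka > res.ke

    def test_study_like_auc_ratio_band(self, noise_free_profile):
        # the 24 h truncation leaves ~14% of the area to extrapolation at
        # these parameters
        with pytest.warns(kp.KoalaPKWarning):
            res = kp.run_nca(noise_free_profile)
        assert 0.80 <= res.auc_ratio <= 0.97

    def test_row_order_invariance(self, noise_free_params):
        prof = kp.simulate_profile(noise_free_params)
        perm = np.array([3, 0, 5, 1, 4, 2, 6, 7, 9, 8, 10])
        order = np.argsort(prof.times[perm])
        shuffled = kp.ConcentrationTimeProfile(
            subject_id=prof.subject_id,
            route=prof.route,
            dose=prof.dose,
            times=prof.times[perm][order],
            concentrations=prof.concentrations[perm][order],
            blq=prof.blq[perm][order],
            lloq=prof.lloq,
        )
        with pytest.warns(kp.KoalaPKWarning):
            a = kp.run_nca(prof)
        with pytest.warns(kp.KoalaPKWarning):
            b = kp.run_nca(shuffled)
        for f in ("ke", "t_half", "cmax", "tmax", "auc_0_inf", "aumc_0_inf", "cl_f"):
            assert getattr(a, f) == getattr(b, f)

    def test_too_few_points_propagates(self, profile_factory):
        prof = profile_factory([1.0, 2.0], [5.0, 2.0])
        with pytest.raises(TooFewPointsError):
            kp.run_nca(prof)

    def test_blq_handling(self, profile_factory):
        # leading BLQ integrates as zero; trailing BLQ stops the integration
        t = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0])
        c = np.array([0.0, 0.3, 8.0, 10.0, 5.0, 2.5, 0.7, 0.1])
        prof = kp.ConcentrationTimeProfile(
            subject_id="B", route="oral", dose=15.0, times=t, concentrations=c,
            lloq=0.625,
        )
        assert prof.blq.tolist() == [True, True, False, False, False, False, False, True]
        res = kp.run_nca(prof, t_end=48.0)
        assert res.t_end == 24.0  # last quantifiable sample
        assert "truncated" in "; ".join(res.notes)


class TestProfileValidation:
    def test_unsorted_times_rejected(self):
        with pytest.raises(ValidationError):
            kp.ConcentrationTimeProfile(
                "X", "oral", 15.0, np.array([1.0, 0.5]), np.array([1.0, 2.0])
            )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            kp.ConcentrationTimeProfile(
                "X", "oral", 15.0, np.array([0.5, 1.0]), np.array([1.0, -2.0])
            )

    def test_unknown_route_rejected(self):
        with pytest.raises(ValidationError):
            kp.ConcentrationTimeProfile(
                "X", "intravenous", 15.0, np.array([0.5]), np.array([1.0])
            )
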