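import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import cumulative_trapezoid, quad, solve_ivp

from renalpet.errors import DegenerateInputError, InvalidParameterError
from renalpet.frames import FramingSchedule
from renalpet.input_function import eval_input_function
from renalpet.kinetics import (
    FitDiagnostics,
    KineticParams,
    _forward,
    fit_2tcm,
    ki_macro,
    simulate_tissue,
    simulate_tissue_framed,
)
from .conftest import framed_input_tac


class TestKiMacro:
    def test_closed_form(self):
        assert ki_macro(KineticParams(K1=0.1, k2=0.5, k3=0.1)) == pytest.approx(0.016667, abs=1e-6)

    def test_no_trapping_gives_zero(self):
        assert ki_macro(KineticParams(K1=0.5, k2=1.0, k3=0.0)) == 0.0

    def test_degenerate_denominator(self):
        assert ki_macro(KineticParams(K1=0.5, k2=0.0, k3=0.0)) == 0.0

    @given(
        k1=st.floats(0.01, 2.0),
        k2=st.floats(0.01, 5.0),
        k3=st.floats(0.01, 2.0),
        bump=st.floats(0.01, 1.0),
    )
    def test_strictly_increasing_in_k1_and_k3(self, k1, k2, k3, bump):
        base = ki_macro(KineticParams(K1=k1, k2=k2, k3=k3))
        assert ki_macro(KineticParams(K1=k1 + bump, k2=k2, k3=k3)) > base
        assert ki_macro(KineticParams(K1=k1, k2=k2, k3=k3 + bump)) > base


class TestKineticParamsValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            KineticParams(K1=-0.1, k2=0.5, k3=0.1)

    def test_reversible_model_rejected(self):
        with pytest.raises(InvalidParameterError):
            KineticParams(K1=0.1, k2=0.5, k3=0.1, k4=0.01)

    def test_vb_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            KineticParams(K1=0.1, k2=0.5, k3=0.1, Vb=1.0)


class TestSimulateTissue:
    def test_no_extraction_equals_blood_fraction(self, bolus):
        t = np.linspace(0, 600, 1201)
        kp = KineticParams(K1=0.0, k2=0.5, k3=0.1, Vb=0.3)
        ct = simulate_tissue(bolus, kp, t)
        assert np.allclose(ct, 0.3 * np.asarray(eval_input_function(bolus, t)), atol=1e-12)

    def test_pure_integrator_is_k1_times_plasma_integral(self, bolus):
        t = np.linspace(0, 600, 1201)
        kp = KineticParams(K1=0.25, k2=0.0, k3=0.0, Vb=0.0)
        ct = simulate_tissue(bolus, kp, t)
        cp = np.asarray(eval_input_function(bolus, t))
        expected = (kp.K1 / 60.0) * cumulative_trapezoid(cp, t, initial=0.0)
        # conservation of delivered activity, quadrature-consistent to 1e-6
        assert np.allclose(ct, expected, rtol=1e-6, atol=1e-9)
        assert np.all(np.diff(ct) >= -1e-12)

    def test_matches_stiff_ode_solution(self, bolus):
        kp = KineticParams(K1=0.3, k2=0.6, k3=0.1, Vb=0.05)
        t = np.linspace(0, 2400, 9601)
        ct = simulate_tissue(bolus, kp, t)
        k1s, k2s, k3s = kp.K1 / 60, kp.k2 / 60, kp.k3 / 60

        def rhs(tt, y):
            cp = float(eval_input_function(bolus, tt))
            return [k1s * cp - (k2s + k3s) * y[0], k3s * y[0]]

        sol = solve_ivp(
            rhs, (0, 2400), [0.0, 0.0], t_eval=t, method="LSODA",
            rtol=1e-10, atol=1e-12, max_step=1.0,
        )
        ct_ode = (1 - kp.Vb) * (sol.y[0] + sol.y[1]) + kp.Vb * np.asarray(
            eval_input_function(bolus, t)
        )
        assert np.max(np.abs(ct - ct_ode)) < 1e-3 * ct.max()

    def test_non_negative_everywhere(self, bolus):
        t = np.linspace(0, 2400, 4801)
        ct = simulate_tissue(bolus, KineticParams(K1=0.8, k2=1.4, k3=0.06, Vb=0.2), t)
        assert np.all(ct >= 0)

    def test_grid_must_start_at_zero(self, bolus):
        with pytest.raises(InvalidParameterError):
            simulate_tissue(bolus, KineticParams(K1=0.1, k2=0.5, k3=0.1), np.array([1.0, 2.0]))


def test_framed_means_equal_quadrature_oracle(bolus):
    """Frame averages are exact integrals of the piecewise-linear-input model.

    Independent oracle: the convolution response integrated per frame by
    adaptive quadrature of the explicit kernel expressions.
    """
    kp = KineticParams(K1=0.3, k2=0.6, k3=0.1, Vb=0.05)
    sched = FramingSchedule.from_epochs([(60, 1.0), (12, 10.0)])
    nodes, frame_idx = sched.refined(0.5)
    cp_nodes = np.asarray(eval_input_function(bolus, nodes), float)
    fwd = _forward(nodes, cp_nodes, kp)
    means = np.bincount(frame_idx, weights=fwd.int_ct, minlength=sched.n_frames) / sched.duration

    k1s, k2s, k3s = kp.K1 / 60, kp.k2 / 60, kp.k3 / 60
    beta = k2s + k3s
    cp_lin = lambda s: np.interp(s, nodes, cp_nodes)
    interior = [float(x) for x in nodes]

    def frame_mean_quad(a, b):
        pts_b = [x for x in interior if 0 < x < b]
        i_z = quad(lambda s: cp_lin(s) * (b - max(a, s)), 0, b, points=pts_b, limit=400)[0]

        def kern(s):
            lo = max(a, s)
            return (np.exp(-beta * (lo - s)) - np.exp(-beta * (b - s))) / beta

        i_y = quad(lambda s: cp_lin(s) * kern(s), 0, b, points=pts_b, limit=400)[0]
        i_cp = quad(cp_lin, a, b, points=[x for x in interior if a < x < b], limit=200)[0]
        conv = k1s * (k3s * i_z + k2s * i_y) / beta
        return ((1 - kp.Vb) * conv + kp.Vb * i_cp) / (b - a)

    for i in (10, 20, 40, 59, 60, 65, 71):
        expected = frame_mean_quad(sched.start[i], sched.end[i])
        assert means[i] == pytest.approx(expected, rel=1e-9)


def test_patlak_limit_slope_equals_ki(schedule, bolus, aorta_tac):
    """Late-window Patlak slope of the simulated curve equals K1*k3/(k2+k3)."""
    from renalpet.patlak import LinearWindow, fit_slope, patlak_transform

    rng = np.random.default_rng(11)
    for _ in range(10):
        kp = KineticParams(
            K1=rng.uniform(0.1, 1.2), k2=rng.uniform(0.3, 1.5), k3=rng.uniform(0.02, 0.3), Vb=0.0
        )
        tissue = simulate_tissue_framed(bolus, kp, schedule)
        marker = fit_slope(patlak_transform(tissue, aorta_tac), LinearWindow(1200.0, 2400.0))
        assert marker.slope_per_min == pytest.approx(kp.ki, rel=0.01)


class TestFit2TCM:
    def test_noiseless_recovery_from_perturbed_init(self, schedule, bolus, aorta_tac):
        kp_true = KineticParams(K1=0.3, k2=0.6, k3=0.1, Vb=0.05)
        tissue = simulate_tissue_framed(bolus, kp_true, schedule)
        init = KineticParams(K1=0.45, k2=0.9, k3=0.05, Vb=0.075)  # +/-50% perturbation
        kp_fit, diag = fit_2tcm(tissue, aorta_tac, init=init)
        assert diag.converged
        assert kp_fit.K1 == pytest.approx(kp_true.K1, rel=5e-3)
        assert kp_fit.k2 == pytest.approx(kp_true.k2, rel=5e-3)
        assert kp_fit.k3 == pytest.approx(kp_true.k3, rel=5e-3)
        # fit idempotence: parameters reproduced within optimizer tolerance
        assert kp_fit.ki == pytest.approx(kp_true.ki, rel=1e-3)

    def test_all_zero_tissue_raises(self, schedule, aorta_tac):
        from renalpet.frames import TimeActivityCurve

        zero = TimeActivityCurve(schedule, np.zeros(schedule.n_frames))
        with pytest.raises(DegenerateInputError):
            fit_2tcm(zero, aorta_tac)

    def test_all_zero_input_raises(self, schedule, aorta_tac):
        from renalpet.frames import TimeActivityCurve

        zero = TimeActivityCurve(schedule, np.zeros(schedule.n_frames))
        with pytest.raises(DegenerateInputError):
            fit_2tcm(aorta_tac, zero)

    def test_mismatched_schedules_rejected(self, bolus, aorta_tac):
        short = FramingSchedule.from_epochs([(60, 1.0)])
        tissue = simulate_tissue_framed(bolus, KineticParams(K1=0.3, k2=0.6, k3=0.1), short)
        with pytest.raises(InvalidParameterError):
            fit_2tcm(tissue, aorta_tac)

    def test_diagnostics_invariants(self):
        with pytest.raises(InvalidParameterError):
            FitDiagnostics(residual_sum_squares=-1.0, iterations=3, converged=True, covariance_ok=True)
        with pytest.raises(InvalidParameterError):
            FitDiagnostics(residual_sum_squares=0.0, iterations=0, converged=True, covariance_ok=True)
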