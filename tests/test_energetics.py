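"""Mechanical work, stride length, and the CoT decomposition."""

import numpy as np
import pytest

from ratloco import MuscleCurves, cot, mechanical_work, stride_length
from ratloco.energetics import component_tensions, cycle_report

CURVES = MuscleCurves()


class TestMechanicalWork:
    def grid(self, n=1001):
        return np.linspace(0.0, 1.0, n)

    def test_constant_concentric(self):
        t = self.grid()
        F = np.ones((t.size, 1))
        v = np.full((t.size, 1), 0.1)
        ep, em, W = mechanical_work(F, v, t)
        assert ep == pytest.approx(0.1)
        assert em == 0.0
        assert W == pytest.approx(0.1)

    def test_constant_eccentric_quarter_weight(self):
        t = self.grid()
        F = np.ones((t.size, 1))
        v = np.full((t.size, 1), -0.1)
        ep, em, W = mechanical_work(F, v, t)
        assert ep == 0.0
        assert em == pytest.approx(0.025)

    def test_zero_velocity_zero_work(self):
        t = self.grid()
        F = np.ones((t.size, 3))
        _, _, W = mechanical_work(F, np.zeros((t.size, 3)), t)
        assert W == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            mechanical_work(np.ones((1, 1)), np.ones((1, 1)), np.array([0.0]))

    def test_quadrature_convergence(self):
        """Halving the sampling step changes the work by < 0.1 %."""
        def work(n):
            t = np.linspace(0.0, 0.26, n)
            F = (1.0 + 0.5 * np.sin(2 * np.pi * t / 0.26))[:, None]
            v = (0.05 * np.cos(2 * np.pi * t / 0.26))[:, None]
            return mechanical_work(F, v, t)
        ep1, em1, _ = work(260)
        ep2, em2, _ = work(520)
        assert abs(ep2 - ep1) / ep2 < 1e-3
        assert abs(em2 - em1) / em2 < 1e-3


class TestStrideAndCot:
    def test_constant_speed_stride(self):
        t = np.linspace(0.0, 1.0, 500)
        x = 0.2 * t
        assert stride_length(t, x, (0.3, 0.56)) == pytest.approx(0.052)

    def test_stationary(self):
        t = np.linspace(0.0, 1.0, 100)
        assert stride_length(t, np.zeros_like(t), (0.0, 0.5)) == 0.0

    def test_backward_drift_warns(self):
        t = np.linspace(0.0, 1.0, 100)
        with pytest.warns(UserWarning, match="backward"):
            D = stride_length(t, -0.1 * t, (0.0, 0.5))
        assert D < 0.0

    def test_cot_basics(self):
        assert cot(0.1, 0.1) == pytest.approx(1.0)
        assert cot(0.2, 0.2) == pytest.approx(1.0)   # homogeneity
        assert cot(0.0, 0.1) == 0.0
        assert np.isnan(cot(0.1, 0.0))


class TestDecomposition:
    def synthetic(self, n=521):
        """A one-cycle record where the synergy component is the whole
        command and the regulator components are silent."""
        rng = np.random.default_rng(5)
        t = np.linspace(0.0, 0.26, n)
        M = 4
        a = rng.uniform(0.0, 1.0, (n, M))
        lbar = rng.uniform(0.7, 1.1, (n, M))
        vbar = rng.uniform(-0.5, 0.5, (n, M))
        fmax = np.array([3.5, 11.1, 24.0, 4.1])
        lmax = np.full(M, 0.02)
        x = 0.2 * t
        return t, x, a, lbar, vbar, fmax, lmax

    def test_single_source_decomposition(self):
        """With u_height = u_speed = 0, the synergy CoT equals the
        active-term CoT and the regulator components vanish."""
        t, x, a, lbar, vbar, fmax, lmax = self.synthetic()
        zeros = np.zeros_like(a)
        F = component_tensions(a, lbar, vbar, fmax, CURVES)
        rep = cycle_report(0, (t[0], t[-1]), t, x, F, lbar, vbar,
                           a, a, zeros, zeros, fmax, lmax, CURVES)
        assert rep.cot_height == 0.0
        assert rep.cot_speed == 0.0
        assert rep.cot_syn == pytest.approx(rep.cot_active, rel=1e-9)

    def test_all_zero_commands(self):
        t, x, a, lbar, vbar, fmax, lmax = self.synthetic()
        zeros = np.zeros_like(a)
        F = np.zeros_like(a)
        rep = cycle_report(0, (t[0], t[-1]), t, x, F, lbar, vbar,
                           zeros, zeros, zeros, zeros, fmax, lmax, CURVES)
        assert rep.work == 0.0
        assert (rep.cot_syn, rep.cot_height, rep.cot_speed) == (0.0, 0.0, 0.0)

    def test_report_consistency(self):
        t, x, a, lbar, vbar, fmax, lmax = self.synthetic()
        zeros = np.zeros_like(a)
        F = component_tensions(a, lbar, vbar, fmax, CURVES)
        rep = cycle_report(0, (t[0], t[-1]), t, x, F, lbar, vbar,
                           a, a, zeros, zeros, fmax, lmax, CURVES)
        assert rep.work == pytest.approx(rep.eta_plus + rep.eta_minus)
        assert rep.cot == pytest.approx(rep.work / rep.stride)
        assert rep.mean_speed == pytest.approx(0.2, rel=1e-6)

    def test_mismatched_series_rejected(self):
        with pytest.raises(ValueError):
            component_tensions(np.zeros((10, 2)), np.zeros((9, 2)),
                               np.zeros((9, 2)), np.ones(2), CURVES)
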