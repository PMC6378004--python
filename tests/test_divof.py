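import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import divflow.divof as dv
from divflow.core import SolverConfig, ValidationError, VelocitySlice
from divflow.divof import (
    ConstraintTerms,
    brightness_terms,
    coefficients,
    divergence_terms,
    divof_solve,
    divof_update,
)
from divflow.gradients import d1
from divflow.horn_schunck import hs_solve


def _const_slice(vx, vy, vz, shape=(8, 8), z=0.0):
    return VelocitySlice(np.full(shape, vx), np.full(shape, vy), np.full(shape, vz), z=z)


def _terms(rng, shape=(1, 1), Hz=None):
    g = lambda: rng.normal(size=shape)
    return ConstraintTerms(g(), g(), g() if Hz is None else Hz, g(), g(), g())


class TestBrightnessTerms:
    def test_identical_slices(self, rng):
        I = rng.normal(size=(8, 8))
        Hx, Hy, Hz = brightness_terms(I, I)
        assert np.array_equal(Hz, np.zeros_like(I))
        assert np.allclose(Hx, 2 * d1(I, axis=1))
        assert np.allclose(Hy, 2 * d1(I, axis=0))

    def test_constant_slices(self):
        I = np.full((6, 6), 4.2)
        Hx, Hy, Hz = brightness_terms(I, I)
        assert not np.any(Hx) and not np.any(Hy) and not np.any(Hz)

    def test_offset_upper_shifts_only_hz(self, rng):
        I = rng.normal(size=(8, 8))
        c = 1.7
        Hx0, Hy0, _ = brightness_terms(I, I)
        Hx, Hy, Hz = brightness_terms(I, I + c)
        assert np.allclose(Hz, c)
        assert np.allclose(Hx, Hx0) and np.allclose(Hy, Hy0)


class TestDivergenceTerms:
    def test_constant_identical_slices(self):
        s = _const_slice(1.0, -2.0, 0.5)
        Dx, Dy, Dz = divergence_terms(s, s, delta=1)
        assert not np.any(Dx) and not np.any(Dy) and not np.any(Dz)

    def test_antisymmetry_for_identical_slices(self, rng):
        # all Dx, Dy entries are differences of identical derivatives
        v = rng.normal(size=(3, 10, 10))
        s = VelocitySlice(*v)
        Dx, Dy, _ = divergence_terms(s, s.copy(), delta=1)
        assert np.array_equal(Dx, np.zeros((10, 10)))
        assert np.array_equal(Dy, np.zeros((10, 10)))

    def test_invalid_delta(self):
        s = _const_slice(0, 0, 0)
        with pytest.raises(ValidationError):
            divergence_terms(s, s, delta=0)


class TestCoefficients:
    def test_gamma_zero_has_horn_schunck_structure(self, rng):
        t = _terms(rng, shape=(5, 5))
        c = coefficients(t, gamma=0.0, lam=1.3)
        l2 = 1.3**2
        assert np.allclose(c.A1, l2 * t.Hx**2)
        assert np.allclose(c.B1, l2 * t.Hx * t.Hy)
        assert np.allclose(c.C2, t.Hx * t.Hz)
        assert np.array_equal(c.D1, (t.Hx * t.Dy - t.Hy * t.Dx) ** 2)
        assert np.allclose(c.D2, t.Hx**2 + t.Hy**2 + l2)

    def test_direct_substitution(self):
        # Hx=1, Hy=Dx=Dy=Dz=0, Hz=h, lam=1
        h = 0.4
        one, zero = np.ones((1, 1)), np.zeros((1, 1))
        t = ConstraintTerms(one, zero, h * one, zero, zero, zero)
        c = coefficients(t, gamma=2.0, lam=1.0)
        assert c.A1[0, 0] == 1.0
        assert c.B1[0, 0] == 0.0
        assert c.C1[0, 0] == 0.0
        assert c.C2[0, 0] == h
        assert c.D1[0, 0] == 0.0
        assert c.D2[0, 0] == 2.0

    def test_all_zero_terms(self):
        zero = np.zeros((3, 3))
        t = ConstraintTerms(zero, zero, zero, zero, zero, zero)
        c = coefficients(t, gamma=150.0, lam=2.0)
        for name in ("A1", "B1", "C1", "C2", "D1", "A2", "B2", "C3", "C4", "D3"):
            assert not np.any(getattr(c, name)), name
        assert np.allclose(c.D2, 4.0) and np.allclose(c.D4, 4.0)

    def test_printed_identities(self, rng):
        t = _terms(rng, shape=(4, 4))
        c = coefficients(t, gamma=7.0, lam=0.8)
        assert c.D3 is c.D1 and c.D4 is c.D2
        assert np.array_equal(c.A2, c.B1)

    @given(st.integers(0, 2**31 - 1))
    def test_denominator_at_least_lambda_fourth(self, seed):
        rng = np.random.default_rng(seed)
        t = _terms(rng, shape=(4, 4))
        gamma, lam = rng.uniform(0, 300), rng.uniform(0.2, 3)
        c = coefficients(t, gamma, lam)
        denom = gamma**2 * c.D1 + lam**2 * c.D2
        assert np.all(denom >= lam**4 * (1 - 1e-12))


class TestUpdate:
    def test_zero_terms_identity(self, rng):
        zero = np.zeros((4, 4))
        t = ConstraintTerms(zero, zero, zero, zero, zero, zero)
        c = coefficients(t, gamma=150.0, lam=1.0)
        ab, bb = rng.normal(size=(2, 4, 4))
        a, b = divof_update(ab, bb, c, gamma=150.0, lam=1.0)
        assert np.allclose(a, ab, atol=1e-15) and np.allclose(b, bb, atol=1e-15)

    def test_matches_quadratic_minimizer_oracle(self, rng):
        # independent 2x2 normal-equations solve of the per-pixel quadratic
        worst = 0.0
        for _ in range(300):
            Hx, Hy, Hz, Dx, Dy, Dz, ab, bb = rng.normal(size=8)
            gamma = abs(rng.normal(0, 50))
            lam = rng.uniform(0.5, 2.0)
            g2, l2 = gamma**2, lam**2
            M = np.array(
                [
                    [Hx**2 + g2 * Dx**2 + l2, Hx * Hy + g2 * Dx * Dy],
                    [Hx * Hy + g2 * Dx * Dy, Hy**2 + g2 * Dy**2 + l2],
                ]
            )
            rhs = np.array(
                [l2 * ab - Hx * Hz - g2 * Dx * Dz, l2 * bb - Hy * Hz - g2 * Dy * Dz]
            )
            ref = np.linalg.solve(M, rhs)
            one = np.ones((1, 1))
            t = ConstraintTerms(Hx * one, Hy * one, Hz * one, Dx * one, Dy * one, Dz * one)
            a, b = divof_update(ab * one, bb * one, coefficients(t, gamma, lam), gamma, lam)
            got = np.array([a[0, 0], b[0, 0]])
            worst = max(worst, np.max(np.abs(got - ref) / np.maximum(np.abs(ref), 1e-6)))
        assert worst < 1e-8


class TestSolve:
    def test_constant_identical_slices_zero_flow(self):
        s = _const_slice(1.0, 2.0, -1.0, z=0.0)
        s2 = _const_slice(1.0, 2.0, -1.0, z=1.0)
        flow = divof_solve(s, s2, SolverConfig(iterations=30))
        assert np.array_equal(flow.alpha, np.zeros(s.shape))
        assert np.array_equal(flow.beta, np.zeros(s.shape))

    def test_gamma_zero_reduces_to_horn_schunck(self, small_noisy_stack):
        lo, up = small_noisy_stack.slices[2], small_noisy_stack.slices[4]
        cfg = SolverConfig(gamma=0.0, lam=1.0, iterations=50)
        hist_d, hist_h = [], []
        divof_solve(lo, up, cfg, callback=lambda n, a, b: hist_d.append((a.copy(), b.copy())))
        hs_solve(lo.magnitude(), up.magnitude(), cfg, gradients="symmetric",
                 callback=lambda n, a, b: hist_h.append((a.copy(), b.copy())))
        for (a1, b1), (a2, b2) in zip(hist_d, hist_h):
            assert np.abs(a1 - a2).max() < 1e-10
            assert np.abs(b1 - b2).max() < 1e-10

    def test_terms_computed_once(self, small_noisy_stack, monkeypatch):
        calls = {"b": 0, "d": 0, "c": 0}
        orig_b, orig_d, orig_c = dv.brightness_terms, dv.divergence_terms, dv.coefficients
        monkeypatch.setattr(dv, "brightness_terms", lambda *a, **k: (calls.__setitem__("b", calls["b"] + 1), orig_b(*a, **k))[1])
        monkeypatch.setattr(dv, "divergence_terms", lambda *a, **k: (calls.__setitem__("d", calls["d"] + 1), orig_d(*a, **k))[1])
        monkeypatch.setattr(dv, "coefficients", lambda *a, **k: (calls.__setitem__("c", calls["c"] + 1), orig_c(*a, **k))[1])
        lo, up = small_noisy_stack.slices[2], small_noisy_stack.slices[4]
        divof_solve(lo, up, SolverConfig(iterations=25))
        assert calls == {"b": 1, "d": 1, "c": 1}

    def test_deterministic_bitwise(self, small_noisy_stack):
        lo, up = small_noisy_stack.slices[1], small_noisy_stack.slices[3]
        cfg = SolverConfig(iterations=40)
        f1, f2 = divof_solve(lo, up, cfg), divof_solve(lo, up, cfg)
        assert np.array_equal(f1.alpha, f2.alpha) and np.array_equal(f1.beta, f2.beta)

    def test_shape_mismatch(self):
        a = _const_slice(0, 0, 0, shape=(6, 6))
        b = _const_slice(0, 0, 0, shape=(8, 8))
        with pytest.raises(ValidationError):
            divof_solve(a, b, SolverConfig(iterations=1))
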