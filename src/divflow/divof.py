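"""Symmetric, divergence-constrained optical flow between two outer slices.

The method estimates an in-plane flow (α, β) relating the (unknown) mid-slice
to the two acquired slices at z−Δ and z+Δ, by minimizing

    ∬ (Hx α + Hy β + Hz)² + γ² (Dx α + Dy β + Dz)² + λ² (|∇α|² + |∇β|²) dx dy

where the H-terms encode symmetric brightness constancy of the velocity
magnitude image and the D-terms encode the incompressibility (zero
divergence) of the velocity field at the mid-plane, written entirely in terms
of the two outer slices.  Setting γ=0 reduces the iteration to plain
Horn–Schunck on the magnitude images.

The Jacobi update per pixel is

    αⁿ⁺¹ = ᾱⁿ − (A1 ᾱⁿ + B1 β̄ⁿ + γ² C1 + λ² C2) / (γ² D1 + λ² D2)
    βⁿ⁺¹ = β̄ⁿ − (A2 ᾱⁿ + B2 β̄ⁿ + γ² C3 + λ² C4) / (γ² D3 + λ² D4)

with coefficients that are fixed functions of the constraint terms, so they
are computed once before iterating.  The denominator satisfies
γ²D1 + λ²D2 ≥ λ⁴ > 0, and each update is exactly the minimizer of the local
per-pixel quadratic given the neighborhood averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FlowField, SolverConfig, ValidationError, VelocitySlice
from .gradients import d1, d2, dxy, symmetric_gradients
from .horn_schunck import neighborhood_average

__all__ = [
    "ConstraintTerms",
    "UpdateCoefficients",
    "brightness_terms",
    "divergence_terms",
    "coefficients",
    "divof_update",
    "divof_solve",
]


@dataclass
class ConstraintTerms:
    """Brightness (Hx, Hy, Hz) and divergence (Dx, Dy, Dz) constraint grids."""

    Hx: np.ndarray
    Hy: np.ndarray
    Hz: np.ndarray
    Dx: np.ndarray
    Dy: np.ndarray
    Dz: np.ndarray

    def __post_init__(self) -> None:
        shape = self.Hx.shape
        for name in ("Hx", "Hy", "Hz", "Dx", "Dy", "Dz"):
            g = np.asarray(getattr(self, name), dtype=float)
            if g.shape != shape:
                raise ValidationError("constraint terms must share one shape")
            if not np.all(np.isfinite(g)):
                raise ValidationError(f"{name} contains non-finite values")
            setattr(self, name, g)


@dataclass
class UpdateCoefficients:
    """The twelve per-pixel Jacobi-update coefficient grids.

    Identities hold by construction: D3 is D1, D4 is D2, A2 is B1.
    """

    A1: np.ndarray
    B1: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    D1: np.ndarray
    D2: np.ndarray
    A2: np.ndarray
    B2: np.ndarray
    C3: np.ndarray
    C4: np.ndarray
    D3: np.ndarray
    D4: np.ndarray


def brightness_terms(mag_lower, mag_upper, boundary: str = "replicate", scheme: str = "central"):
    """Symmetric brightness terms from the two outer magnitude images.

    Hx = ∂I(z+Δ)/∂x + ∂I(z−Δ)/∂x, Hy analogous in y, Hz = I(z+Δ) − I(z−Δ).
    """
    return symmetric_gradients(mag_lower, mag_upper, boundary=boundary, scheme=scheme)


def divergence_terms(
    lower: VelocitySlice,
    upper: VelocitySlice,
    delta: float = 1.0,
    boundary: str = "replicate",
    scheme: str = "central",
):
    """Divergence constraint terms (Dx, Dy, Dz) from the two outer slices.

    Dx and Dy are differences of second/mixed derivatives of the in-plane
    components between the upper and lower slices; Dz collects the first
    derivatives of both slices plus 2·∂Vz/∂z estimated from the two-slice
    central difference ``(Vz(z+Δ) − Vz(z−Δ))/Δ`` (Δ in slice-index units), the
    unique estimate that needs no additional slices.
    """
    if upper.shape != lower.shape:
        raise ValidationError("slices must share one shape")
    if delta <= 0:
        raise ValidationError("delta must be > 0")

    def dx1(g):
        return d1(g, axis=1, boundary=boundary, scheme=scheme)

    def dy1(g):
        return d1(g, axis=0, boundary=boundary, scheme=scheme)

    Dx = (d2(upper.vx, axis=1, boundary=boundary) - d2(lower.vx, axis=1, boundary=boundary)) + (
        dxy(upper.vy, boundary=boundary) - dxy(lower.vy, boundary=boundary)
    )
    Dy = (dxy(upper.vx, boundary=boundary) - dxy(lower.vx, boundary=boundary)) + (
        d2(upper.vy, axis=0, boundary=boundary) - d2(lower.vy, axis=0, boundary=boundary)
    )
    Dz = (
        dx1(upper.vx)
        + dx1(lower.vx)
        + dy1(upper.vy)
        + dy1(lower.vy)
        + (upper.vz - lower.vz) / float(delta)
    )
    return Dx, Dy, Dz


def coefficients(terms: ConstraintTerms, gamma: float, lam: float) -> UpdateCoefficients:
    """Per-pixel Jacobi-update coefficients from the constraint terms.

    These follow from eliminating one unknown in the 2×2 normal equations of
    the per-pixel quadratic; the cross determinant
    (Hx Dy − Hy Dx)² appears in A1, B2 and D1, and the update denominator is
    γ² D1 + λ² D2 with D2 = Hx² + Hy² + λ² + γ²Dx² + γ²Dy².
    """
    if lam <= 0:
        raise ValidationError("lam must be > 0")
    g2 = float(gamma) ** 2
    l2 = float(lam) ** 2
    Hx, Hy, Hz = terms.Hx, terms.Hy, terms.Hz
    Dx, Dy, Dz = terms.Dx, terms.Dy, terms.Dz

    cross = (Hx * Dy - Hy * Dx) ** 2
    A1 = g2 * cross + l2 * (Hx**2 + g2 * Dx**2)
    B1 = l2 * (Hx * Hy + g2 * Dx * Dy)
    C1 = Hx * Hz * Dy**2 + Hy**2 * Dx * Dz - Hy * Hz * Dx * Dy - Hx * Hy * Dy * Dz
    C2 = Hx * Hz + g2 * Dx * Dz
    D1 = cross
    D2 = Hx**2 + Hy**2 + l2 + g2 * Dx**2 + g2 * Dy**2
    A2 = B1
    B2 = g2 * cross + l2 * (Hy**2 + g2 * Dy**2)
    C3 = Hy * Hz * Dx**2 + Hx**2 * Dy * Dz - Hx * Hz * Dx * Dy - Hx * Hy * Dx * Dz
    C4 = Hy * Hz + g2 * Dy * Dz
    return UpdateCoefficients(A1, B1, C1, C2, D1, D2, A2, B2, C3, C4, D1, D2)


def divof_update(alpha_bar, beta_bar, coeffs: UpdateCoefficients, gamma: float, lam: float):
    """One elementwise divergence-constrained Jacobi correction step."""
    if lam <= 0:
        raise ValidationError("lam must be > 0 (denominator positivity)")
    g2 = float(gamma) ** 2
    l2 = float(lam) ** 2
    alpha_bar = np.asarray(alpha_bar, dtype=float)
    beta_bar = np.asarray(beta_bar, dtype=float)
    denom = g2 * coeffs.D1 + l2 * coeffs.D2
    alpha = alpha_bar - (coeffs.A1 * alpha_bar + coeffs.B1 * beta_bar + g2 * coeffs.C1 + l2 * coeffs.C2) / denom
    beta = beta_bar - (coeffs.A2 * alpha_bar + coeffs.B2 * beta_bar + g2 * coeffs.C3 + l2 * coeffs.C4) / (
        g2 * coeffs.D3 + l2 * coeffs.D4
    )
    return alpha, beta


def divof_solve(
    lower: VelocitySlice,
    upper: VelocitySlice,
    config: SolverConfig | None = None,
    callback=None,
) -> FlowField:
    """Solve for the symmetric flow between two outer velocity slices.

    Computes the magnitude images, constraint terms and update coefficients
    once, then runs ``config.iterations`` Jacobi sweeps (neighborhood average
    followed by the elementwise correction) from a zero flow.  Deterministic
    for fixed inputs and config.
    """
    cfg = config if config is not None else SolverConfig()
    if upper.shape != lower.shape:
        raise ValidationError("slices must share one shape")

    mag_lo = lower.magnitude()
    mag_up = upper.magnitude()
    Hx, Hy, Hz = brightness_terms(mag_lo, mag_up, boundary=cfg.boundary)
    Dx, Dy, Dz = divergence_terms(lower, upper, delta=cfg.delta, boundary=cfg.boundary)
    terms = ConstraintTerms(Hx, Hy, Hz, Dx, Dy, Dz)
    coeffs = coefficients(terms, cfg.gamma, cfg.lam)

    denom = cfg.gamma**2 * coeffs.D1 + cfg.lam**2 * coeffs.D2
    if np.min(denom) < cfg.lam**4 * (1 - 1e-12):
        raise ValidationError("update denominator fell below lambda^4")

    alpha = np.zeros(lower.shape)
    beta = np.zeros(lower.shape)
    for n in range(cfg.iterations):
        ab = neighborhood_average(alpha)
        bb = neighborhood_average(beta)
        new_a, new_b = divof_update(ab, bb, coeffs, cfg.gamma, cfg.lam)
        step = max(np.max(np.abs(new_a - alpha)), np.max(np.abs(new_b - beta)))
        alpha, beta = new_a, new_b
        if callback is not None:
            callback(n, alpha, beta)
        if cfg.tol is not None and step < cfg.tol:
            break
    return FlowField(alpha, beta)
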