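"""Baseline Horn–Schunck optical flow.

The variational problem minimizes the brightness-constancy residual
``(Ix α + Iy β + It)²`` plus ``λ²`` times the smoothness penalty on the flow,
via the classical Jacobi iteration in which each sweep replaces the flow by a
weighted 3×3 neighborhood average corrected along the brightness gradient.
Used both as a comparator method and as the γ=0 reduction of the
divergence-constrained solver.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import FlowField, SolverConfig, ValidationError, as_grid
from .gradients import hs_gradients, symmetric_gradients

__all__ = ["neighborhood_average", "hs_update", "hs_solve", "hs_energy"]

# 3x3 Horn–Schunck averaging kernel: 1/6 on the 4-neighbors, 1/12 on diagonals.
_AVG_KERNEL = np.array(
    [
        [1 / 12, 1 / 6, 1 / 12],
        [1 / 6, 0.0, 1 / 6],
        [1 / 12, 1 / 6, 1 / 12],
    ]
)


def neighborhood_average(grid) -> np.ndarray:
    """Weighted 3×3 flow average (1/6 edge, 1/12 diagonal neighbors)."""
    g = as_grid(grid)
    if g.shape[0] < 3 or g.shape[1] < 3:
        raise ValidationError("grid must be at least 3x3")
    return ndimage.convolve(g, _AVG_KERNEL, mode="nearest")


def hs_update(alpha_bar, beta_bar, Ix, Iy, It, lam: float):
    """One elementwise Horn–Schunck correction step.

    α⁺ = ᾱ − Ix (Ix ᾱ + Iy β̄ + It) / (λ² + Ix² + Iy²), analogously for β.
    Equivalently the per-pixel minimizer of the local quadratic
    (Ix α + Iy β + It)² + λ²[(α − ᾱ)² + (β − β̄)²].
    """
    if lam <= 0:
        raise ValidationError("lam must be > 0")
    alpha_bar = np.asarray(alpha_bar, dtype=float)
    beta_bar = np.asarray(beta_bar, dtype=float)
    resid = Ix * alpha_bar + Iy * beta_bar + It
    denom = lam**2 + Ix**2 + Iy**2
    return alpha_bar - Ix * resid / denom, beta_bar - Iy * resid / denom


def hs_solve(
    I_prev,
    I_next,
    config: SolverConfig | None = None,
    gradients: str = "hs",
    callback=None,
) -> FlowField:
    """Iterate Horn–Schunck flow between two equal-shape scalar images.

    ``gradients="hs"`` uses the classical cube-averaged kernels (flow is the
    full displacement from I_prev to I_next).  ``gradients="symmetric"`` uses
    the two-slice symmetric terms (Hx, Hy, Hz), under which the flow is the
    half-displacement of the symmetric interpolation setup and the iteration
    coincides with the divergence-constrained solver at γ=0.

    Flow starts at zero; for identical frames the zero flow is a fixed point.
    ``callback(n, alpha, beta)`` is invoked after each sweep if given.
    """
    cfg = config if config is not None else SolverConfig()
    a = as_grid(I_prev, "I_prev")
    b = as_grid(I_next, "I_next")
    if a.shape != b.shape:
        raise ValidationError("images must share one shape")
    if gradients == "hs":
        Ix, Iy, It = hs_gradients(a, b)
    elif gradients == "symmetric":
        Ix, Iy, It = symmetric_gradients(a, b, boundary=cfg.boundary)
    else:
        raise ValidationError(f"unknown gradients mode {gradients!r}")

    alpha = np.zeros_like(a)
    beta = np.zeros_like(a)
    for n in range(cfg.iterations):
        ab = neighborhood_average(alpha)
        bb = neighborhood_average(beta)
        new_a, new_b = hs_update(ab, bb, Ix, Iy, It, cfg.lam)
        step = max(np.max(np.abs(new_a - alpha)), np.max(np.abs(new_b - beta)))
        alpha, beta = new_a, new_b
        if callback is not None:
            callback(n, alpha, beta)
        if cfg.tol is not None and step < cfg.tol:
            break
    return FlowField(alpha, beta)


def hs_energy(alpha, beta, Ix, Iy, It, lam: float) -> float:
    """Discrete optical-flow energy monitored by the iteration.

    Data residual plus λ² times the averaging-kernel quadratic form
    Σ α·(α − Wα) + Σ β·(β − Wβ), the smoothness discretization consistent
    with the neighborhood-average sweep (W is the 3×3 averaging operator,
    whose eigenvalues lie in [−1/3, 1], which makes each sweep a descent
    step on this energy).
    """
    resid = Ix * alpha + Iy * beta + It
    smooth = np.sum(alpha * (alpha - neighborhood_average(alpha)))
    smooth += np.sum(beta * (beta - neighborhood_average(beta)))
    return float(np.sum(resid**2) + lam**2 * smooth)
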