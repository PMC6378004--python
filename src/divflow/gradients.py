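"""Finite-difference stencils shared by the solvers and the divergence metric.

Axis convention: ``axis=0`` is y (rows), ``axis=1`` is x (columns).  All
stencils work in pixel units (no spacing division); physical spacings are
applied only by the divergence metric.  Interior stencils are the standard
second-order central ones, exact on linears (first derivative), quadratics
(second derivative) and bilinears (mixed derivative).  Boundary rows/columns
are handled by padding in the requested mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ValidationError, as_grid

__all__ = ["StencilSpec", "d1", "d2", "dxy", "hs_gradients", "symmetric_gradients"]

_PAD_MODE = {"replicate": "edge", "reflect": "reflect"}


def _pad1(g: np.ndarray, axis: int, boundary: str) -> np.ndarray:
    if boundary not in _PAD_MODE:
        raise ValidationError(f"unknown boundary mode {boundary!r}")
    pw = [(0, 0), (0, 0)]
    pw[axis] = (1, 1)
    return np.pad(g, pw, mode=_PAD_MODE[boundary])


def _check_axis(g: np.ndarray, axis: int) -> None:
    if axis not in (0, 1):
        raise ValidationError(f"axis must be 0 (y) or 1 (x), got {axis}")
    if g.shape[axis] < 3:
        raise ValidationError(f"grid must span >= 3 samples along axis {axis}")


def d1(grid, axis: int = 1, boundary: str = "replicate", scheme: str = "central") -> np.ndarray:
    """First derivative along ``axis`` in pixel units.

    ``central`` (default): (f[i+1] − f[i−1])/2; ``forward``: f[i+1] − f[i].
    """
    g = as_grid(grid)
    _check_axis(g, axis)
    p = _pad1(g, axis, boundary)
    if axis == 0:
        hi, lo, mid = p[2:, :], p[:-2, :], p[1:-1, :]
    else:
        hi, lo, mid = p[:, 2:], p[:, :-2], p[:, 1:-1]
    if scheme == "central":
        return (hi - lo) / 2.0
    if scheme == "forward":
        return hi - mid
    raise ValidationError(f"unknown scheme {scheme!r}")


def d2(grid, axis: int = 1, boundary: str = "replicate") -> np.ndarray:
    """Second derivative along ``axis``: f[i+1] − 2f[i] + f[i−1]."""
    g = as_grid(grid)
    _check_axis(g, axis)
    p = _pad1(g, axis, boundary)
    if axis == 0:
        return p[2:, :] - 2.0 * p[1:-1, :] + p[:-2, :]
    return p[:, 2:] - 2.0 * p[:, 1:-1] + p[:, :-2]


def dxy(grid, boundary: str = "replicate") -> np.ndarray:
    """Mixed second derivative: d1 along x composed with d1 along y.

    Commutes exactly with the reverse composition in the interior.
    """
    g = as_grid(grid)
    if g.shape[0] < 3 or g.shape[1] < 3:
        raise ValidationError("grid must be at least 3x3 for mixed derivatives")
    return d1(d1(g, axis=1, boundary=boundary), axis=0, boundary=boundary)


@dataclass
class StencilSpec:
    """Configuration of one derivative operator (order, axes, boundary)."""

    order: str = "1"  # "1" | "2" | "mixed"
    axis: int = 1
    boundary: str = "replicate"
    scheme: str = "central"

    def __post_init__(self) -> None:
        if self.order not in ("1", "2", "mixed"):
            raise ValidationError("order must be '1', '2' or 'mixed'")
        if self.boundary not in _PAD_MODE:
            raise ValidationError(f"boundary mode must be one of {tuple(_PAD_MODE)}")

    def apply(self, grid) -> np.ndarray:
        if self.order == "1":
            return d1(grid, self.axis, self.boundary, self.scheme)
        if self.order == "2":
            return d2(grid, self.axis, self.boundary)
        return dxy(grid, self.boundary)


def hs_gradients(I_prev, I_next):
    """Classical Horn–Schunck gradient estimates between two frames.

    ``Ix`` and ``Iy`` are forward differences averaged over the 2×2×2 cube
    spanning both frames; ``It`` is the frame difference averaged over the
    2×2 in-plane block.  The trailing row/column is replicated so shapes are
    preserved.
    """
    a = as_grid(I_prev, "I_prev")
    b = as_grid(I_next, "I_next")
    if a.shape != b.shape:
        raise ValidationError("frames must share one shape")
    ap = np.pad(a, ((0, 1), (0, 1)), mode="edge")
    bp = np.pad(b, ((0, 1), (0, 1)), mode="edge")

    def fx(f):
        return f[:-1, 1:] - f[:-1, :-1] + f[1:, 1:] - f[1:, :-1]

    def fy(f):
        return f[1:, :-1] - f[:-1, :-1] + f[1:, 1:] - f[:-1, 1:]

    Ix = 0.25 * (fx(ap) + fx(bp))
    Iy = 0.25 * (fy(ap) + fy(bp))
    d = bp - ap
    It = 0.25 * (d[:-1, :-1] + d[:-1, 1:] + d[1:, :-1] + d[1:, 1:])
    return Ix, Iy, It


def symmetric_gradients(I_lower, I_upper, boundary: str = "replicate", scheme: str = "central"):
    """Two-slice symmetric brightness terms (Hx, Hy, Hz).

    ``Hx`` and ``Hy`` sum the central x/y derivatives of the two outer
    magnitude images; ``Hz`` is their plain difference (upper minus lower).
    """
    lo = as_grid(I_lower, "I_lower")
    up = as_grid(I_upper, "I_upper")
    if lo.shape != up.shape:
        raise ValidationError("magnitude images must share one shape")
    Hx = d1(up, axis=1, boundary=boundary, scheme=scheme) + d1(lo, axis=1, boundary=boundary, scheme=scheme)
    Hy = d1(up, axis=0, boundary=boundary, scheme=scheme) + d1(lo, axis=0, boundary=boundary, scheme=scheme)
    Hz = up - lo
    return Hx, Hy, Hz
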