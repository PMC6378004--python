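"""Domain containers, grid conventions, and validation.

Grid convention used everywhere in this package: 2D arrays are indexed
``[row, col] = [y, x]``, 0-based, pixel-centered.  Solvers operate in
pixel / slice-index units; the physical spacings ``(dx, dy, dz)`` stored on a
:class:`VelocityVolume` are applied only when evaluating the physical
divergence metric.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ValidationError",
    "VelocitySlice",
    "VelocityVolume",
    "FlowField",
    "SolverConfig",
    "EvalReport",
    "magnitude",
    "pad_to",
]


class ValidationError(ValueError):
    """Raised when a domain object or operation input violates an invariant."""


def as_grid(a, name: str = "grid") -> np.ndarray:
    """Coerce to a finite 2D float array or raise :class:`ValidationError`."""
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class VelocitySlice:
    """One z-plane of a velocity volume.

    Three co-registered scalar grids (``vx``, ``vy``, ``vz``) of identical
    shape ``(ny, nx)`` in consistent velocity units, plus the plane's z
    coordinate.  The per-pixel Euclidean norm of the vector is the *velocity
    magnitude image* used as the brightness signal for optical flow.
    """

    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray
    z: float = 0.0

    def __post_init__(self) -> None:
        self.vx = as_grid(self.vx, "vx")
        self.vy = as_grid(self.vy, "vy")
        self.vz = as_grid(self.vz, "vz")
        if not (self.vx.shape == self.vy.shape == self.vz.shape):
            raise ValidationError(
                "vx, vy, vz must share one shape, got "
                f"{self.vx.shape}, {self.vy.shape}, {self.vz.shape}"
            )
        self.z = float(self.z)
        if not np.isfinite(self.z):
            raise ValidationError("z must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vx.shape

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.vx**2 + self.vy**2 + self.vz**2)

    def copy(self) -> "VelocitySlice":
        return VelocitySlice(self.vx.copy(), self.vy.copy(), self.vz.copy(), self.z)


def magnitude(slc: VelocitySlice) -> np.ndarray:
    """Elementwise Euclidean norm ``sqrt(vx² + vy² + vz²)`` of a slice."""
    return slc.magnitude()


@dataclass
class VelocityVolume:
    """Ordered stack of :class:`VelocitySlice` with grid spacings.

    ``dx, dy`` are in-plane physical spacings and ``dz`` the nominal
    out-of-plane spacing between consecutive slices; slice z-coordinates must
    be strictly increasing.
    """

    slices: list[VelocitySlice]
    dx: float = 1.0
    dy: float = 1.0
    dz: float = 1.0

    def __post_init__(self) -> None:
        if len(self.slices) == 0:
            raise ValidationError("volume must contain at least one slice")
        shape = self.slices[0].shape
        for s in self.slices:
            if s.shape != shape:
                raise ValidationError("all slices must share one shape")
        zs = self.zs
        if len(zs) > 1 and not np.all(np.diff(zs) > 0):
            raise ValidationError("slice z-coordinates must be strictly increasing")
        for name in ("dx", "dy", "dz"):
            v = float(getattr(self, name))
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be positive and finite")
            setattr(self, name, v)

    @property
    def zs(self) -> np.ndarray:
        return np.array([s.z for s in self.slices])

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    @property
    def nz(self) -> int:
        return len(self.slices)

    def copy(self) -> "VelocityVolume":
        return VelocityVolume([s.copy() for s in self.slices], self.dx, self.dy, self.dz)


@dataclass
class FlowField:
    """Per-pixel in-plane displacement (alpha, beta) in pixel units.

    The sign convention follows the symmetric two-slice setup: ``(alpha,
    beta)`` displaces a mid-slice coordinate forward into the upper slice and
    backward into the lower slice.
    """

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = as_grid(self.alpha, "alpha")
        self.beta = as_grid(self.beta, "beta")
        if self.alpha.shape != self.beta.shape:
            raise ValidationError("alpha and beta must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.alpha.shape


_BOUNDARIES = ("replicate", "reflect")


@dataclass
class SolverConfig:
    """Parameters of the variational solvers and the evaluation protocol.

    gamma
        Weight of the divergence term (enters the functional squared); 0
        recovers plain Horn–Schunck.
    lam
        Weight of the smoothness term (enters squared); must be positive so
        the Jacobi update denominator ``γ²D1 + λ²D2 ≥ λ⁴`` stays positive.
    iterations
        Fixed number of Jacobi sweeps.
    delta
        Slice half-offset Δ in slice-index units (1 reconstructs from the two
        nearest neighbours, 2 from the slices two steps away).
    boundary
        Finite-difference boundary handling, ``replicate`` or ``reflect``.
    region
        Side length of the centered square window over which MSE and
        divergence statistics are evaluated.
    tol
        Optional early-stop threshold on the max absolute flow update; by
        default iteration count alone controls termination.
    """

    gamma: float = 150.0
    lam: float = 1.0
    iterations: int = 2000
    delta: int = 1
    boundary: str = "replicate"
    region: int = 110
    tol: float | None = None

    def __post_init__(self) -> None:
        self.gamma = float(self.gamma)
        self.lam = float(self.lam)
        if not (np.isfinite(self.gamma) and self.gamma >= 0):
            raise ValidationError("gamma must be finite and >= 0")
        if not (np.isfinite(self.lam) and self.lam > 0):
            raise ValidationError("lam must be finite and > 0")
        if int(self.iterations) < 1:
            raise ValidationError("iterations must be a positive integer")
        self.iterations = int(self.iterations)
        if int(self.delta) < 1:
            raise ValidationError("delta must be a positive integer")
        self.delta = int(self.delta)
        if self.boundary not in _BOUNDARIES:
            raise ValidationError(f"boundary must be one of {_BOUNDARIES}")
        if int(self.region) < 1:
            raise ValidationError("region must be a positive integer")
        self.region = int(self.region)
        if self.tol is not None and not (np.isfinite(self.tol) and self.tol > 0):
            raise ValidationError("tol must be positive when given")

    def replace(self, **kw) -> "SolverConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class EvalReport:
    """Per-slice and aggregate reconstruction statistics for one method."""

    method: str
    per_slice: list[dict] = field(default_factory=list)
    mse: float = np.nan
    div_mean_abs: float = np.nan
    div_ss: float = np.nan

    def __post_init__(self) -> None:
        for v in (self.mse, self.div_mean_abs, self.div_ss):
            if np.isfinite(v) and v < 0:
                raise ValidationError("report statistics must be >= 0")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "mse": self.mse,
            "div_mean_abs": self.div_mean_abs,
            "div_ss": self.div_ss,
            "per_slice": self.per_slice,
        }


def pad_to(grid, target_ny: int, target_nx: int):
    """Center a grid in a zero-filled ``(target_ny, target_nx)`` frame.

    Per dimension, the input is centrally cropped if it exceeds the target
    and centrally zero-padded if it is smaller (crop precedes pad).  Returns
    ``(out, (row_off, col_off))`` where the offsets give the output position
    of the input's origin pixel; negative offsets mean the origin was cropped
    away.  ``pad_to`` followed by cropping back with the offsets is the
    identity on the retained region.
    """
    g = as_grid(grid, "grid")
    target_ny, target_nx = int(target_ny), int(target_nx)
    if target_ny < 1 or target_nx < 1:
        raise ValidationError("target dimensions must be positive")

    offs = []
    for axis, target in ((0, target_ny), (1, target_nx)):
        n = g.shape[axis]
        if n > target:  # central crop
            start = (n - target) // 2
            sl = [slice(None), slice(None)]
            sl[axis] = slice(start, start + target)
            g = g[tuple(sl)]
            offs.append(-start)
        else:  # central zero-pad
            before = (target - n) // 2
            pw = [(0, 0), (0, 0)]
            pw[axis] = (before, target - n - before)
            g = np.pad(g, pw, mode="constant")
            offs.append(before)
    return g, (offs[0], offs[1])
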