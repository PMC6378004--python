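"""Mid-slice reconstruction from a flow field, plus non-flow baselines.

The symmetric setup says a mid-slice point (x, y) corresponds to
(x+α, y+β) in the upper slice and (x−α, y−β) in the lower slice, so the
reconstruction is the motion-compensated average

    C_mid(x, y) = ½ [ C_upper(x+α, y+β) + C_lower(x−α, y−β) ]

per velocity component C, with bilinear sampling and replicate handling of
out-of-range coordinates.  Zero flow reduces this exactly to the linear
(elementwise-average) baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import FlowField, SolverConfig, ValidationError, VelocitySlice, VelocityVolume
from .divof import divof_solve
from .horn_schunck import hs_solve

__all__ = [
    "warp_midslice",
    "linear_midslice",
    "sinc_midslice",
    "interpolate_volume",
    "InterpolationResult",
    "METHODS",
]

METHODS = ("divof", "hs", "linear", "sinc")


def _sample(grid: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    # bilinear interpolation, replicate beyond the border
    return ndimage.map_coordinates(grid, [rows, cols], order=1, mode="nearest")


def warp_midslice(lower: VelocitySlice, upper: VelocitySlice, flow: FlowField) -> VelocitySlice:
    """Symmetric motion-compensated average of the two outer slices."""
    if lower.shape != upper.shape:
        raise ValidationError("slices must share one shape")
    if flow.shape != lower.shape:
        raise ValidationError("flow shape must match the slices")
    ny, nx = lower.shape
    rows, cols = np.mgrid[0:ny, 0:nx].astype(float)
    up_r, up_c = rows + flow.beta, cols + flow.alpha
    lo_r, lo_c = rows - flow.beta, cols - flow.alpha
    comps = {}
    for name in ("vx", "vy", "vz"):
        cu = _sample(getattr(upper, name), up_r, up_c)
        cl = _sample(getattr(lower, name), lo_r, lo_c)
        comps[name] = 0.5 * (cu + cl)
    return VelocitySlice(comps["vx"], comps["vy"], comps["vz"], z=0.5 * (lower.z + upper.z))


def linear_midslice(lower: VelocitySlice, upper: VelocitySlice) -> VelocitySlice:
    """Elementwise mean of each component (exact for fields linear in z)."""
    if lower.shape != upper.shape:
        raise ValidationError("slices must share one shape")
    return VelocitySlice(
        0.5 * (lower.vx + upper.vx),
        0.5 * (lower.vy + upper.vy),
        0.5 * (lower.vz + upper.vz),
        z=0.5 * (lower.z + upper.z),
    )


def sinc_midslice(volume: VelocityVolume, z_target: float, taps: int = 6) -> VelocitySlice:
    """Truncated-sinc interpolation along z from the ``taps`` nearest slices.

    Weights are sinc((z_target − z_k)/dz) renormalized to sum to one, so an
    existing slice position is reproduced exactly and the half-way point of
    two slices with taps=2 reduces to the linear baseline.
    """
    if taps < 2:
        raise ValidationError("taps must be >= 2")
    if volume.nz < taps:
        raise ValidationError(f"volume has {volume.nz} slices, fewer than taps={taps}")
    zs = volume.zs
    if not (zs[0] <= z_target <= zs[-1]):
        raise ValidationError("z_target must lie within the slice range")
    order = np.argsort(np.abs(zs - z_target), kind="stable")[:taps]
    w = np.sinc((z_target - zs[order]) / volume.dz)
    total = w.sum()
    if abs(total) < 1e-12:
        raise ValidationError("sinc weights sum to zero; cannot renormalize")
    w = w / total
    vx = sum(wk * volume.slices[k].vx for wk, k in zip(w, order))
    vy = sum(wk * volume.slices[k].vy for wk, k in zip(w, order))
    vz = sum(wk * volume.slices[k].vz for wk, k in zip(w, order))
    return VelocitySlice(vx, vy, vz, z=float(z_target))


@dataclass
class InterpolationResult:
    """Reconstructed volume plus the per-slice flows (flow methods only)."""

    volume: VelocityVolume
    method: str
    targets: list[int]
    flows: dict[int, FlowField] = field(default_factory=dict)


def default_targets(volume: VelocityVolume, delta: int) -> list[int]:
    """All 0-based indices whose outer slices at ±delta exist."""
    return list(range(delta, volume.nz - delta))


def interpolate_volume(
    volume: VelocityVolume,
    method: str = "divof",
    config: SolverConfig | None = None,
    targets: list[int] | None = None,
    taps: int = 6,
) -> InterpolationResult:
    """Reconstruct interior slices of a volume from their outer neighbours.

    Each target slice k (0-based) is rebuilt from slices k−Δ and k+Δ (flow
    and linear methods) or from the remaining stack at the same Δ-striding
    (sinc).  Non-target slices are copied through unchanged.  The ``hs``
    method runs the identical symmetric reconstruction path with the plain
    Horn–Schunck iteration (no divergence term), so method differences
    isolate the divergence constraint.
    """
    cfg = config if config is not None else SolverConfig()
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {METHODS}")
    delta = cfg.delta
    if targets is None:
        targets = default_targets(volume, delta)
    if len(targets) == 0:
        raise ValidationError("no target slices to reconstruct")
    for k in targets:
        if not (0 <= k - delta and k + delta < volume.nz):
            raise ValidationError(
                f"target slice {k} needs outer slices {k - delta} and {k + delta}"
            )

    out = volume.copy()
    flows: dict[int, FlowField] = {}
    for k in targets:
        lower, upper = volume.slices[k - delta], volume.slices[k + delta]
        if method == "linear":
            mid = linear_midslice(lower, upper)
        elif method == "sinc":
            # odd multiples of delta only: the decimated stack with period
            # 2*delta*dz in which the target sits half-way between samples
            # (even multiples are integer sinc offsets with zero weight)
            keep = [k + m * delta for m in range(-volume.nz, volume.nz + 1)
                    if m % 2 != 0 and 0 <= k + m * delta < volume.nz]
            sub = VelocityVolume(
                [volume.slices[i].copy() for i in keep],
                dx=volume.dx, dy=volume.dy, dz=2 * volume.dz * delta,
            )
            n_taps = min(taps, sub.nz)
            if n_taps < 2:
                raise ValidationError("not enough slices for sinc interpolation")
            mid = sinc_midslice(sub, volume.slices[k].z, taps=n_taps)
        else:
            if method == "divof":
                flow = divof_solve(lower, upper, cfg)
            else:  # hs comparator: symmetric formulation without divergence term
                flow = hs_solve(
                    lower.magnitude(), upper.magnitude(), cfg, gradients="symmetric"
                )
            flows[k] = flow
            mid = warp_midslice(lower, upper, flow)
        mid.z = volume.slices[k].z
        out.slices[k] = mid
    return InterpolationResult(volume=out, method=method, targets=list(targets), flows=flows)
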