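"""Evaluation quantities: regional MSE, mid-plane divergence, and sweeps.

MSE is computed on the velocity magnitude over a centered square window
(per-component MSE is reported alongside).  The divergence of a reconstructed
mid-slice is

    D = ∂Vx/∂x / dx + ∂Vy/∂y / dy + (Vz_upper − Vz_lower) / (z_upper − z_lower)

with in-plane derivatives from the reconstruction under test and the z-term
from the *true* outer slices, so the metric isolates the reconstruction.
Both the mean absolute divergence and the sum of squares over the window are
reported; neither reduction is privileged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import EvalReport, SolverConfig, ValidationError, VelocitySlice, VelocityVolume
from .gradients import d1
from .interpolate import interpolate_volume

__all__ = ["central_window", "mse_region", "slice_divergence", "evaluate", "sweep"]


def central_window(shape: tuple[int, int], side: int):
    """Slices selecting the centered ``side × side`` window, plus offsets."""
    ny, nx = shape
    side = int(side)
    if side < 1 or side > ny or side > nx:
        raise ValidationError(f"region side {side} does not fit in shape {shape}")
    r0 = (ny - side) // 2
    c0 = (nx - side) // 2
    return (slice(r0, r0 + side), slice(c0, c0 + side)), (r0, c0)


def mse_region(
    estimate: VelocitySlice,
    truth: VelocitySlice,
    region_side: int,
    per_component: bool = False,
):
    """Mean squared magnitude error over the centered evaluation window."""
    if estimate.shape != truth.shape:
        raise ValidationError("estimate and truth must share one shape")
    (ry, rx), _ = central_window(estimate.shape, region_side)
    diff = estimate.magnitude()[ry, rx] - truth.magnitude()[ry, rx]
    mse = float(np.mean(diff**2))
    if not per_component:
        return mse
    comps = {
        name: float(np.mean((getattr(estimate, name)[ry, rx] - getattr(truth, name)[ry, rx]) ** 2))
        for name in ("vx", "vy", "vz")
    }
    return mse, comps


def slice_divergence(
    mid: VelocitySlice,
    lower: VelocitySlice,
    upper: VelocitySlice,
    dx: float = 1.0,
    dy: float = 1.0,
    region_side: int | None = None,
    boundary: str = "replicate",
):
    """Discrete mid-plane divergence field and its regional statistics.

    Returns ``(field, mean_abs, sum_sq)`` where the statistics are taken over
    the centered ``region_side`` window (the whole slice if None).
    """
    if not (mid.shape == lower.shape == upper.shape):
        raise ValidationError("slices must share one shape")
    if dx <= 0 or dy <= 0:
        raise ValidationError("spacings must be positive")
    dz_gap = upper.z - lower.z
    if dz_gap <= 0:
        raise ValidationError("upper slice must lie above lower slice in z")
    div = (
        d1(mid.vx, axis=1, boundary=boundary) / dx
        + d1(mid.vy, axis=0, boundary=boundary) / dy
        + (upper.vz - lower.vz) / dz_gap
    )
    if region_side is None:
        win = div
    else:
        (ry, rx), _ = central_window(div.shape, region_side)
        win = div[ry, rx]
    return div, float(np.mean(np.abs(win))), float(np.sum(win**2))


def evaluate(
    truth_volume: VelocityVolume,
    recon_volume: VelocityVolume,
    config: SolverConfig | None = None,
    targets: list[int] | None = None,
    method: str = "divof",
) -> EvalReport:
    """Per-slice and aggregate MSE / divergence report for one method.

    ``targets`` are the 0-based indices of the reconstructed slices; for each
    the MSE is measured against the truth slice and the divergence z-term
    uses the truth outer slices at ±config.delta.
    """
    cfg = config if config is not None else SolverConfig()
    if truth_volume.nz != recon_volume.nz or truth_volume.shape != recon_volume.shape:
        raise ValidationError("truth and reconstruction volumes must match in geometry")
    if targets is None or len(targets) == 0:
        raise ValidationError("evaluate requires a non-empty list of target slices")

    rows = []
    for k in targets:
        if not (0 <= k - cfg.delta and k + cfg.delta < truth_volume.nz):
            raise ValidationError(f"target {k} lacks outer slices at ±{cfg.delta}")
        est = recon_volume.slices[k]
        tru = truth_volume.slices[k]
        mse, comps = mse_region(est, tru, cfg.region, per_component=True)
        _, mean_abs, sum_sq = slice_divergence(
            est,
            truth_volume.slices[k - cfg.delta],
            truth_volume.slices[k + cfg.delta],
            dx=truth_volume.dx,
            dy=truth_volume.dy,
            region_side=cfg.region,
            boundary=cfg.boundary,
        )
        rows.append(
            {
                "slice": k,
                "mse": mse,
                "mse_vx": comps["vx"],
                "mse_vy": comps["vy"],
                "mse_vz": comps["vz"],
                "div_mean_abs": mean_abs,
                "div_ss": sum_sq,
            }
        )
    return EvalReport(
        method=method,
        per_slice=rows,
        mse=float(np.mean([r["mse"] for r in rows])),
        div_mean_abs=float(np.mean([r["div_mean_abs"] for r in rows])),
        div_ss=float(np.mean([r["div_ss"] for r in rows])),
    )


def sweep(
    input_volume: VelocityVolume,
    gammas,
    lambdas,
    config: SolverConfig | None = None,
    truth_volume: VelocityVolume | None = None,
    targets: list[int] | None = None,
) -> pd.DataFrame:
    """Run the divergence-constrained method over a (γ, λ) grid.

    One reconstruction + evaluation per pair on the same inputs; rows ordered
    by (γ, λ).  ``truth_volume`` defaults to the input volume itself (the
    acquired-data protocol, where the held-out slice is the reference).
    """
    cfg = config if config is not None else SolverConfig()
    gammas = list(gammas)
    lambdas = list(lambdas)
    if len(gammas) == 0 or len(lambdas) == 0:
        raise ValidationError("gamma and lambda grids must be non-empty")
    truth = truth_volume if truth_volume is not None else input_volume
    if targets is None:
        targets = list(range(cfg.delta, input_volume.nz - cfg.delta))

    rows = []
    for g in sorted(gammas):
        for l in sorted(lambdas):
            c = cfg.replace(gamma=g, lam=l)
            res = interpolate_volume(input_volume, method="divof", config=c, targets=targets)
            rep = evaluate(truth, res.volume, c, targets=targets, method="divof")
            rows.append(
                {
                    "gamma": g,
                    "lam": l,
                    "mse": rep.mse,
                    "div_mean_abs": rep.div_mean_abs,
                    "div_ss": rep.div_ss,
                }
            )
    return pd.DataFrame(rows)
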