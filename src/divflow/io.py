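"""Delimited-text volume format, modelled on columnar PIV ASCII exports.

A volume file is plain CSV with comment-prefixed header lines::

    # divflow-volume v1
    # shape: ny nx nz
    # spacing: dx dy dz
    # z: z0,z1,...
    # targets: k0,k1,...        (optional, 0-based reconstructed indices)
    i,j,k,x,y,z,vx,vy,vz
    ...

Rows are in slice-major order (k, then i, then j); x = j·dx, y = i·dy.
Round-trips are lossless to printed precision (17 significant digits).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ValidationError, VelocitySlice, VelocityVolume

__all__ = ["read_volume", "write_volume", "VolumeParseError"]

_COLUMNS = ["i", "j", "k", "x", "y", "z", "vx", "vy", "vz"]


class VolumeParseError(ValidationError):
    """Raised when a volume file is malformed."""


def write_volume(volume: VelocityVolume, path, targets: list[int] | None = None) -> None:
    """Write a volume (and optionally its reconstructed-slice indices)."""
    ny, nx = volume.shape
    ii, jj = np.mgrid[0:ny, 0:nx]
    frames = []
    for k, s in enumerate(volume.slices):
        frames.append(
            pd.DataFrame(
                {
                    "i": ii.ravel(),
                    "j": jj.ravel(),
                    "k": k,
                    "x": (jj * volume.dx).ravel(),
                    "y": (ii * volume.dy).ravel(),
                    "z": s.z,
                    "vx": s.vx.ravel(),
                    "vy": s.vy.ravel(),
                    "vz": s.vz.ravel(),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    zs = ",".join(repr(float(z)) for z in volume.zs)
    with open(path, "w") as fh:
        fh.write("# divflow-volume v1\n")
        fh.write(f"# shape: {ny} {nx} {volume.nz}\n")
        fh.write(f"# spacing: {volume.dx!r} {volume.dy!r} {volume.dz!r}\n")
        fh.write(f"# z: {zs}\n")
        if targets is not None:
            fh.write("# targets: " + ",".join(str(int(t)) for t in targets) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_volume(path, with_targets: bool = False):
    """Read a volume file; returns the volume (and targets if requested)."""
    header: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
            elif n_header == 1 and "divflow-volume" not in body:
                raise VolumeParseError(f"line 1: unrecognized format marker {body!r}")

    if "shape" not in header or "spacing" not in header or "z" not in header:
        raise VolumeParseError("missing required header line (shape / spacing / z)")
    try:
        ny, nx, nz = (int(v) for v in header["shape"].split())
        dx, dy, dz = (float(v) for v in header["spacing"].split())
        zs = np.array([float(v) for v in header["z"].split(",")])
    except ValueError as exc:
        raise VolumeParseError(f"malformed header: {exc}") from exc
    if len(zs) != nz:
        raise VolumeParseError(f"header lists {len(zs)} z values for nz={nz}")

    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:
        raise VolumeParseError(f"malformed data rows: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise VolumeParseError(f"missing column(s): {', '.join(missing)}")
    if len(df) != ny * nx * nz:
        raise VolumeParseError(f"expected {ny * nx * nz} rows, found {len(df)}")
    vals = df[["vx", "vy", "vz"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = int(np.argwhere(~np.isfinite(vals))[0, 0]) + n_header + 2
        raise VolumeParseError(f"non-finite value near line {bad}")

    df = df.sort_values(["k", "i", "j"], kind="stable")
    slices = []
    for k in range(nz):
        sub = df[df["k"] == k]
        if len(sub) != ny * nx:
            raise VolumeParseError(f"slice {k} has {len(sub)} rows, expected {ny * nx}")
        slices.append(
            VelocitySlice(
                sub["vx"].to_numpy().reshape(ny, nx),
                sub["vy"].to_numpy().reshape(ny, nx),
                sub["vz"].to_numpy().reshape(ny, nx),
                z=float(zs[k]),
            )
        )
    vol = VelocityVolume(slices, dx=dx, dy=dy, dz=dz)
    if not with_targets:
        return vol
    targets = None
    if "targets" in header and header["targets"]:
        targets = [int(t) for t in header["targets"].split(",")]
    return vol, targets
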