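"""Synthetic velocity data: the analytical benchmark field, its noise model,
and auxiliary phantoms for property testing.

The analytical benchmark is the divergence-free polynomial field

    Vx = 0.3 y² + 0.15 x²
    Vy = 0.3 (1 − x²) y − 1 − 0.3 x y
    Vz = −0.3 (1 − x²) z

whose divergence 0.3x + [0.3(1−x²) − 0.3x] − 0.3(1−x²) vanishes identically.
Published typesettings of Vy drop the grouping parentheses; the parse above
is the unique natural reading under which the field is divergence-free, and
the main alternative parse is exposed for inspection via ``variant``.

Default stack geometry mimics a stereo-PIV acquisition: 7 slices of
128×128 pixels with the out-of-plane spacing roughly 20× the in-plane
spacing, so mid-slice interpolation is genuinely anisotropic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp

from .core import ValidationError, VelocitySlice, VelocityVolume

__all__ = [
    "GridSpec",
    "analytical_expressions",
    "analytical_field",
    "add_gaussian_noise",
    "solenoidal_random_expressions",
    "solenoidal_random_field",
    "translation_phantom",
    "symbolic_divergence",
]

X, Y, Z = sp.symbols("x y z", real=True)

_VARIANTS = {
    # divergence-free parse (default)
    "divergence_free": (
        sp.Rational(3, 10) * Y**2 + sp.Rational(3, 20) * X**2,
        sp.Rational(3, 10) * (1 - X**2) * Y - 1 - sp.Rational(3, 10) * X * Y,
        -sp.Rational(3, 10) * (1 - X**2) * Z,
    ),
    # flat literal reading of the ungrouped typesetting "0.31 − x²y − 1 − 0.3yx"
    "literal_flat": (
        sp.Rational(3, 10) * Y**2 + sp.Rational(3, 20) * X**2,
        sp.Rational(31, 100) - X**2 * Y - 1 - sp.Rational(3, 10) * Y * X,
        -sp.Rational(3, 10) * (1 - X**2) * Z,
    ),
}


@dataclass
class GridSpec:
    """Regular sampling grid: counts and physical ranges per axis."""

    nx: int = 128
    ny: int = 128
    nz: int = 7
    x_range: tuple[float, float] = (-1.0, 1.0)
    y_range: tuple[float, float] = (-1.0, 1.0)
    z_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3 or self.nz < 3:
            raise ValidationError("nx, ny, nz must all be >= 3")
        for name in ("x_range", "y_range", "z_range"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
                raise ValidationError(f"{name} must be a non-degenerate interval")

    @property
    def xs(self) -> np.ndarray:
        return np.linspace(*self.x_range, self.nx)

    @property
    def ys(self) -> np.ndarray:
        return np.linspace(*self.y_range, self.ny)

    @property
    def zs(self) -> np.ndarray:
        return np.linspace(*self.z_range, self.nz)

    @property
    def dx(self) -> float:
        return (self.x_range[1] - self.x_range[0]) / (self.nx - 1)

    @property
    def dy(self) -> float:
        return (self.y_range[1] - self.y_range[0]) / (self.ny - 1)

    @property
    def dz(self) -> float:
        return (self.z_range[1] - self.z_range[0]) / (self.nz - 1)


def analytical_expressions(variant: str = "divergence_free"):
    """Sympy expressions (Vx, Vy, Vz) of the analytical benchmark field."""
    if variant not in _VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}; choose from {tuple(_VARIANTS)}")
    return _VARIANTS[variant]


def symbolic_divergence(vx: sp.Expr, vy: sp.Expr, vz: sp.Expr) -> sp.Expr:
    """∂Vx/∂x + ∂Vy/∂y + ∂Vz/∂z, simplified."""
    return sp.simplify(sp.diff(vx, X) + sp.diff(vy, Y) + sp.diff(vz, Z))


def _sample_expressions(exprs, grid: GridSpec) -> VelocityVolume:
    fns = [sp.lambdify((X, Y, Z), e, "numpy") for e in exprs]
    xg, yg = np.meshgrid(grid.xs, grid.ys)  # rows = y, cols = x
    slices = []
    for z in grid.zs:
        comps = [np.broadcast_to(np.asarray(f(xg, yg, z), dtype=float), xg.shape).copy() for f in fns]
        slices.append(VelocitySlice(*comps, z=float(z)))
    return VelocityVolume(slices, dx=grid.dx, dy=grid.dy, dz=grid.dz)


def analytical_field(grid: GridSpec | None = None, variant: str = "divergence_free") -> VelocityVolume:
    """Sample the analytical benchmark field on a regular grid."""
    g = grid if grid is not None else GridSpec()
    return _sample_expressions(analytical_expressions(variant), g)


def add_gaussian_noise(
    volume: VelocityVolume,
    fraction: float = 0.1,
    seed: int | None = None,
    scope: str = "component",
) -> VelocityVolume:
    """Perturb each component grid with zero-mean Gaussian noise.

    The standard deviation is ``fraction`` times the maximum absolute
    velocity of each component field across the volume (``scope="component"``,
    the default) or of the full vector magnitude (``scope="global"``).
    Reproducible for a fixed seed.
    """
    if fraction < 0:
        raise ValidationError("fraction must be >= 0")
    if scope not in ("component", "global"):
        raise ValidationError("scope must be 'component' or 'global'")
    out = volume.copy()
    if fraction == 0:
        return out
    rng = np.random.default_rng(seed)
    if scope == "global":
        gmax = max(np.max(s.magnitude()) for s in volume.slices)
        stds = {"vx": fraction * gmax, "vy": fraction * gmax, "vz": fraction * gmax}
    else:
        stds = {
            name: fraction * max(np.max(np.abs(getattr(s, name))) for s in volume.slices)
            for name in ("vx", "vy", "vz")
        }
    for s in out.slices:
        for name in ("vx", "vy", "vz"):
            g = getattr(s, name)
            g += rng.normal(0.0, stds[name], size=g.shape) if stds[name] > 0 else 0.0
    return out


def solenoidal_random_expressions(seed: int = 0, smoothness: float = 1.0, n_modes: int = 2):
    """Random smooth vector potential A and its curl V (symbolic).

    A has trigonometric components with seeded coefficients; V = ∇×A is
    divergence-free identically.  Larger ``smoothness`` lowers the spatial
    frequencies.  Returns ``(A, V)`` as two triples of sympy expressions.
    """
    if smoothness <= 0:
        raise ValidationError("smoothness must be > 0")
    rng = np.random.default_rng(seed)
    base = sp.pi / (2 * sp.nsimplify(smoothness))

    def component():
        expr = sp.Integer(0)
        for _ in range(n_modes):
            c = sp.Float(rng.normal(0, 1))
            kx, ky, kz = (int(k) for k in rng.integers(1, 3, size=3))
            px, py, pz = (sp.Float(p) for p in rng.uniform(0, 2 * np.pi, size=3))
            expr += c * sp.sin(kx * base * X + px) * sp.sin(ky * base * Y + py) * sp.sin(kz * base * Z + pz)
        return expr

    Ax, Ay, Az = component(), component(), component()
    V = (
        sp.diff(Az, Y) - sp.diff(Ay, Z),
        sp.diff(Ax, Z) - sp.diff(Az, X),
        sp.diff(Ay, X) - sp.diff(Ax, Y),
    )
    return (Ax, Ay, Az), V


def solenoidal_random_field(
    grid: GridSpec | None = None, smoothness: float = 1.0, seed: int = 0, n_modes: int = 2
) -> VelocityVolume:
    """Sample a random solenoidal field (curl of a smooth vector potential)."""
    g = grid if grid is not None else GridSpec()
    _, V = solenoidal_random_expressions(seed=seed, smoothness=smoothness, n_modes=n_modes)
    return _sample_expressions(V, g)


def translation_phantom(
    shape: tuple[int, int] = (64, 64),
    shift: tuple[float, float] = (1.0, 0.0),
    blob_width: float = 4.0,
    seed: int = 0,
    amplitude: float = 10.0,
):
    """Gaussian blob image and its analytically shifted copy.

    ``shift = (sx, sy)`` in pixels is applied by evaluating the blob at
    displaced coordinates, not by resampling, so sub-pixel shifts are exact.
    The default contrast of 10 makes the peak brightness gradients O(1),
    comparable to the default smoothness weight λ=1, so shift recovery
    probes the flow estimate rather than the regularizer.  Returns
    ``((I0, I1), shift)``.
    """
    ny, nx = shape
    sx, sy = float(shift[0]), float(shift[1])
    if abs(sx) > nx / 4 or abs(sy) > ny / 4:
        raise ValidationError("shift must not exceed a quarter of the image size")
    if blob_width <= 0:
        raise ValidationError("blob_width must be > 0")
    rng = np.random.default_rng(seed)
    cx = (nx - 1) / 2 + rng.uniform(-2, 2)
    cy = (ny - 1) / 2 + rng.uniform(-2, 2)
    rows, cols = np.mgrid[0:ny, 0:nx].astype(float)

    def blob(x0, y0):
        return amplitude * np.exp(-((cols - x0) ** 2 + (rows - y0) ** 2) / (2 * blob_width**2))

    return (blob(cx, cy), blob(cx + sx, cy + sy)), (sx, sy)
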