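# Methods

## Model

A velocity volume is an ordered stack of planes, each carrying three
co-registered component grids (Vx, Vy, Vz). The brightness signal driving the
flow estimate is the velocity-magnitude image I = |V|; the vector components
enter only the divergence terms and the final reconstruction.

The symmetric setup postulates a mid-slice point (x, y) whose images in the
two acquired outer slices are displaced oppositely:

    I(x+α, y+β, z+Δ) = I(x−α, y−β, z−Δ).

First-order expansion gives the brightness constraint Hx α + Hy β + Hz = 0
with

    Hx = ∂I(z+Δ)/∂x + ∂I(z−Δ)/∂x,   Hy likewise in y,   Hz = I(z+Δ) − I(z−Δ).

Incompressibility is imposed not on the flow (α, β) but on the *interpolated
velocity field*: summing the divergence expressions of the two outer slices
evaluated at the displaced points, expanding to first order in (α, β), and
replacing the out-of-plane derivative ∂Vz/∂z by its unique two-slice central
estimate yields a second linear constraint Dx α + Dy β + Dz = 0 with

    Dx = [∂²Vx/∂x²] + [∂²Vy/∂x∂y]           (upper minus lower slice)
    Dy = [∂²Vx/∂y∂x] + [∂²Vy/∂y²]           (upper minus lower slice)
    Dz = ∂Vx/∂x|₊ + ∂Vx/∂x|₋ + ∂Vy/∂y|₊ + ∂Vy/∂y|₋ + (Vz₊ − Vz₋)/Δ,

Δ in slice-index units. The energy

    ε = ∬ (Hxα + Hyβ + Hz)² + γ²(Dxα + Dyβ + Dz)² + λ²(|∇α|² + |∇β|²)

is minimized by a Jacobi sweep: each iteration replaces (α, β) by their
weighted 3×3 neighborhood averages (1/6 edge, 1/12 diagonal) and applies the
closed-form per-pixel correction whose coefficient grids are fixed functions
of (H, D, γ, λ), computed once before iterating. Each correction is exactly
the minimizer of the local quadratic

    (Hxα + Hyβ + Hz)² + γ²(Dxα + Dyβ + Dz)² + λ²[(α−ᾱ)² + (β−β̄)²],

which we verify against an independent 2×2 normal-equations solve; the
update denominator γ²D1 + λ²D2 is bounded below by λ⁴, so λ > 0 guarantees
well-posedness. At γ = 0 the sweep coincides, iteration by iteration, with
the classical Horn–Schunck sweep on the magnitude images.

The published coefficient table loses grouping parentheses in one entry; we
use the form that follows from the normal-equations derivation,
B1 = λ²(HxHy + γ²DxDy), under which the printed identities A2 = B1, D3 = D1,
D4 = D2 and the oracle equivalence hold exactly.

The mid-slice is reconstructed per component as the symmetric
motion-compensated average ½[C(x+α, y+β, z+Δ) + C(x−α, y−β, z−Δ)] with
bilinear sampling and replicated borders; zero flow reduces it exactly to the
linear (elementwise-average) baseline. Components are warped directly; a
magnitude-image warp would require re-scaling components and is not offered.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| γ | divergence-term weight (squared in ε) | 150 | 0 disables the constraint (plain Horn–Schunck) |
| λ | smoothness weight (squared in ε) | 1 | must be > 0; guarantees denominator ≥ λ⁴ |
| iterations | Jacobi sweeps | 2000 | metrics stabilize after ≈200 sweeps; tests and the bundled experiments use 200 |
| Δ | slice half-offset, slice-index units | 1 | 1 = nearest neighbours (2-slice gap), 2 = 4-slice gap |
| boundary | stencil border handling | replicate | `reflect` available |
| region | evaluation-window side | 110 | centered in the slice |
| tol | optional early-stop on max flow update | off | fixed iteration count is the reference protocol |

Solvers work in pixel/slice-index units throughout; the physical spacings
(dx, dy, dz) stored on a volume are applied only inside the divergence
metric. All stencils are second-order central differences (a forward-
difference switch exists for the constraint terms); the flow-gradient terms
of the two-frame Horn–Schunck comparator use the classical cube-averaged
kernels, while the symmetric-mode comparator used in interpolation shares
the H-terms of the constrained solver so that method differences isolate the
divergence term.

## Evaluation

MSE is the mean squared difference of velocity magnitude over the centered
region (per-component MSEs are reported alongside). The mid-plane divergence
is d(vx)/dx·(1/dx) + d(vy)/dy·(1/dy) + (Vz₊ − Vz₋)/(z₊ − z₋), with the
z-term taken from the *reference* outer slices so the metric probes only the
reconstruction under test. Because the reference literature plots
"divergence" without fixing a reduction, both the mean absolute value and
the sum of squares over the window are reported. The sweep harness runs one
reconstruction + evaluation per (γ, λ) pair on identical inputs; by default
the reference for MSE is the acquired stack itself (the only option for real
data), and a separate clean-truth volume can be supplied for synthetic runs.

The truncated-sinc baseline reconstructs a target slice from the decimated
stack k±Δ, k±3Δ, …, in which the target lies half-way between samples, with
weights sinc((z − z_k)/(2Δ·dz)) renormalized to unit sum. Slices at even
multiples of Δ sit at integer sinc offsets and would receive zero weight,
which is why they are excluded.

## Synthetic data

The generator provides everything the experiments need:

- **Analytical benchmark field**: Vx = 0.3y² + 0.15x²,
  Vy = 0.3(1−x²)y − 1 − 0.3xy, Vz = −0.3(1−x²)z, sampled by default as
  7 slices of 128×128 over [−1,1]³ so the out-of-plane spacing is ≈21× the
  in-plane spacing. The ungrouped typesetting of Vy found in print is
  ambiguous; the parse above is the unique natural reading with identically
  zero divergence (verified symbolically), and the flat literal parse is
  exposed as a variant for inspection. Note the field is polynomial of
  degree ≤ 2 in each variable, so the second-order stencils differentiate it
  *exactly*: its discrete divergence is machine-zero at any resolution, and
  order-of-accuracy studies need the trigonometric fields below.
- **Noise model**: i.i.d. zero-mean Gaussian noise per component with std =
  10% (configurable) of that component's maximum absolute value over the
  volume (a global-magnitude scope is available). Noise is added to the
  sampled slices.
- **Random solenoidal fields**: V = ∇×A for a seeded low-frequency
  trigonometric vector potential A, built symbolically so div V = 0 can be
  checked symbolically and sampled numerically; discrete divergence decays
  as O(h²).
- **Translation phantom**: a Gaussian blob and an analytically shifted copy
  (no resampling), used to validate shift recovery. Its default contrast is
  10 so that peak brightness gradients are O(1), comparable to λ = 1 — at
  unit contrast the smoothness term dominates and the recovered shift probes
  the regularizer rather than the data term.

What the synthetic stack does *not* emulate: spatially correlated PIV noise,
cross-correlation window artefacts, solid boundaries/masked regions, and
turbulent fine structure. Conclusions drawn from the bundled experiments are
therefore about the solver's behaviour under calibrated white noise on a
smooth incompressible field, not about any particular instrument. In
particular, on this stand-in the divergence term also *lowers* magnitude MSE
(it acts as a variance-reducing regularizer), whereas on real acquired data
a monotone MSE-vs-γ trade-off has been reported; the trade-off profile is
data-dependent.

## Numerical choices and edge cases

- Flow is initialized to zero, making identical outer slices an exact
  zero-flow fixed point and runs bitwise-reproducible.
- The iteration count is fixed (no convergence test) in the reference
  protocol; `tol` offers an optional max-update early stop.
- The energy monitored in tests uses the averaging-kernel quadratic form
  Σ α·(α − Wα) for the smoothness term — the discretization consistent with
  the sweep, under which each sweep is provably a descent step (the kernel's
  eigenvalues lie in [−1/3, 1]); a forward-difference energy is *not*
  monotone under Jacobi sweeps and differs by ~1e−5 relative oscillations.
- Grids are row = y, column = x, 0-based, pixel-centered. Frame padding
  (e.g. 154×121 → 128×128) centrally crops oversized dimensions and
  centrally zero-pads undersized ones, recording the offsets.
- Out-of-range warp coordinates replicate the border; inputs must be dense
  and finite (no NaN handling).

## Known limitations

- Single-resolution solver: large displacements (≫ a few pixels) are outside
  the linearization's validity; no pyramid/warping scheme is provided.
- The divergence constraint is first-order in (α, β) and inherits the
  two-slice ∂Vz/∂z estimate's O(Δ²) error.
- Quadratic penalties throughout; no robust data terms, vorticity
  regularizers, or multigrid acceleration.
- The CSV volume format is verbose by design (diffable, dependency-free);
  very large volumes are better kept in binary containers outside this tool.
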