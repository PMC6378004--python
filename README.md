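# divflow

Divergence-constrained optical-flow interpolation of velocimetry slice stacks.

## The problem

3D velocity measurements — stereo-PIV stacks, flow MRI, CFD exports sampled on
planes — are usually acquired with in-plane pixel spacing far finer than the
spacing between planes. Reconstructing the missing intermediate slices by
plain averaging or generic registration ignores a strong physical prior: for
an incompressible fluid the velocity field is solenoidal,

    ∇·V = ∂Vx/∂x + ∂Vy/∂y + ∂Vz/∂z = 0.

`divflow` reconstructs a mid-slice between two acquired slices with a
symmetric optical-flow formulation whose energy functional penalizes, in
addition to the usual brightness-constancy and smoothness terms, the
divergence of the interpolated field:

    ε = ∬ (Hx α + Hy β + Hz)² + γ² (Dx α + Dy β + Dz)² + λ² (|∇α|² + |∇β|²) dx dy

Here (α, β) is the in-plane flow that maps a mid-slice point forward into the
upper slice (z+Δ) and backward into the lower slice (z−Δ); the H-terms come
from the velocity-magnitude images of the two outer slices, and the D-terms
express the mid-plane divergence using only those two slices. The functional
is minimized by a Jacobi iteration whose per-pixel coefficients are computed
once; setting γ = 0 recovers the classical Horn–Schunck iteration exactly.
The mid-slice is then the motion-compensated average
½[V(x+α, y+β, z+Δ) + V(x−α, y−β, z−Δ)].

The package provides the solver, a plain Horn–Schunck comparator on the same
reconstruction path, linear and truncated-sinc baselines, MSE/divergence
evaluation, (γ, λ) sweeps, a synthetic-data module (a divergence-free
analytical benchmark field, a calibrated noise model, random solenoidal
fields, translation phantoms), a columnar CSV volume format, and a CLI. It is
aimed at experimentalists post-processing planar velocimetry data and at
anyone studying physics-constrained variational interpolation.

## Worked example

Generate the noisy analytical benchmark stack (7 slices of 128×128, Gaussian
noise with std 10% of each component's maximum), reconstruct slices 3–5 from
their neighbours with and without the divergence term, and evaluate over the
centered 110×110 window:

```sh
divflow simulate --field analytic --nx 128 --ny 128 --nz 7 \
    --noise 0.1 --seed 1 --out noisy.csv --clean-out clean.csv
divflow interpolate --in noisy.csv --out recon_divof.csv --method divof \
    --gamma 150 --lam 1 --iterations 200 --targets 3,4,5
divflow interpolate --in noisy.csv --out recon_hs.csv --method hs \
    --lam 1 --iterations 200 --targets 3,4,5
divflow evaluate --truth clean.csv --recon recon_divof.csv --region 110
divflow evaluate --truth clean.csv --recon recon_hs.csv --region 110
```

which prints, per reconstructed slice (1-based), the magnitude MSE against
the clean truth, the mean absolute divergence and the sum of squared
divergence over the window:

```
# divof (gamma = 150)
 slice           mse  div_mean_abs        div_ss
     3    0.00411049       2.35316        107726
     4    0.00414598       2.36264        106985
     5    0.00414776       2.37723        108891

# hs (gamma = 0)
 slice           mse  div_mean_abs        div_ss
     3    0.00725518       3.24314        203316
     4    0.00738695       3.27105        203729
     5    0.00729838       3.29117        206237
```

With the divergence term active the reconstructed slices are markedly closer
to solenoidal (mean |∇·V| about 28% lower on every slice), and on this noisy
stack the magnitude error drops as well — the constraint acts as a
physically-motivated regularizer. The same experiment is available from
Python via `divflow.synthetic`, `divflow.interpolate_volume` and
`divflow.evaluate`; `divflow sweep` tabulates the behaviour over a (γ, λ)
grid.

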