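# Methods

This note documents the model, the numerical choices and the validation
design of `loresd`, including the decisions made where the design was
genuinely open, and what the synthetic experiments do and do not show.

## Signal model and estimator

Each voxel's multi-shell signal is represented per shell by its real,
even-order spherical-harmonics (SH) coefficients `S_ℓ` (orthonormal basis,
MRtrix-style ordering: blocks of increasing even ℓ, `m = −ℓ…ℓ`).  A shell
contributes only the orders its direction count supports; the b=0 shell
contributes only `ℓ = 0`.  The signal is modelled as a single spherical
convolution of an axially symmetric response `H` with an ODF `p`, which in
SH is `S_ℓ = N_ℓ h_ℓ p_ℓᵀ` with `N_ℓ = √(4π/(2ℓ+1))`.  This normalisation is
pinned by the property that convolving a delta ODF with `H` reproduces `H`'s
own profile (tested).

The response is a convex mixture of axially symmetric Gaussian kernels
`G(b, α | λ∥, λ⊥) = e^{−bλ⊥} e^{−b(λ∥−λ⊥)cos²α}` on a triangular grid of
diffusivities (`λ⊥ ≤ λ∥`; 10 per axis on [0, 4] μm²/ms → 55 nodes; b stored
in ms/μm² so exponents are dimensionless).  Kernel zonal coefficients are
exact Gauss–Legendre projections onto Legendre polynomials (64 nodes;
projection error ≪ the ℓmax=8 truncation error).  The per-voxel problem is

```
min_{f,q}  Σ_ℓ ‖S_ℓ − N_ℓ h_ℓ(f) p_ℓᵀ‖²_F + λ Σ_{ℓ>0} ‖N_ℓ h_ℓ(f)‖²₂
```

subject to `0 ≤ f ≤ 1`, `Σf = 1`, `p₀ = 1/√(4π)` and `Qp ≥ 0` on a fixed
300-direction set, solved by SLSQP with the analytic gradient.

**Regulariser scale.** The anisotropy penalty is applied to the convolution
coefficients `N_ℓ h_ℓ` — the numbers through which the response actually
enters the forward model — rather than to the bare basis coefficients
`h_ℓ`.  The two readings differ only by fixed per-order weights
`4π/(2ℓ+1)`, but the choice matters at the default `λ = 10⁻³`: with the
penalty on `N_ℓ h_ℓ`, the estimator resolves noisy 60° crossings reliably
(mean ACC ≈ 0.91–0.92 at SNR 20) and matches the behaviour expected of the
method, whereas the bare-coefficient reading lets the response absorb
crossing-fibre anisotropy in a fraction of noise realisations (the known
response/ODF ambiguity), dragging the mean ACC just below 0.90.  Noiseless
recovery is unaffected (see below).

**Variables and constraints.** The 55 fractions and the 44 coefficients of
orders 2–8 are the free variables; `p₀` is substituted, not constrained.
The nonnegativity set `Q` is a fixed, shipped 300-direction electrostatic
design (`src/loresd/data/directions300.txt`), so constraint matrices are
bit-stable.  After the solve, fractions are clipped to [0, 1] and
renormalised, and the ODF is shrunk toward isotropy only if its worst
amplitude violates −1e-7 (a no-op in practice), so every returned fit
satisfies `Σf = 1 ± 1e-6` and amplitudes ≥ −1e-6.

**Initialisation.** Uniform fractions (1/55) plus one CSD iteration: with
the mixture fixed, the data term is diagonal in the ODF coefficients, so the
unconstrained optimum is closed-form; a small convex QP restores
nonnegativity.  Degenerate (all-zero) signals return the isotropic ODF.
Deterministic throughout — fits are reproducible bit-for-bit and independent
of thread count (each voxel is self-contained).

**Stopping.** SciPy's SLSQP `ftol` is absolute; the configured relative
tolerance (default 1e-4) is scaled by the initial objective of the
S0-normalised problem, `ftol = rel_ftol · max(F(x₀), 1e-6)`.  Because the
signal is divided by S0 before fitting, tolerances and λ are independent of
scanner units, and the fit is exactly scale-equivariant: scaling the input
by c leaves the ODF unchanged and scales the response by c (tested at
c = 10).  Default iteration cap 200; non-convergence is reported in the
returned fit, never raised.

**Diagnostics.** RMSE is computed in raw signal space at the acquisition
directions.  AIC uses the Gaussian form with profiled-out variance,
`n ln(rss/n) + 2k`, with n = raw volume count; parameter counts are
45 + 55 − 2 = 98 for the joint estimator (two equality constraints) and
45 + n_iso for the fixed-response baseline.  The same formula is applied to
both models so ΔAIC is consistent.

## Baseline

The multi-tissue CSD comparator takes response functions as input (the
simulation ground truth, or files in the standard multi-shell response text
format) and solves the convex problem: WM convolution plus nonnegative
isotropic tissue contributions, WM ODF amplitudes ≥ 0 on the same fixed
300-direction set.  The unconstrained least-squares solution is returned
directly when it is already feasible (it is then the exact optimum);
otherwise SLSQP polishes it to `ftol = 1e-12`.  Hard inequality constraints
are used rather than the soft-penalty iterations of historical CSD
implementations, for uniformity with the joint estimator.  Heuristic
response estimation from data is deliberately out of scope.

## Synthetic phantoms

The voxel-level validation emulates the study conditions:

- **Kernels** (compartment fractions / diffusivities in μm²/ms): default
  0.45 stick (λ∥ 2.2) + 0.45 zeppelin (2.0, 0.7) + 0.10 ball (3.0);
  alternative 0.30/0.40/0.30 with zeppelin radial diffusivity 1.4.  S0 = 1.
  These diffusivities deliberately do *not* lie on the 10-point grid, so the
  estimator must interpolate across nodes; accuracy is therefore scored by
  ACC rather than by node-weight recovery.
- **ODFs**: apodised deltas; crossings are equal-weight symmetric pairs
  sharing one kernel (single-convolution model).
- **Acquisition**: b = 0/1000/2000 s/mm² with 5/128/128 directions
  (deterministic electrostatic direction sets), the study's
  healthy-volunteer protocol; configurable.
- **Noise**: Rician, `√((S+n₁)² + n₂²)` with `σ = S0/SNR`, seeded through a
  single `SeedSequence` root so the full results table is reproducible.
- **Scoring**: ACC (cosine similarity of ℓ ≥ 2 SH coefficients, undefined —
  not zero — for isotropic arguments) and raw-signal RMSE.

**Apodised delta.** A per-order taper must remove the negative ringing of
the truncated delta expansion.  A raised-cosine-in-ℓ taper proved
insufficient (minimum amplitude −0.037, i.e. an infeasible ground truth for
the constrained fitters); the shipped construction is the square of the
half-band (ℓ ≤ 4) truncated delta — a Fejér-type kernel — normalised to unit
integral: exactly band-limited at ℓmax = 8, nonnegative everywhere by
construction, `w₀ = 1`, and as peaked as that allows.  For `ℓmax < 4` the
monomial profile `(n·μ)^{ℓmax}` is used instead.

**What the phantoms do not show.** Single-voxel simulations have no spatial
context (no partial voluming, no misalignment, no spatially varying noise or
bias fields), use exactly the forward model the estimators assume (a single
convolution, Gaussian compartments, no exchange), and reference SNR to a
known S0.  Passing them demonstrates correct estimation under the model, not
robustness to in vivo acquisition artefacts; in vivo claims (cross-method
agreement, glioma RMSE changes, tractography quality) need real scans and
are out of scope here.

## Problem sizes and tolerances in the shipped validation

The packaged experiments use 100 noise realisations per configuration at
SNR 20 for the headline accuracy numbers and 50 per condition for the
SNR-trend checks (the full study-scale experiment at 500 repetitions is a
flag away: `n_reps`).  Noise-free recovery checks run the solver to
convergence (`rel_ftol ≤ 1e-7`) because they probe the optimum, not the
default early-stopping behaviour; noisy-data experiments use the default
`rel_ftol = 1e-4`, where early stopping also acts as mild extra
regularisation.  Grid-snapped ("on-model") phantoms are used where exact
recovery is asserted (ACC ≥ 0.99, RMSE ≤ 1e-3·S0); the off-grid default
kernel adds a grid-interpolation floor of ≈ 2–3 × 10⁻³ to the RMSE.

## Known limitations

- The band-limited reconstruction of the sharpest grid kernels
  (b·(λ∥−λ⊥) = 8) rings to ≈ −0.018; this is inherent to ℓmax = 8, not a
  defect of the projection.
- The free-water contrast's hard 2.6 μm²/ms threshold straddles the grid
  node at 2.22, so pure free-water voxels place ≈ 0.77 (not 1.0) of their
  mass above the threshold at the optimum; all mass is fast and isotropic
  (λ⊥ ≥ 2.2).
- Multi-exponential ambiguity: isotropic multi-shell signals admit many
  near-exact mixture representations; node weights are therefore not
  individually identifiable (contrasts, which integrate over nodes, are the
  intended read-out).
- One diffusion time / echo time only; no spatial regularisation across
  voxels; odd-order SH (asymmetric ODFs) unsupported.
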