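# Methods

## Signal model

A voxel is modelled as two non-exchanging water pools: tissue (fraction
`1 − f`, diffusivity `D`) and a flow-related fluid pool (fraction `f`,
pseudo-diffusivity `D*`, with `D* ≥ D` enforced structurally).  In a
spin-echo acquisition with repetition time TR and echo time TE each pool is
weighted by its own saturation-recovery and transverse-decay factors, giving
the relaxation-weighted signal

    S(b, TE, TR) = s0 · [ (1−f)·w_t·e^(−bD) + f·w_f·e^(−bD*) ],
    w_x = (1 − e^(−TR/T1_x)) · e^(−TE/T2_x).

At fixed (TE, TR) this is still an exact biexponential in b, but with the
apparent fraction `f_app = f·w_f / ((1−f)·w_t + f·w_f)`.  That identity is
the package's analytic oracle: a conventional fit to noiseless
relaxation-weighted data must recover `f_app` exactly, which the test suite
verifies to < 1e-4 relative error across a grid of TE, ΔT2 ∈ [0, 60] ms,
ΔT1 ∈ {0, 300, 600} ms and TR ∈ {2000, 4000} ms.  Units throughout:
b in s/mm², D and D* in mm²/s, all times in ms.

## Normalization conventions

Three conventions coexist and are tagged on every dataset:

* **per_reference** (default): signals divided by the b = 0 signal at a
  single anchor (the grid's shortest TE, the simulation TR).  Absolute TE
  decay across echoes is preserved, so both compartmental T2s are
  identifiable for the joint fit, and `sigma` is exactly 1/SNR at the
  anchor.
* **per_te**: each (TE, TR) slab divided by its own b = 0 signal.  Every
  slab starts at 1; the absolute T2 decay is gone and only the transverse
  rate difference `ΔR2 = 1/T2_tissue − 1/T2_fluid` remains identifiable.
  This is the ratio form of the relaxation-weighted model itself, and the
  convention under which conventional-vs-joint variance comparisons are
  run (see below).
* **absolute**: un-normalized, for image stacks where S0 is fitted freely.

## Estimators

All fits are one-step bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, method `trf`) with analytic Jacobians.
Segmented estimates only *seed* the one-step fit: `D` from a log-linear fit
of the b ≥ 200 tail, `f` from the b = 0 intercept gap, `D* = 10·D`, T2 from
the log-linear TE decay of the b = 0 series.  Global bounds: `f ∈ [0, 1]`,
`D ∈ [1e-5, 5e-3]`, `D* ∈ [D_init, 0.5]` mm²/s, `T2 ∈ [5, 500]` ms.
Non-convergence flags the result instead of raising; label degeneracy at
the optimum (`D* < D`) is repaired by swapping compartments and mapping
`f → 1 − f`.

The joint (b, TE) fit flattens the plane b-fastest (all b ascending within
each TE, TEs ascending) and estimates `(f, D, D*, T2_tissue, T2_fluid)`.
Its scale handling follows the data: with absolute data S0 is a free sixth
parameter (the in vivo convention); with per-reference data the model is
*self-normalized* — divided by its own b = 0 value at the reference TE — so
no scale parameter exists and S0 noise cannot propagate into f (the
simulation convention).  Per-TE data are refused by this fitter because the
individual T2s are not identifiable; the reduced estimator
`fit_t2ivim_2d_delta_r2` fits `(f, D, D*, ΔR2)` on the ratio model instead.

### Why the variance comparison runs on per-TE data

Under the anchored convention the conventional single-TE estimator at short
TE is *better* conditioned than the five-parameter joint estimator: the
CRLB of f at TE = 52 ms (16 b-values, σ = 0.025) is 0.030 versus 0.036 for
the joint model, so no efficient joint fit can beat the per-TE fit there.
The headline precision advantage of joint fitting holds for ratio-form
(per-TE-normalized) data, where each slab carries full amplitude and the
reduced four-parameter estimator pools all 96 points: there the joint fit's
f SD is ~39% below every per-TE fit's (one-sided F-test p < 1e-26 at 500
repetitions, SNR 40, ΔT1 = 300 ms, ΔT2 = 15 ms).  The package therefore
runs that comparison through the per-TE pathway and documents both
conventions rather than pretending one number covers both.

## Monte-Carlo simulation

Rician noise replaces each value v by `sqrt((v + n1)² + n2²)` with
`n1, n2 ~ N(0, σ²)`; at v = 0 the magnitude mean is `σ·sqrt(π/2)` (verified
to 3 standard errors).  Tissue presets: liver (f = 0.095, D = 1.0e-3,
D* = 0.067, T1/T2 tissue 800/27 ms) and kidney (f = 0.15, D = 1.6e-3,
D* = 0.012, T1/T2 tissue 1200/67 ms) at 3 T, with fluid offsets ΔT1, ΔT2 as
scenario knobs; b-sets (16-point 0–750 s/mm² and 6-point consensus/short
sets), TE ladders 47–72 and 50–100 ms in 5 ms steps, TR 2000–4000 ms.
Noise SD is specified on the normalized scale so SNR at S0 = 1/σ
(σ = 0.025 ⇔ SNR 40).  Ensembles are seeded and bit-reproducible; failed
fits are excluded, logged and reported as a failure rate, never imputed.
Per-b averaging, when a scheme declares it, averages independent Rician
draws.  Ensemble sizes in the test suite are 120–500 repetitions — large
enough that the F-tests and CI checks they feed are decisive — rather than
the 2500 used for the archival figures.

## Protocol design

Under Gaussian noise the Fisher matrix of the design is
`F = (1/σ²)·Jᵀ·W·J`, with J the analytic Jacobian over the (b, TE) design
points and W per-point averages.  The design objective is

    nRMSE = Σ_i sqrt(β_i² + σ_f,i²) / f,

summed over a fluid-T2 scenario grid (liver: 27–87 ms in 5 ms steps, 13
scenarios), with σ_f from the CRLB.  β = 0 by default: the joint model is
correctly specified under the simulation conditions, so the asymptotic bias
vanishes and the objective reduces to a summed coefficient of variation; a
bias plug-in hook (`DesignSpace.bias_fn`) exists for model-mismatch
studies.  The design-mode Fisher matrix uses the parameter set
`(f, D, D*, T2_tissue, T2_fluid)` with the scale fixed by normalization
(a parameter-independent constant anchoring the true b = 0 signal at the
space's shortest candidate TE to 1, so every subset is scored at the same
absolute noise level); S0 inclusion and a self-normalized variant (whose
denominator derivatives enter J — the right bound to compare against the
self-normalized estimator's ensemble SD) are options.  With this objective
the optimal 3-TE subset of the 47–72 ms ladder with 16 b-values is
{47, 67, 72} ms, and the consensus-b/50–100 ms space optimum has maximum
TE = 100 ms with minimum TE = 50 ms; its middle TE (95 ms under this
objective) is softer — nearby subsets differ by fractions of a percent —
and shifts with the bias policy and CRLB variant, so only the extreme TEs
are treated as robust design conclusions.

TE subsets are selected exhaustively (deterministic, ties to the
lexicographically smallest subset) up to 1e6 subsets, or by an
integer-coded genetic algorithm: chromosomes are k distinct candidate
indices, tournament selection, uniform crossover with duplicate repair,
per-gene mutation, top-5% elitism, stall-window termination, fully seeded.
The GA memoizes subset evaluations and is tested to match the exhaustive
optimum on every small space.

## IDEAL parameter mapping

Voxel-wise five/six-parameter fits are fragile at clinical SNR, so maps are
produced coarse-to-fine.  The resolution ladder for a 176×176 image is
1, 2, 4, 8, 16, 32, 64, 96, 128, 152, 176 (squared); other sizes follow the
same generalized ramp (powers of two up to ~55% of full size, then ~55%,
~73%, ~86% and full resolution, per dimension).  Each level is an
anti-aliased local-mean downsample of the stack, restricted to foreground:
masked averaging divides the masked sum by the local foreground fraction,
because background air contributes only the Rician floor — a non-decaying
offset that otherwise corrupts the coarse seeds.  Background is defined as
b = 0 reference-TE signal below 5% of the robust (99th percentile) image
maximum.  The 1×1 level uses the global data-driven defaults; every finer
level bounds each voxel's parameters to ±20% (f, D, D*, T2s) or ±50% (S0)
around the bilinearly upsampled previous-level estimates, clamped to the
global boxes.  The 3×3 Gaussian pre-filter is the separable [1, 2, 1]/4
kernel with reflect padding.

On a 20×20 two-region phantom at SNR 40 this recovers disc-median f, D and
T2_tissue within 2% of truth and cuts the voxel-wise SD of f by roughly a
third relative to unconstrained per-voxel fitting; the test suite asserts
the 10% recovery margin.  T2_fluid is the least determined map (its
uncertainty is intrinsically large when ΔT2 is small relative to the TE
range).

## Numerical choices and edge cases

* Solver tolerances 1e-10 (xtol/ftol/gtol), max 400 function evaluations.
* The one-sided F-test for σ_a < σ_b uses the variance-ratio CDF with
  (n_a − 1, n_b − 1) degrees of freedom; Δσ (%) = 100·(σ_a − σ_b)/σ_b is
  reported as the effect size.
* CRLB-vs-MC checks allow 5% slack below the bound: the bounded NLS
  estimator carries a slight shrinkage (f and T2_fluid correlate at ≈ −0.97),
  and the unbiased-estimator inequality does not bind it exactly.
* Singular Fisher matrices raise with the condition number and the
  unidentifiable direction named; a design must have more points than
  parameters.
* Grids validate b ≥ 0 ascending with b = 0 first, unique positive TEs, and
  a reference TE contained in the grid.

## What the synthetic data do and do not show

The phantoms are piecewise-constant, single-slice, perfectly registered,
with spatially uncorrelated Rician noise and exactly two relaxation
compartments.  Passing tests therefore demonstrate correctness of the
estimators, the bias mechanism and the design machinery — not robustness to
motion, partial volume, fat signal, flow anisotropy, multi-vessel fluid
pools or exchange, all of which real abdominal data contain.  Registration
and organ segmentation are accepted as upstream steps; three-compartment
models and ballistic-flow (b–M1) variants are out of scope.
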