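# t2ivim — relaxation-compensated IVIM modelling for abdominal MRI

Intravoxel incoherent motion (IVIM) imaging separates molecular diffusion
from capillary-flow "pseudo-diffusion" by sampling the diffusion-weighted
signal at multiple b-values:

    S(b)/S0 = (1 − f)·e^(−b·D) + f·e^(−b·D*)

with perfusion fraction `f`, diffusion coefficient `D` and pseudo-diffusion
coefficient `D*` (mm²/s, `D* ≫ D`).  The model silently assumes both
compartments relax identically.  They do not: blood and pre-urine have much
longer T2 than liver or kidney parenchyma, so the *apparent* `f` grows with
echo time — a pure model bias that varies with the scanner's minimum TE and
confounds multi-centre comparisons.

`t2ivim` is a library for quantifying and removing that bias.  It provides:

* **Forward models** — the conventional biexponential, the fully
  relaxation-weighted two-compartment signal (T1 saturation + T2 decay), and
  the closed-form *apparent-f oracle*: the exact `f` a conventional fit
  recovers from noiseless relaxation-weighted data,
  `f_app = f·w_f / ((1−f)·w_t + f·w_f)` with
  `w_x = (1 − e^(−TR/T1_x))·e^(−TE/T2_x)`.
* **A Rician Monte-Carlo simulator** with liver/kidney tissue presets at 3 T
  and seeded, reproducible noise ensembles.
* **Fitting** — bounded trust-region least squares with analytic Jacobians:
  per-TE conventional fits, and a joint fit over the flattened (b, TE) plane
  estimating `f, D, D*, T2_tissue, T2_fluid` (and optionally S0) in one step.
* **Protocol design** — Fisher-information/Cramér–Rao machinery and a
  design objective `Σ_i sqrt(β_i² + σ_f,i²)/f` summed over plausible fluid-T2
  scenarios, minimized over TE subsets exhaustively or with an integer-coded
  genetic algorithm, plus end-to-end Monte-Carlo validation.
* **IDEAL parameter mapping** — multiresolution voxel-wise fitting that
  constrains each resolution level around bilinearly interpolated
  coarser-level estimates (±20% for `f, D, D*, T2`; ±50% for S0), with 3×3
  Gaussian pre-smoothing, ROI summaries and Δf difference maps.
* **I/O and a thin CLI** — YAML acquisition schemes, long-format CSV signal
  tables, 4D NIfTI stacks (`t2ivim simulate | fit | fit-image |
  optimize-protocol | validate-protocol`).

## Worked example

`examples/01_te_bias.py` generates noiseless liver signals
(`f = 0.095`, `T2_tissue = 27 ms`) whose fluid compartment has just a 5 ms
longer T2, and fits the conventional model at each echo time:

```
 TE (ms)   fitted f   oracle f   bias (%)
      47     0.1211     0.1211       27.5
      52     0.1242     0.1242       30.7
      ...
      72     0.1374     0.1374       44.6
```

The conventional fit overestimates `f` by 27–45% across the 47–72 ms TE
range — with *no noise at all* — and lands exactly on the closed-form
apparent fraction, confirming the bias is structural.
`examples/02_joint_fit.py` shows the cure: fitting all (b, TE) data jointly
returns `f = 0.0955 ± 0.0153` (truth 0.095) at SNR 40 while the per-TE fits
read 0.17–0.21, with ~39% larger spreads.  `examples/03_protocol_design.py`
finds economical TE subsets (two short TEs to pin the IVIM decay, one long
TE to separate the compartmental T2s), and `examples/04_ideal_mapping.py`
maps a two-region phantom, recovering region medians within 2% of truth at
half the voxel-wise spread of independent fitting.

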