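"""Joint b-TE fitting removes the TE dependence and tightens f estimates.

Simulates Rician-noised liver data (SNR 40) with compartmental relaxation
differences, then compares the conventional per-TE fit with the joint fit
over all (b, TE) points in a small Monte-Carlo ensemble.  The joint fit is
run on per-TE-normalized slabs (the reduced model estimating the transverse
rate difference delta_r2 alongside f, D, D*).
"""

import numpy as np

from t2ivim import (NoiseModel, fit_ivim_1d, fit_t2ivim_2d_delta_r2,
                    liver_state, run_monte_carlo, simulation_grid,
                    summarize_comparison)

state = liver_state(delta_t1=300.0, delta_t2=15.0)
grid = simulation_grid()
n_rep = 200

joint = run_monte_carlo(state, grid, NoiseModel(sigma=0.025, seed=0), n_rep,
                        fitter=lambda ds: fit_t2ivim_2d_delta_r2(ds).estimates,
                        normalization="per_te")
print(f"joint (b,TE) fit over {n_rep} noisy repetitions:")
print(f"  f     = {joint.mean['f']:.4f} +/- {joint.sd['f']:.4f}  (true 0.095)")
print(f"  dR2   = {joint.mean['delta_r2']:.5f} 1/ms  (true {1/27 - 1/42:.5f})\n")

for te in (52.0, 62.0, 72.0):
    def fit1(ds, te=te):
        return fit_ivim_1d(ds.te_slice(te), ds.grid.b_values).estimates
    conv = run_monte_carlo(state, grid, NoiseModel(sigma=0.025, seed=int(te)),
                           n_rep, fitter=fit1, normalization="per_te")
    cmp_ = summarize_comparison(joint, conv, "f")
    print(f"conventional fit at TE={te:.0f}: f = {conv.mean['f']:.4f} "
          f"+/- {conv.sd['f']:.4f}; joint fit SD is "
          f"{-cmp_['delta_sigma_percent']:.0f}% lower (p = {cmp_['p_value']:.1e})")

print("\nThe per-TE fits are biased upward (and increasingly so with TE);")
print("the joint fit stays on truth with a markedly tighter spread.")
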