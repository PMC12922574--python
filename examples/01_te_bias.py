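"""How much does a tissue-fluid T2 mismatch bias the IVIM perfusion fraction?

Generates noiseless relaxation-weighted liver signals with a 5 ms fluid-tissue
T2 difference, fits the conventional single-TE biexponential model at each
echo time, and compares the fitted f against the closed-form apparent-f
corollary.  The printed bias is pure model error: it grows with TE and is
exactly predicted by the relaxation weight ratio, no noise involved.
"""

import numpy as np

from t2ivim import (apparent_f_oracle, fit_ivim_1d, generate_dataset,
                    liver_state, percent_bias, simulation_grid)

state = liver_state(delta_t2=5.0)          # T2_tissue 27 ms, T2_fluid 32 ms
grid = simulation_grid()                   # 16 b-values, TE 47-72 ms, TR 4000
ds = generate_dataset(state, grid)

print(f"true f = {state.ivim.f:.3f}; fluid T2 exceeds tissue T2 by 5 ms\n")
print(f"{'TE (ms)':>8} {'fitted f':>10} {'oracle f':>10} {'bias (%)':>10}")
for te in grid.te_values:
    fhat = fit_ivim_1d(ds.te_slice(te), np.asarray(grid.b_values))["f"]
    oracle = apparent_f_oracle(state, te, grid.reference_tr)
    print(f"{te:8.0f} {fhat:10.4f} {oracle:10.4f} {percent_bias(fhat, 0.095):10.1f}")

print("\nEven a 5 ms T2 difference inflates f by ~30% at TE=52 ms and ~45% at")
print("TE=72 ms; the fit lands exactly on the closed-form apparent fraction.")
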