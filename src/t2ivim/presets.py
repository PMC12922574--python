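"""Tissue and acquisition presets for abdominal T2-IVIM at 3 T.

Two numerical phantoms are shipped: healthy liver and kidney parenchyma with
biologically realistic IVIM parameters and compartmental relaxation times at
3 T, plus the b-value and TE sets used with them.  ``b`` in s/mm², times in
ms, diffusivities in mm²/s.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .signal_models import AcquisitionGrid, IVIMParams, RelaxationParams, TissueState

__all__ = [
    "liver_state",
    "kidney_state",
    "tissue_preset",
    "B_SET_1",
    "B_CONSENSUS_LIVER",
    "B_SET_2_KIDNEY",
    "TE_SET_1",
    "TE_SET_2",
    "TR_SET",
    "T2_FLUID_GRID_LIVER",
    "T2_FLUID_GRID_KIDNEY",
    "simulation_grid",
]

# 16-point multi-b protocol shared by both phantoms
B_SET_1 = (0.0, 10.0, 20.0, 30.0, 50.0, 70.0, 100.0, 150.0,
           200.0, 250.0, 300.0, 350.0, 450.0, 550.0, 650.0, 750.0)
# community-consensus 6-point liver set (CRLB-derived)
B_CONSENSUS_LIVER = (0.0, 10.0, 20.0, 100.0, 200.0, 550.0)
B_SET_2_KIDNEY = (0.0, 10.0, 100.0, 200.0, 500.0, 800.0)

TE_SET_1 = tuple(np.arange(47.0, 72.0 + 1e-9, 5.0))     # 47-72 ms, 6 values
TE_SET_2 = tuple(np.arange(50.0, 100.0 + 1e-9, 5.0))    # 50-100 ms, 11 values
TR_SET = (2000.0, 2500.0, 3000.0, 3500.0, 4000.0)

# fluid-T2 scenario grids used in protocol design
T2_FLUID_GRID_LIVER = tuple(np.arange(27.0, 87.0 + 1e-9, 5.0))    # 13 values
T2_FLUID_GRID_KIDNEY = tuple(np.arange(67.0, 150.0 + 1e-9, 15.0))

# Noise ladder: Rician SD on the normalized scale and the matching SNR at S0
NOISE_SD_LEVELS = (0.0, 0.005, 0.01, 0.015, 0.02, 0.025, 0.03)


def liver_state(delta_t1: float = 0.0, delta_t2: float = 0.0, s0: float = 1.0) -> TissueState:
    """Liver phantom at 3 T: f=0.095, D=1.0e-3, D*=0.067 mm²/s, T1t=800 ms,
    T2t=27 ms; fluid relaxation offset by the requested deltas (ms)."""
    return TissueState(
        ivim=IVIMParams(f=0.095, D=0.0010, D_star=0.067),
        relax=RelaxationParams(
            T1_tissue=800.0, T1_fluid=800.0 + delta_t1,
            T2_tissue=27.0, T2_fluid=27.0 + delta_t2,
        ),
        s0=s0,
    )


def kidney_state(delta_t1: float = 0.0, delta_t2: float = 0.0, s0: float = 1.0) -> TissueState:
    """Kidney phantom at 3 T: f=0.15, D=1.6e-3, D*=0.012 mm²/s, T1t=1200 ms,
    T2t=67 ms; fluid relaxation offset by the requested deltas (ms)."""
    return TissueState(
        ivim=IVIMParams(f=0.15, D=0.0016, D_star=0.012),
        relax=RelaxationParams(
            T1_tissue=1200.0, T1_fluid=1200.0 + delta_t1,
            T2_tissue=67.0, T2_fluid=67.0 + delta_t2,
        ),
        s0=s0,
    )


_PRESETS = {"liver": liver_state, "kidney": kidney_state}


def tissue_preset(name: str, delta_t1: float = 0.0, delta_t2: float = 0.0,
                  s0: float = 1.0) -> TissueState:
    """Look up a tissue preset by name ('liver' or 'kidney')."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}") from None
    return factory(delta_t1=delta_t1, delta_t2=delta_t2, s0=s0)


def simulation_grid(b_values=B_SET_1, te_values=TE_SET_1, tr=4000.0) -> AcquisitionGrid:
    """Single-TR acquisition grid with the normalization anchor at the
    shortest TE (the default simulation design)."""
    return AcquisitionGrid(b_values=tuple(b_values), te_values=tuple(te_values),
                           tr_values=(float(tr),))


def full_simulation_grid() -> AcquisitionGrid:
    """The complete 16 b × 6 TE × 5 TR phantom grid."""
    return AcquisitionGrid(b_values=B_SET_1, te_values=TE_SET_1, tr_values=TR_SET)
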