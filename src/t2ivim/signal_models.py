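"""Forward signal models for relaxation-compensated IVIM imaging.

The conventional intravoxel-incoherent-motion (IVIM) model describes the
diffusion-weighted signal as a biexponential decay over the b-value,

    S(b)/S0 = (1 - f) * exp(-b*D) + f * exp(-b*D*),

where ``f`` is the pseudo-diffusion volume fraction (perfusion fraction),
``D`` the molecular diffusion coefficient and ``D*`` the pseudo-diffusion
coefficient of the flowing compartment.  The model implicitly assumes both
compartments share the same relaxation times; when the fluid compartment has
a longer T2 (as blood and pre-urine do), the apparent ``f`` grows with echo
time.  The relaxation-compensated model makes the compartmental T1/T2
weighting explicit, which is what this module implements, together with its
analytic corollary: the exact ``f`` a conventional fit would recover from
noiseless relaxation-weighted data.

Units used throughout: b in s/mm², D and D* in mm²/s, all times (TE, TR,
T1, T2) in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "IVIMParams",
    "RelaxationParams",
    "AcquisitionGrid",
    "TissueState",
    "ivim_signal",
    "relaxation_ivim_signal",
    "t2ivim_signal",
    "apparent_f_oracle",
    "percent_bias",
]


@dataclass(frozen=True)
class IVIMParams:
    """Biexponential IVIM parameters.

    Attributes
    ----------
    f : float
        Pseudo-diffusion volume fraction, dimensionless, in [0, 1].
    D : float
        Molecular diffusion coefficient, mm²/s, strictly positive.
    D_star : float
        Pseudo-diffusion coefficient, mm²/s.  Must satisfy ``D_star >= D``:
        the flowing compartment decays faster, and enforcing the ordering at
        the type level prevents compartment-label switching.
    """

    f: float
    D: float
    D_star: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if self.D <= 0.0:
            raise ValueError(f"D must be positive, got {self.D}")
        if self.D_star < self.D:
            raise ValueError(
                f"D_star ({self.D_star}) must be >= D ({self.D}); "
                "swap compartments and use f -> 1 - f instead"
            )


@dataclass(frozen=True)
class RelaxationParams:
    """Compartmental relaxation times (ms), all strictly positive.

    ``delta_t1`` and ``delta_t2`` (fluid minus tissue) are derived, never
    stored independently.
    """

    T1_tissue: float
    T1_fluid: float
    T2_tissue: float
    T2_fluid: float

    def __post_init__(self) -> None:
        for name in ("T1_tissue", "T1_fluid", "T2_tissue", "T2_fluid"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def delta_t1(self) -> float:
        return self.T1_fluid - self.T1_tissue

    @property
    def delta_t2(self) -> float:
        return self.T2_fluid - self.T2_tissue


@dataclass(frozen=True)
class AcquisitionGrid:
    """The (b, TE, TR) acquisition design every model, fit and CRLB uses.

    ``reference_te``/``reference_tr`` anchor signal normalization: the b=0
    signal at that node defines S0 = 1 for normalized datasets.
    """

    b_values: tuple
    te_values: tuple
    tr_values: tuple = (4000.0,)
    averages: tuple | None = None
    reference_te: float | None = None
    reference_tr: float | None = None

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.b_values)
        te = tuple(float(x) for x in self.te_values)
        tr = tuple(float(x) for x in self.tr_values)
        if len(b) == 0 or len(te) == 0 or len(tr) == 0:
            raise ValueError("b_values, te_values and tr_values must be non-empty")
        if any(x < 0 for x in b):
            raise ValueError("b_values must be non-negative")
        if b[0] != 0.0:
            raise ValueError("b_values must start at b=0 (ascending order)")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("b_values must be strictly ascending")
        if len(set(te)) != len(te):
            raise ValueError("te_values must be unique")
        if any(x <= 0 for x in te) or any(x <= 0 for x in tr):
            raise ValueError("te_values and tr_values must be positive")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "te_values", te)
        object.__setattr__(self, "tr_values", tr)
        if self.averages is not None:
            avg = tuple(int(a) for a in self.averages)
            if len(avg) != len(b) or any(a < 1 for a in avg):
                raise ValueError("averages must give one positive integer per b-value")
            object.__setattr__(self, "averages", avg)
        ref_te = min(te) if self.reference_te is None else float(self.reference_te)
        ref_tr = max(tr) if self.reference_tr is None else float(self.reference_tr)
        if ref_te not in te:
            raise ValueError(f"reference_te {ref_te} not among te_values")
        object.__setattr__(self, "reference_te", ref_te)
        object.__setattr__(self, "reference_tr", ref_tr)

    @property
    def shape(self) -> tuple:
        """(n_b, n_te, n_tr)."""
        return (len(self.b_values), len(self.te_values), len(self.tr_values))

    def restrict_te(self, te_subset: Sequence[float]) -> "AcquisitionGrid":
        """Grid restricted to a TE subset (sorted); reference TE re-anchored
        to the smallest retained TE if the original anchor is dropped."""
        subset = tuple(sorted(float(t) for t in te_subset))
        missing = [t for t in subset if t not in self.te_values]
        if missing:
            raise ValueError(f"TE values {missing} not in grid")
        ref = self.reference_te if self.reference_te in subset else min(subset)
        return replace(self, te_values=subset, reference_te=ref)


@dataclass(frozen=True)
class TissueState:
    """IVIM + relaxation parameters of one tissue, with an overall scale s0."""

    ivim: IVIMParams
    relax: RelaxationParams
    s0: float = 1.0

    def __post_init__(self) -> None:
        if self.s0 <= 0.0:
            raise ValueError(f"s0 must be positive, got {self.s0}")


def ivim_signal(p: IVIMParams, b):
    """Conventional biexponential IVIM signal, normalized to S(b=0) = 1.

    Parameters
    ----------
    p : IVIMParams
    b : float or array_like
        Diffusion weighting in s/mm², non-negative.

    Returns
    -------
    float or ndarray in (0, 1].
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    out = (1.0 - p.f) * np.exp(-b * p.D) + p.f * np.exp(-b * p.D_star)
    return out.item() if out.ndim == 0 else out


def _compartment_weights(relax: RelaxationParams, te, tr):
    """Steady-state (1 - exp(-TR/T1)) * exp(-TE/T2) weights per compartment."""
    te = np.asarray(te, dtype=float)
    tr = np.asarray(tr, dtype=float)
    w_t = (1.0 - np.exp(-tr / relax.T1_tissue)) * np.exp(-te / relax.T2_tissue)
    w_f = (1.0 - np.exp(-tr / relax.T1_fluid)) * np.exp(-te / relax.T2_fluid)
    return w_t, w_f


def relaxation_ivim_signal(state: TissueState, b, te, tr):
    """Relaxation-compensated IVIM signal normalized by its own b=0 value.

    Each compartment term carries a saturation-recovery T1 factor
    ``1 - exp(-TR/T1)`` and a transverse decay ``exp(-TE/T2)``; the
    denominator is the b=0 signal at the *same* (TE, TR), so the result is
    again a biexponential in b whose apparent volume fraction depends on
    (TE, TR) — the source of the TE-dependent bias in f.
    """
    b = np.asarray(b, dtype=float)
    te = np.asarray(te, dtype=float)
    tr = np.asarray(tr, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    if np.any(te <= 0) or np.any(tr <= 0):
        raise ValueError("te and tr must be positive")
    p = state.ivim
    w_t, w_f = _compartment_weights(state.relax, te, tr)
    num = (1.0 - p.f) * w_t * np.exp(-b * p.D) + p.f * w_f * np.exp(-b * p.D_star)
    den = (1.0 - p.f) * w_t + p.f * w_f
    out = num / den
    return out.item() if out.ndim == 0 else out


def relaxation_ivim_signal_absolute(state: TissueState, b, te, tr):
    """Un-normalized relaxation-weighted signal ``s0 * numerator`` (keeps the
    absolute TE/TR decay; used for anchored dataset generation)."""
    b = np.asarray(b, dtype=float)
    te = np.asarray(te, dtype=float)
    tr = np.asarray(tr, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    if np.any(te <= 0) or np.any(tr <= 0):
        raise ValueError("te and tr must be positive")
    p = state.ivim
    w_t, w_f = _compartment_weights(state.relax, te, tr)
    out = state.s0 * (
        (1.0 - p.f) * w_t * np.exp(-b * p.D) + p.f * w_f * np.exp(-b * p.D_star)
    )
    return out.item() if out.ndim == 0 else out


def t2ivim_signal(p: IVIMParams, t2_tissue, t2_fluid, s0, b, te):
    """Joint b-TE forward model with absolute TE decay and free scale.

        S(b, TE) = S0 * [ (1-f) e^{-TE/T2t} e^{-bD} + f e^{-TE/T2f} e^{-bD*} ]

    This is the model the 2D (b, TE) fit estimates; T1 terms are omitted
    (long-TR regime, or absorbed into S0).
    """
    b = np.asarray(b, dtype=float)
    te = np.asarray(te, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    if t2_tissue <= 0 or t2_fluid <= 0:
        raise ValueError("T2 values must be positive")
    out = s0 * (
        (1.0 - p.f) * np.exp(-te / t2_tissue) * np.exp(-b * p.D)
        + p.f * np.exp(-te / t2_fluid) * np.exp(-b * p.D_star)
    )
    return out.item() if out.ndim == 0 else out


def apparent_f_oracle(state: TissueState, te, tr) -> float:
    """Exact pseudo-diffusion fraction a conventional IVIM fit recovers from
    noiseless relaxation-weighted data at one (TE, TR).

    At fixed (TE, TR) the relaxation-compensated signal is still an exact
    biexponential in b with the same D, D* but an apparent fraction

        f_app = f * w_f / ((1-f) * w_t + f * w_f),
        w_x = (1 - exp(-TR/T1_x)) * exp(-TE/T2_x),

    so the global minimum of a conventional fit to noiseless data is known in
    closed form.  This is the oracle the fitting tests compare against.
    """
    w_t, w_f = _compartment_weights(state.relax, te, tr)
    f = state.ivim.f
    return float(f * w_f / ((1.0 - f) * w_t + f * w_f))


def percent_bias(estimate, truth):
    """Percent bias 100 * (estimate - truth) / truth."""
    truth = np.asarray(truth, dtype=float)
    if np.any(truth == 0):
        raise ValueError("truth must be non-zero for a percent bias")
    out = 100.0 * (np.asarray(estimate, dtype=float) - truth) / truth
    return out.item() if out.ndim == 0 else out
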