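"""Bounded trust-region estimation of IVIM and compartmental-T2 parameters.

Two estimators are provided:

* :func:`fit_ivim_1d` — the conventional biexponential IVIM fit to the
  signal decay over b at a single echo time;
* :func:`fit_t2ivim_2d` — the joint fit over the flattened (b, TE) plane
  that estimates f, D, D* and both compartmental T2 values (plus an optional
  free scale S0) in a single one-step nonlinear least-squares problem.

Both use a bounded trust-region-reflective solver with analytic Jacobians
and data-driven initialization (segmented estimates seed the one-step fit).
Compartment-label degeneracies at the optimum (D* < D) are repaired by
swapping compartments and complementing f.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .simulator import SignalDataset

__all__ = ["FitOptions", "FitResult", "fit_ivim_1d", "fit_t2ivim_2d",
           "fit_t2ivim_2d_delta_r2", "default_fit_options"]

# global physical bounds
F_BOUNDS = (0.0, 1.0)
D_BOUNDS = (1e-5, 5e-3)           # mm²/s
D_STAR_UPPER = 0.5                # mm²/s
T2_BOUNDS = (5.0, 500.0)          # ms


@dataclass
class FitOptions:
    """Initial values and box bounds per parameter, plus solver controls.

    ``initial``, ``lower`` and ``upper`` map parameter names to floats; the
    bounds must bracket the initial values.  ``fit_s0`` toggles a free
    overall scale.
    """

    initial: dict
    lower: dict
    upper: dict
    fit_s0: bool = True
    max_iter: int = 400
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        for k, v in self.initial.items():
            lo, hi = self.lower[k], self.upper[k]
            if not lo <= v <= hi:
                raise ValueError(f"initial {k}={v} outside bounds [{lo}, {hi}]")


@dataclass
class FitResult:
    """Point estimates with convergence diagnostics."""

    estimates: dict
    residual_norm: float
    converged: bool
    n_iter: int
    swapped: bool = False

    def __getitem__(self, key: str) -> float:
        return self.estimates[key]


def _loglinear_high_b(signals: np.ndarray, b: np.ndarray) -> tuple:
    """Segmented seed: slope/intercept of log-signal over the high-b tail
    (b >= 200 where available, else the upper half of the b range)."""
    high = b >= 200.0
    if high.sum() < 2:
        high = b >= np.median(b)
    pos = signals > 0
    sel = high & pos
    if sel.sum() < 2:
        return 1e-3, float(max(signals[0], 1e-6))
    slope, intercept = np.polyfit(b[sel], np.log(signals[sel]), 1)
    return float(-slope), float(np.exp(intercept))


def _options_1d(signals: np.ndarray, b: np.ndarray, fit_s0: bool) -> FitOptions:
    d0, inter = _loglinear_high_b(signals, b)
    d0 = float(np.clip(d0, *D_BOUNDS))
    s_at_0 = float(max(signals[b == 0].mean(), 1e-6))
    f0 = float(np.clip(1.0 - inter / s_at_0, 1e-3, 0.7))
    ds_lower = d0
    initial = {"f": f0, "D": d0, "D_star": float(np.clip(10.0 * d0, ds_lower, D_STAR_UPPER))}
    lower = {"f": F_BOUNDS[0], "D": D_BOUNDS[0], "D_star": ds_lower}
    upper = {"f": F_BOUNDS[1], "D": D_BOUNDS[1], "D_star": D_STAR_UPPER}
    if fit_s0:
        initial["S0"] = s_at_0
        lower["S0"] = 1e-6
        upper["S0"] = 10.0 * s_at_0
    return FitOptions(initial=initial, lower=lower, upper=upper, fit_s0=fit_s0)


def _options_2d(ds: SignalDataset, fit_s0: bool) -> FitOptions:
    grid = ds.grid
    b = np.asarray(grid.b_values)
    te = np.asarray(grid.te_values)
    j = grid.tr_values.index(grid.reference_tr)
    # T2 seed from the log-linear TE decay of the b=0 signal
    s_b0 = np.clip(ds.values[0, :, j], 1e-9, None)
    if len(te) >= 2:
        slope, _ = np.polyfit(te, np.log(s_b0), 1)
        t2_0 = float(np.clip(-1.0 / slope if slope < 0 else 80.0, *T2_BOUNDS))
    else:
        t2_0 = 80.0
    # IVIM seed from the reference-TE slice
    i_ref = grid.te_values.index(grid.reference_te)
    ref = ds.values[:, i_ref, j]
    base = _options_1d(ref / max(ref[0], 1e-9), b, fit_s0=False)
    initial = dict(base.initial)
    lower, upper = dict(base.lower), dict(base.upper)
    initial["T2_tissue"] = t2_0
    initial["T2_fluid"] = float(np.clip(2.0 * t2_0, *T2_BOUNDS))
    for k in ("T2_tissue", "T2_fluid"):
        lower[k], upper[k] = T2_BOUNDS
    if fit_s0:
        # b=0 signal at the reference TE extrapolated to TE=0
        s00 = float(max(ref[0] * np.exp(grid.reference_te / t2_0), 1e-6))
        initial["S0"] = s00
        lower["S0"] = 1e-6
        upper["S0"] = 100.0 * s00
    return FitOptions(initial=initial, lower=lower, upper=upper, fit_s0=fit_s0)


def default_fit_options(model: str, ds, b_values=None, fit_s0: bool | None = None) -> FitOptions:
    """Data-driven initial values and global physical bounds.

    ``model`` is ``'ivim_1d'`` (``ds`` = per-b signal vector, ``b_values``
    required) or ``'t2ivim_2d'`` (``ds`` = :class:`SignalDataset`).
    """
    if model == "ivim_1d":
        if b_values is None:
            raise ValueError("ivim_1d options need b_values")
        return _options_1d(np.asarray(ds, float), np.asarray(b_values, float),
                           fit_s0=True if fit_s0 is None else fit_s0)
    if model == "t2ivim_2d":
        return _options_2d(ds, fit_s0=True if fit_s0 is None else fit_s0)
    raise ValueError(f"unknown model {model!r}")


def _run_trf(residual, jac, options: FitOptions, order: Sequence[str]) -> FitResult:
    x0 = np.array([options.initial[k] for k in order])
    lo = np.array([options.lower[k] for k in order])
    hi = np.array([options.upper[k] for k in order])
    res = least_squares(residual, x0, jac=jac, bounds=(lo, hi), method="trf",
                        xtol=options.tol, ftol=options.tol, gtol=options.tol,
                        max_nfev=options.max_iter)
    est = dict(zip(order, res.x))
    return FitResult(estimates=est, residual_norm=float(np.linalg.norm(res.fun)),
                     converged=bool(res.success), n_iter=int(res.nfev))


def _repair_labels(result: FitResult) -> FitResult:
    """Swap compartments (f -> 1-f, D <-> D*, T2t <-> T2f) if the
    pseudo-diffusion label landed on the slower compartment."""
    e = result.estimates
    if e["D_star"] >= e["D"]:
        return result
    e = dict(e)
    e["f"] = 1.0 - e["f"]
    e["D"], e["D_star"] = e["D_star"], e["D"]
    if "T2_tissue" in e:
        e["T2_tissue"], e["T2_fluid"] = e["T2_fluid"], e["T2_tissue"]
    result.estimates = e
    result.swapped = True
    return result


def fit_ivim_1d(signals, b_values, options: FitOptions | None = None) -> FitResult:
    """Conventional biexponential IVIM fit at one echo time.

    Requires at least four distinct b-values including b=0.  The default
    options fit a free scale S0, so the input need not be normalized to its
    own b=0 signal.  Non-convergence is flagged on the result, not raised.
    """
    y = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if y.shape != b.shape:
        raise ValueError("signals and b_values must have the same length")
    if len(np.unique(b)) < 4 or 0.0 not in b:
        raise ValueError("need >= 4 distinct b-values including b=0")
    if np.any(y <= 0):
        raise ValueError("signals must be positive")
    if options is None:
        options = _options_1d(y, b, fit_s0=True)
    n_par = 3 + int(options.fit_s0)
    if len(y) < n_par:
        raise ValueError(f"{len(y)} points cannot constrain {n_par} parameters")
    order = ["f", "D", "D_star"] + (["S0"] if options.fit_s0 else [])

    def residual(x):
        f, D, Ds = x[:3]
        s0 = x[3] if options.fit_s0 else 1.0
        return s0 * ((1 - f) * np.exp(-b * D) + f * np.exp(-b * Ds)) - y

    def jac(x):
        f, D, Ds = x[:3]
        s0 = x[3] if options.fit_s0 else 1.0
        ed, eds = np.exp(-b * D), np.exp(-b * Ds)
        cols = [s0 * (eds - ed), -s0 * (1 - f) * b * ed, -s0 * f * b * eds]
        if options.fit_s0:
            cols.append((1 - f) * ed + f * eds)
        return np.stack(cols, axis=1)

    return _repair_labels(_run_trf(residual, jac, options, order))


def flatten_bte(ds: SignalDataset, tr: float | None = None):
    """Flatten a (b, TE) dataset to 1D: b ascending within each TE, TEs
    ascending (the joint-fit concatenation order).  Returns (y, b, te, w)
    with per-point weights from the grid's averages (1 where absent)."""
    grid = ds.grid
    tr = grid.reference_tr if tr is None else float(tr)
    j = grid.tr_values.index(tr)
    order_te = np.argsort(grid.te_values)
    b = np.asarray(grid.b_values)
    y = np.concatenate([ds.values[:, i, j] for i in order_te])
    bb = np.tile(b, len(order_te))
    tt = np.repeat(np.asarray(grid.te_values)[order_te], len(b))
    w = np.tile(np.sqrt(np.asarray(grid.averages, float)) if grid.averages else
                np.ones(len(b)), len(order_te))
    return y, bb, tt, w


def fit_t2ivim_2d_delta_r2(ds: SignalDataset, tr: float | None = None) -> FitResult:
    """Joint fit of per-TE-normalized (b, TE) data.

    When every TE slab is normalized to its own b=0 signal, the absolute T2
    decay is gone and only the transverse-rate difference
    ``delta_r2 = 1/T2_tissue - 1/T2_fluid`` (1/ms) remains identifiable; the
    slab at echo time TE is

        [(1-f) e^{-bD} + f q e^{-bD*}] / [(1-f) + f q],   q = exp(TE * delta_r2).

    Estimates (f, D, D_star, delta_r2); f is the T1-apparent fraction.
    """
    grid = ds.grid
    if len(grid.te_values) < 2:
        raise ValueError("joint b-TE fit needs >= 2 echo times")
    if len(grid.b_values) < 4:
        raise ValueError("joint b-TE fit needs >= 4 b-values")
    y, b, te, w = flatten_bte(ds, tr=tr)
    i_ref = grid.te_values.index(grid.reference_te)
    j = grid.tr_values.index(grid.reference_tr if tr is None else float(tr))
    base = _options_1d(ds.values[:, i_ref, j], np.asarray(grid.b_values), fit_s0=False)
    initial = dict(base.initial, delta_r2=0.01)
    lower = dict(base.lower, delta_r2=0.0)
    upper = dict(base.upper, delta_r2=0.2)
    options = FitOptions(initial=initial, lower=lower, upper=upper, fit_s0=False)
    order = ["f", "D", "D_star", "delta_r2"]

    def parts(x):
        f, D, Ds, dr2 = x
        q = np.exp(te * dr2)
        ed, eds = np.exp(-b * D), np.exp(-b * Ds)
        u = (1 - f) * ed + f * q * eds
        u0 = (1 - f) + f * q
        return f, q, ed, eds, u, u0

    def residual(x):
        _, _, _, _, u, u0 = parts(x)
        return w * (u / u0 - y)

    def jac(x):
        f, q, ed, eds, u, u0 = parts(x)
        du = [q * eds - ed, -(1 - f) * b * ed, -f * b * q * eds, f * te * q * eds]
        du0 = [q - 1.0, 0.0, 0.0, f * te * q]
        cols = [(du[i] * u0 - u * du0[i]) / u0**2 for i in range(4)]
        return np.stack(cols, axis=1) * w[:, None]

    return _repair_labels(_run_trf(residual, jac, options, order))


def fit_t2ivim_2d(ds: SignalDataset, options: FitOptions | None = None,
                  tr: float | None = None) -> FitResult:
    """Joint T2-IVIM fit over the flattened (b, TE) plane.

    Estimates (f, D, D*, T2_tissue, T2_fluid) and, depending on the scale
    convention, a free scale S0.  Two conventions are supported:

    * ``fit_s0=True`` — the model carries an explicit free S0 (the image /
      in vivo convention, default for 'absolute' data);
    * ``fit_s0=False`` — the model is self-normalized by its own b=0 value
      at the grid's reference TE, eliminating S0 from the fit entirely and
      avoiding S0-noise propagation into f (the simulation convention,
      default for 'per_reference' data).

    The input must span at least two echo times and four b-values and must
    carry absolute TE decay: with per-TE normalization the individual T2s
    are not identifiable (only their rate difference is), so such input is
    refused.
    """
    grid = ds.grid
    if len(grid.te_values) < 2:
        raise ValueError("joint b-TE fit needs >= 2 echo times (T2s unidentifiable)")
    if len(grid.b_values) < 4:
        raise ValueError("joint b-TE fit needs >= 4 b-values")
    if ds.normalization == "per_te":
        raise ValueError(
            "per-TE-normalized input removes the absolute TE decay; only the "
            "transverse-rate difference is identifiable — use "
            "fit_t2ivim_2d_delta_r2 to opt into that reduced model"
        )
    if options is None:
        options = _options_2d(ds, fit_s0=(ds.normalization == "absolute"))
    y, b, te, w = flatten_bte(ds, tr=tr)
    te_ref = grid.reference_te
    order = ["f", "D", "D_star", "T2_tissue", "T2_fluid"] + (
        ["S0"] if options.fit_s0 else [])

    def parts(x):
        f, D, Ds, t2t, t2f = x[:5]
        A = np.exp(-te / t2t)
        B = np.exp(-te / t2f)
        ed, eds = np.exp(-b * D), np.exp(-b * Ds)
        return f, t2t, t2f, A, B, ed, eds

    if options.fit_s0:

        def residual(x):
            f, _, _, A, B, ed, eds = parts(x)
            s0 = x[5]
            return w * (s0 * ((1 - f) * A * ed + f * B * eds) - y)

        def jac(x):
            f, t2t, t2f, A, B, ed, eds = parts(x)
            s0 = x[5]
            cols = [
                s0 * (B * eds - A * ed),
                -s0 * (1 - f) * b * A * ed,
                -s0 * f * b * B * eds,
                s0 * (1 - f) * A * ed * te / t2t**2,
                s0 * f * B * eds * te / t2f**2,
                (1 - f) * A * ed + f * B * eds,
            ]
            return np.stack(cols, axis=1) * w[:, None]

    else:
        # self-normalized model: u(b, TE) / u(0, te_ref); the denominator
        # depends on (f, T2t, T2f) so its derivatives enter the Jacobian
        def residual(x):
            f, t2t, t2f, A, B, ed, eds = parts(x)
            u = (1 - f) * A * ed + f * B * eds
            u0 = (1 - f) * np.exp(-te_ref / t2t) + f * np.exp(-te_ref / t2f)
            return w * (u / u0 - y)

        def jac(x):
            f, t2t, t2f, A, B, ed, eds = parts(x)
            a_ref, b_ref = np.exp(-te_ref / t2t), np.exp(-te_ref / t2f)
            u = (1 - f) * A * ed + f * B * eds
            u0 = (1 - f) * a_ref + f * b_ref
            du = [B * eds - A * ed,
                  -(1 - f) * b * A * ed,
                  -f * b * B * eds,
                  (1 - f) * A * ed * te / t2t**2,
                  f * B * eds * te / t2f**2]
            du0 = [b_ref - a_ref, 0.0, 0.0,
                   (1 - f) * a_ref * te_ref / t2t**2,
                   f * b_ref * te_ref / t2f**2]
            cols = [(du[i] * u0 - u * du0[i]) / u0**2 for i in range(5)]
            return np.stack(cols, axis=1) * w[:, None]

    return _repair_labels(_run_trf(residual, jac, options, order))
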