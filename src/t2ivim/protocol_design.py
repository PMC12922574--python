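"""CRLB-based b-TE protocol design for pseudo-diffusion fraction estimation.

The precision attainable by the joint T2-IVIM fit on a candidate (b, TE)
design is bounded below by the Cramér–Rao bound: under Gaussian noise of SD
sigma the Fisher information is F = (1/σ²) Jᵀ W J, with J the Jacobian of
the forward model over the design points and W per-point averaging weights.
The design objective sums the normalized root-mean-square error of f,
sqrt(β² + σ_f²)/f, over a grid of plausible fluid-T2 scenarios; with a
correctly specified model the asymptotic bias β vanishes, so by default the
objective is the summed coefficient of variation of f with σ_f from the
CRLB.  TE subsets of fixed size are selected either exhaustively or by an
integer-coded genetic algorithm, and selections can be validated end-to-end
by Monte-Carlo simulation and fitting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .fitting import fit_t2ivim_2d
from .signal_models import AcquisitionGrid, TissueState, t2ivim_signal
from .simulator import MCSummary, NoiseModel, run_monte_carlo

__all__ = [
    "DesignSpace",
    "GAOptions",
    "DesignResult",
    "fisher_information",
    "crlb_sd_f",
    "nrmse_objective",
    "optimize_tes_exhaustive",
    "optimize_tes_ga",
    "validate_protocol_mc",
]

EXHAUSTIVE_BUDGET = 10**6

# parameter order of the design-mode Fisher matrix
DESIGN_PARAMS = ("f", "D", "D_star", "T2_tissue", "T2_fluid")


@dataclass(frozen=True)
class DesignSpace:
    """A TE-subset selection problem.

    ``candidates`` are the admissible echo times (ms), ``k`` the subset
    size; ``b_values`` and ``tr`` fix the rest of the acquisition.  The
    objective is evaluated for every fluid T2 in ``t2_fluid_grid`` with the
    tissue otherwise described by ``state``; ``sigma`` is the noise SD on
    the normalized scale (SNR at S0 = 1/sigma).
    """

    candidates: tuple
    b_values: tuple
    k: int
    state: TissueState
    t2_fluid_grid: tuple
    sigma: float = 0.025
    tr: float = 4000.0
    include_s0: bool = False
    bias_fn: Callable[[Sequence[float], float], float] | None = None

    def __post_init__(self) -> None:
        cand = tuple(sorted(float(t) for t in self.candidates))
        if len(set(cand)) != len(cand):
            raise ValueError("candidate TEs must be unique")
        if not 1 <= self.k <= len(cand):
            raise ValueError(f"subset size k={self.k} outside [1, {len(cand)}]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive for a CRLB")
        object.__setattr__(self, "candidates", cand)
        object.__setattr__(self, "b_values", tuple(float(b) for b in self.b_values))
        object.__setattr__(self, "t2_fluid_grid", tuple(float(t) for t in self.t2_fluid_grid))

    @property
    def reference_te(self) -> float:
        """Normalization anchor: the shortest candidate TE, shared by every
        subset so all subsets see the same absolute noise level."""
        return min(self.candidates)

    @property
    def n_subsets(self) -> int:
        return math.comb(len(self.candidates), self.k)


@dataclass(frozen=True)
class GAOptions:
    """Genetic-algorithm controls (integer-coded TE-index chromosomes)."""

    population: int = 200
    generations: int = 50
    tol: float = 1e-3
    elite_fraction: float = 0.05
    stall_generations: int = 15
    tournament: int = 3
    mutation_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0.0 < self.elite_fraction < 1.0:
            raise ValueError("elite_fraction must be in (0, 1)")


@dataclass
class DesignResult:
    """Chosen TE subset with its objective and search diagnostics."""

    te_subset: tuple
    objective: float
    breakdown: list            # per-T2_fluid (t2f, sigma_f, beta)
    method: str
    n_evaluations: int


def _design_points(space_or_grid, te_subset=None):
    if isinstance(space_or_grid, DesignSpace):
        b = np.asarray(space_or_grid.b_values)
        te = np.asarray(sorted(te_subset))
        avg = None
    else:
        grid: AcquisitionGrid = space_or_grid
        b = np.asarray(grid.b_values)
        te = np.asarray(sorted(grid.te_values))
        avg = grid.averages
    B, TE = np.meshgrid(b, te, indexing="ij")
    w = np.ones(B.size)
    if avg is not None:
        w = np.tile(np.asarray(avg, float)[:, None], (1, len(te))).ravel()
    return B.ravel(), TE.ravel(), w


def _jacobian(state: TissueState, t2_fluid: float, b, te, reference_te: float,
              include_s0: bool, model: str = "s0_constant") -> np.ndarray:
    """Analytic Jacobian of the normalized T2-IVIM model at the true state.

    ``model='s0_constant'`` (design default): the forward model is scaled by
    the parameter-independent constant that makes the true b=0 signal at
    ``reference_te`` equal 1, so sigma is the noise SD relative to that
    anchor for every design and S0 carries no uncertainty.

    ``model='self_normalized'``: the model is divided by its own b=0 value
    at ``reference_te``; the denominator depends on (f, T2t, T2f) and its
    derivatives enter the Jacobian.  This matches the estimator used by the
    S0-free-less simulation fit, so it is the right bound for CRLB-vs-MC
    consistency checks.
    """
    p = state.ivim
    t2t = state.relax.T2_tissue
    f, D, Ds = p.f, p.D, p.D_star
    A = np.exp(-te / t2t)
    Bf = np.exp(-te / t2_fluid)
    a_ref = np.exp(-reference_te / t2t)
    b_ref = np.exp(-reference_te / t2_fluid)
    ed, eds = np.exp(-b * D), np.exp(-b * Ds)
    du = [
        Bf * eds - A * ed,                      # d/df
        -(1 - f) * b * A * ed,                  # d/dD
        -f * b * Bf * eds,                      # d/dD*
        (1 - f) * A * ed * te / t2t**2,         # d/dT2_tissue
        f * Bf * eds * te / t2_fluid**2,        # d/dT2_fluid
    ]
    u0 = (1 - f) * a_ref + f * b_ref
    if model == "s0_constant":
        cols = du
        if include_s0:
            cols = du + [(1 - f) * A * ed + f * Bf * eds]
        return np.stack(cols, axis=1) / u0
    if model == "self_normalized":
        if include_s0:
            raise ValueError("self-normalized model has no S0 parameter")
        u = (1 - f) * A * ed + f * Bf * eds
        du0 = [b_ref - a_ref, 0.0, 0.0,
               (1 - f) * a_ref * reference_te / t2t**2,
               f * b_ref * reference_te / t2_fluid**2]
        cols = [(du[i] * u0 - u * du0[i]) / u0**2 for i in range(5)]
        return np.stack(cols, axis=1)
    raise ValueError(f"unknown CRLB model {model!r}")


def fisher_information(state: TissueState, grid: AcquisitionGrid, sigma: float,
                       t2_fluid: float | None = None,
                       include_s0: bool = False,
                       model: str = "s0_constant") -> np.ndarray:
    """Gaussian-noise Fisher matrix F = (1/σ²) Jᵀ W J over a (b, TE) grid.

    Parameters follow :data:`DESIGN_PARAMS` order (plus S0 if requested);
    W holds per-point averages from the grid (1 otherwise).  ``t2_fluid``
    overrides the state's fluid T2 (scenario evaluation); ``model`` selects
    the normalization convention (see :func:`_jacobian`).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t2f = state.relax.T2_fluid if t2_fluid is None else float(t2_fluid)
    b, te, w = _design_points(grid)
    n_par = 5 + int(include_s0)
    if b.size <= n_par:
        raise ValueError("design needs more points than parameters")
    J = _jacobian(state, t2f, b, te, grid.reference_te, include_s0, model)
    return (J.T * w) @ J / sigma**2


def _crlb_sd_f_from_jac(J: np.ndarray, w: np.ndarray, sigma: float) -> float:
    F = (J.T * w) @ J / sigma**2
    try:
        cov = np.linalg.inv(F)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(F)
        raise np.linalg.LinAlgError(
            f"singular Fisher matrix (condition number {cond:.3g}); "
            "the f direction is not identifiable on this design"
        ) from exc
    var = cov[0, 0]
    if var <= 0 or not np.isfinite(var):
        raise np.linalg.LinAlgError("Fisher matrix numerically singular for f")
    return float(np.sqrt(var))


def crlb_sd_f(state: TissueState, grid: AcquisitionGrid, sigma: float,
              t2_fluid: float | None = None, include_s0: bool = False,
              model: str = "s0_constant") -> float:
    """CRLB standard-deviation bound on f: sqrt of the (f, f) entry of the
    inverse Fisher matrix."""
    t2f = state.relax.T2_fluid if t2_fluid is None else float(t2_fluid)
    b, te, w = _design_points(grid)
    J = _jacobian(state, t2f, b, te, grid.reference_te, include_s0, model)
    return _crlb_sd_f_from_jac(J, w, sigma)


def nrmse_objective(te_subset: Sequence[float], space: DesignSpace,
                    return_breakdown: bool = False):
    """Design objective: sum over the fluid-T2 grid of sqrt(β² + σ_f²)/f.

    σ_f is the CRLB bound for the subset's (b, TE) design; β is 0 unless the
    space carries a ``bias_fn`` (e.g. a small Monte-Carlo plug-in).
    """
    subset = tuple(sorted(float(t) for t in te_subset))
    if any(t not in space.candidates for t in subset):
        raise ValueError("te_subset must be drawn from the candidates")
    b = np.asarray(space.b_values)
    te = np.asarray(subset)
    B, TE = np.meshgrid(b, te, indexing="ij")
    Bv, TEv = B.ravel(), TE.ravel()
    w = np.ones(Bv.size)
    f_true = space.state.ivim.f
    total, breakdown = 0.0, []
    for t2f in space.t2_fluid_grid:
        J = _jacobian(space.state, t2f, Bv, TEv, space.reference_te, space.include_s0)
        sd = _crlb_sd_f_from_jac(J, w, space.sigma)
        beta = space.bias_fn(subset, t2f) if space.bias_fn is not None else 0.0
        total += math.sqrt(beta**2 + sd**2) / f_true
        breakdown.append((t2f, sd, beta))
    return (total, breakdown) if return_breakdown else total


def optimize_tes_exhaustive(space: DesignSpace) -> DesignResult:
    """Evaluate every k-subset of the candidate TEs; global minimizer, ties
    broken toward the lexicographically smallest subset."""
    if space.n_subsets > EXHAUSTIVE_BUDGET:
        raise ValueError(
            f"{space.n_subsets} subsets exceed the exhaustive budget "
            f"({EXHAUSTIVE_BUDGET}); use optimize_tes_ga"
        )
    best, best_obj, n_eval = None, np.inf, 0
    for subset in itertools.combinations(space.candidates, space.k):
        obj = nrmse_objective(subset, space)
        n_eval += 1
        if obj < best_obj or (obj == best_obj and subset < best):
            best, best_obj = subset, obj
    _, breakdown = nrmse_objective(best, space, return_breakdown=True)
    return DesignResult(te_subset=best, objective=best_obj, breakdown=breakdown,
                        method="exhaustive", n_evaluations=n_eval)


def optimize_tes_ga(space: DesignSpace, opts: GAOptions | None = None) -> DesignResult:
    """Integer-coded genetic algorithm over TE subsets.

    Chromosomes are k distinct candidate indices; selection is by
    tournament, recombination by uniform crossover with duplicate repair,
    mutation re-draws a gene uniformly; the fittest ``elite_fraction`` of
    each generation is carried over unchanged.  Stops at the generation cap
    or when the best objective improves by less than ``tol`` over a stall
    window.  Fully reproducible under ``opts.seed``.
    """
    opts = opts or GAOptions()
    rng = np.random.default_rng(opts.seed)
    n_cand, k = len(space.candidates), space.k
    cand = np.asarray(space.candidates)
    cache: dict = {}
    n_eval = 0

    def fitness(idx: tuple) -> float:
        nonlocal n_eval
        key = tuple(sorted(idx))
        if key not in cache:
            cache[key] = nrmse_objective(cand[list(key)], space)
            n_eval += 1
        return cache[key]

    def random_individual():
        return tuple(rng.choice(n_cand, size=k, replace=False))

    def repair(genes):
        seen, out = set(), []
        for g in genes:
            while g in seen:
                g = int(rng.integers(n_cand))
            seen.add(g)
            out.append(g)
        return tuple(out)

    pop = [random_individual() for _ in range(opts.population)]
    n_elite = max(1, int(round(opts.elite_fraction * opts.population)))
    best_hist: list = []
    for _ in range(opts.generations):
        scores = np.array([fitness(ind) for ind in pop])
        order = np.argsort(scores, kind="stable")
        pop = [pop[i] for i in order]
        scores = scores[order]
        best_hist.append(scores[0])
        if (len(best_hist) > opts.stall_generations
                and best_hist[-opts.stall_generations - 1] - best_hist[-1] < opts.tol):
            break
        nxt = pop[:n_elite]
        while len(nxt) < opts.population:
            parents = []
            for _ in range(2):
                rivals = rng.choice(len(pop), size=min(opts.tournament, len(pop)),
                                    replace=False)
                parents.append(pop[min(rivals)])  # pop sorted: lower index = fitter
            child = [parents[int(rng.integers(2))][g] for g in range(k)]
            child = [int(rng.integers(n_cand)) if rng.random() < opts.mutation_rate
                     else g for g in child]
            nxt.append(repair(child))
        pop = nxt
    scores = np.array([fitness(ind) for ind in pop])
    best = pop[int(np.argmin(scores))]
    subset = tuple(float(t) for t in sorted(cand[list(best)]))
    obj, breakdown = nrmse_objective(subset, space, return_breakdown=True)
    return DesignResult(te_subset=subset, objective=obj, breakdown=breakdown,
                        method="ga", n_evaluations=n_eval)


def validate_protocol_mc(te_subset: Sequence[float], space: DesignSpace,
                         n_rep: int = 2500, seed: int = 0,
                         t2_fluid: float | None = None) -> MCSummary:
    """End-to-end check of a TE subset: simulate Rician-noised data on the
    restricted grid at the space's noise level and run the joint 2D fit
    ``n_rep`` times."""
    subset = tuple(sorted(float(t) for t in te_subset))
    grid = AcquisitionGrid(b_values=space.b_values, te_values=subset,
                           tr_values=(space.tr,))
    state = space.state
    if t2_fluid is not None:
        from dataclasses import replace
        state = replace(state, relax=replace(state.relax, T2_fluid=float(t2_fluid)))
    noise = NoiseModel(sigma=space.sigma, seed=seed)
    return run_monte_carlo(state, grid, noise, n_rep,
                           fitter=lambda ds: fit_t2ivim_2d(ds).estimates)
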