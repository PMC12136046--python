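"""CMA-ES inversion of the network model against empirical FC and FCD.

A particle is one candidate free-parameter vector; evaluating it means
expanding the regional weights, running feedback inhibition control,
simulating BOLD, and scoring the simulated FC/FCD against the target
features. The cost is

    cost = -gof + bounds_penalty + fic_penalty

where out-of-bounds components are corrected to the boundary and charged a
quadratic penalty (a violation of 10% of a parameter's range costs 0.01),
and residual excitatory rates outside the 2-4 Hz band are charged the
soft FIC penalty. The optimizer is a standard covariance matrix
adaptation evolution strategy (rank-one plus rank-mu update, cumulative
step-size adaptation) run in the unit cube with per-dimension scaling to
the parameter bounds. Fits are repeated over ``n_runs`` optimizer seeds
and the run with the best goodness of fit wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .constants import ModelConstants
from .features import (GofBreakdown, WindowSpec, compute_fc, compute_fcd,
                       goodness_of_fit, intrahemispheric_edge_mask)
from .fic import FICConfig, run_fic
from .hemo import HemoError
from .model import (Connectome, FreeParams, MapSet, RegionalWeights, SimConfig,
                    SimOutput, SimulationError, expand_regional_params, simulate)

__all__ = ["FitConfig", "FitResult", "FitProblem", "ParamSpace", "model_variant",
           "fic_penalty", "evaluate_particle", "run_cmaes", "fit_subject", "CMAES"]

#: cost assigned to particles whose simulation blows up
BLOWUP_COST = 1e6


def fic_penalty(mean_r_E: np.ndarray, rate_range: tuple[float, float] = (2.0, 4.0),
                center: float = 3.0, decay: float = 0.05) -> float:
    """Soft FIC penalty (2/n) * sum_i (1 - exp(-decay*|<r_E,i> - center|))
    summed over nodes whose rate lies outside ``rate_range`` only."""
    r = np.asarray(mean_r_E, float)
    out = (r < rate_range[0]) | (r > rate_range[1])
    n = r.size
    return float(2.0 / n * np.sum(1.0 - np.exp(-decay * np.abs(r[out] - center))))


# ---------------------------------------------------------------------------
# parameter layouts


@dataclass
class ParamSpace:
    """Free-parameter layout of a model variant.

    ``decode`` maps a bounds-respecting real vector to (G, regional
    weights before FIC).
    """

    variant: str
    dim: int
    bounds: np.ndarray                       # (dim, 2)
    decode: Callable[[np.ndarray], tuple[float, RegionalWeights]]
    names: Sequence[str] = ()


def model_variant(variant: str, maps: Optional[MapSet] = None,
                  n_nodes: Optional[int] = None) -> ParamSpace:
    """Parameter layout for a model variant.

    - ``map_based``: G + two biases + 2k map coefficients (15 when k = 6)
    - ``homogeneous``: G, uniform w_EE, uniform w_EI (3)
    - ``node_based``: G + per-node w_EE and w_EI (1 + 2n; 201 when n = 100)
    """
    from .model import G_BOUNDS, WB_BOUNDS

    if variant == "map_based":
        if maps is None:
            raise ValueError("map_based variant requires a MapSet")
        bounds = FreeParams.default_bounds(maps)
        k, local_maps = maps.k, maps

        def decode(v: np.ndarray) -> tuple[float, RegionalWeights]:
            theta = FreeParams.from_vector(v, k, bounds)
            return theta.G, expand_regional_params(theta, local_maps)

        names = (["G", "wb_EE", "wb_EI"]
                 + [f"c_EE.{nm}" for nm in maps.names]
                 + [f"c_EI.{nm}" for nm in maps.names])
        return ParamSpace(variant, 3 + 2 * k, bounds, decode, names)

    if variant == "homogeneous":
        if n_nodes is None:
            raise ValueError("homogeneous variant requires n_nodes")
        bounds = np.asarray([G_BOUNDS, WB_BOUNDS, WB_BOUNDS], float)
        n = n_nodes

        def decode(v: np.ndarray) -> tuple[float, RegionalWeights]:
            return v[0], RegionalWeights(np.full(n, v[1]), np.full(n, v[2]))

        return ParamSpace(variant, 3, bounds, decode, ["G", "w_EE", "w_EI"])

    if variant == "node_based":
        if n_nodes is None:
            raise ValueError("node_based variant requires n_nodes")
        n = n_nodes
        bounds = np.vstack([np.asarray([G_BOUNDS]),
                            np.tile(WB_BOUNDS, (2 * n, 1))]).astype(float)

        def decode(v: np.ndarray) -> tuple[float, RegionalWeights]:
            return v[0], RegionalWeights(v[1:1 + n], v[1 + n:])

        names = (["G"] + [f"w_EE.{i}" for i in range(n)]
                 + [f"w_EI.{i}" for i in range(n)])
        return ParamSpace(variant, 1 + 2 * n, bounds, decode, names)

    raise ValueError(f"unknown model variant {variant!r}")


# ---------------------------------------------------------------------------
# fit configuration / problem / result


@dataclass
class FitConfig:
    lambda_: int = 210
    max_generations: int = 80
    early_stop_window: int = 30
    early_stop_min_improvement: float = 0.005
    rate_range: tuple[float, float] = (2.0, 4.0)
    n_runs: int = 2
    run_seeds: Optional[Sequence[int]] = None
    sigma0: float = 0.25                 # initial step in unit-cube coordinates

    def __post_init__(self) -> None:
        if self.lambda_ < 4:
            raise ValueError("population size must be >= 4")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")

    @property
    def max_evaluations_per_run(self) -> int:
        return self.lambda_ * self.max_generations

    @property
    def max_evaluations_per_subject(self) -> int:
        return self.n_runs * self.max_evaluations_per_run


@dataclass
class FitProblem:
    """One subject/session's data plus everything needed to score a particle."""

    connectome: Connectome
    space: ParamSpace
    emp_fc: np.ndarray
    emp_fcd: np.ndarray
    window_spec: WindowSpec
    sim_config: SimConfig
    fic_config: FICConfig = field(default_factory=FICConfig)
    constants: ModelConstants = field(default_factory=ModelConstants)
    include_interhemispheric: bool = False
    mask_fcd_edges: bool = True
    rate_range: tuple[float, float] = (2.0, 4.0)

    @property
    def hemisphere(self) -> Optional[np.ndarray]:
        return self.connectome.hemisphere

    def fcd_edge_mask(self) -> Optional[np.ndarray]:
        if self.mask_fcd_edges and self.hemisphere is not None \
                and not self.include_interhemispheric:
            return intrahemispheric_edge_mask(self.hemisphere)
        return None

    @classmethod
    def from_bold(cls, connectome: Connectome, space: ParamSpace,
                  emp_bold: np.ndarray, window_spec: WindowSpec,
                  sim_config: SimConfig,
                  outlier_mask: Optional[np.ndarray] = None,
                  **kw) -> "FitProblem":
        """Build a problem from an empirical BOLD matrix (and optional
        per-volume outlier mask) by computing its FC and FCD features."""
        valid = None if outlier_mask is None else ~np.asarray(outlier_mask, bool)
        emp_fc = compute_fc(emp_bold, valid_mask=valid)
        prob = cls(connectome=connectome, space=space, emp_fc=emp_fc,
                   emp_fcd=np.eye(2), window_spec=window_spec,
                   sim_config=sim_config, **kw)
        emp_fcd, _ = compute_fcd(emp_bold, window_spec,
                                 outlier_mask=outlier_mask,
                                 edge_mask=prob.fcd_edge_mask())
        prob.emp_fcd = emp_fcd
        return prob


@dataclass
class FitResult:
    best_theta: np.ndarray
    best_cost: float
    best_gof: float
    best_breakdown: Optional[GofBreakdown]
    history: list
    n_simulations: int
    run_seed: int
    optimal_sim: Optional[SimOutput]
    optimal_weights: Optional[RegionalWeights]
    stopped_early: bool = False


# ---------------------------------------------------------------------------
# particle evaluation


def evaluate_particle(theta: np.ndarray, problem: FitProblem
                      ) -> tuple[float, Optional[GofBreakdown],
                                 Optional[SimOutput], Optional[RegionalWeights]]:
    """Score one (possibly out-of-bounds) real-space parameter vector.

    Out-of-bounds components are corrected to the boundary and charged a
    quadratic penalty in range-normalized units.
    """
    theta = np.asarray(theta, float)
    lo, hi = problem.space.bounds[:, 0], problem.space.bounds[:, 1]
    clipped = np.clip(theta, lo, hi)
    bounds_pen = float(np.sum(((theta - clipped) / (hi - lo)) ** 2))
    try:
        G, weights = problem.space.decode(clipped)
        weights, _fic = run_fic(problem.connectome, weights, G,
                                problem.sim_config, problem.constants,
                                problem.fic_config)
        sim = simulate(problem.connectome, weights, G, problem.sim_config,
                       constants=problem.constants)
        sim_fc = compute_fc(sim.bold)
        sim_fcd, _ = compute_fcd(sim.bold, problem.window_spec,
                                 edge_mask=problem.fcd_edge_mask())
        breakdown = goodness_of_fit(
            sim_fc, sim_fcd, problem.emp_fc, problem.emp_fcd,
            hemisphere=problem.hemisphere,
            include_interhemispheric=problem.include_interhemispheric)
    except (SimulationError, HemoError, ValueError) as exc:
        import logging
        logging.getLogger(__name__).warning("particle culled: %s", exc)
        return BLOWUP_COST, None, None, None
    fic_pen = fic_penalty(sim.mean_r_E, problem.rate_range)
    breakdown.penalties = {"bounds": bounds_pen, "fic": fic_pen}
    cost = -breakdown.gof + bounds_pen + fic_pen
    return cost, breakdown, sim, weights


# ---------------------------------------------------------------------------
# CMA-ES


class CMAES:
    """Covariance matrix adaptation evolution strategy (mu/mu_w, lambda).

    Standard formulation: log-linear recombination weights over the best
    floor(lambda/2) particles, cumulative step-size adaptation, rank-one
    plus rank-mu covariance update.
    """

    def __init__(self, x0: np.ndarray, sigma0: float, popsize: int,
                 rng: np.random.Generator):
        self.rng = rng
        self.dim = d = len(x0)
        self.m = np.asarray(x0, float).copy()
        self.sigma = float(sigma0)
        self.lam = int(popsize)
        self.mu = self.lam // 2
        w = np.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.w = w / w.sum()
        self.mueff = 1.0 / np.sum(self.w ** 2)
        self.cc = (4 + self.mueff / d) / (d + 4 + 2 * self.mueff / d)
        self.cs = (self.mueff + 2) / (d + self.mueff + 5)
        self.c1 = 2 / ((d + 1.3) ** 2 + self.mueff)
        self.cmu = min(1 - self.c1,
                       2 * (self.mueff - 2 + 1 / self.mueff)
                       / ((d + 2) ** 2 + self.mueff))
        self.damps = (1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (d + 1)) - 1)
                      + self.cs)
        self.chiN = np.sqrt(d) * (1 - 1 / (4 * d) + 1 / (21 * d ** 2))
        self.pc = np.zeros(d)
        self.ps = np.zeros(d)
        self.C = np.eye(d)
        self._decompose()
        self.count = 0
        self.restarted = False
        self._y = None

    def _decompose(self) -> None:
        evals, B = np.linalg.eigh((self.C + self.C.T) / 2)
        if not np.all(np.isfinite(evals)) or evals.max() <= 0 \
                or evals.max() / max(evals.min(), 1e-300) > 1e14:
            raise FloatingPointError("degenerate covariance")
        self.B = B
        self.Dd = np.sqrt(np.maximum(evals, 0.0))

    def ask(self) -> np.ndarray:
        z = self.rng.standard_normal((self.lam, self.dim))
        self._y = z * self.Dd @ self.B.T        # y_i = B D z_i
        return self.m + self.sigma * self._y

    def tell(self, costs: np.ndarray) -> None:
        order = np.argsort(costs)
        y_sel = self._y[order[: self.mu]]
        y_w = self.w @ y_sel
        self.m = self.m + self.sigma * y_w
        c_inv_sqrt_yw = self.B @ ((self.B.T @ y_w) / np.maximum(self.Dd, 1e-300))
        self.ps = ((1 - self.cs) * self.ps
                   + np.sqrt(self.cs * (2 - self.cs) * self.mueff) * c_inv_sqrt_yw)
        self.count += 1
        hsig = (np.linalg.norm(self.ps)
                / np.sqrt(1 - (1 - self.cs) ** (2 * self.count)) / self.chiN
                < 1.4 + 2 / (self.dim + 1))
        self.pc = ((1 - self.cc) * self.pc
                   + hsig * np.sqrt(self.cc * (2 - self.cc) * self.mueff) * y_w)
        rank_mu = (y_sel * self.w[:, None]).T @ y_sel
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc)
                               + (1 - hsig) * self.cc * (2 - self.cc) * self.C)
                  + self.cmu * rank_mu)
        self.sigma *= np.exp(self.cs / self.damps
                             * (np.linalg.norm(self.ps) / self.chiN - 1))
        try:
            self._decompose()
        except FloatingPointError:
            if self.restarted:
                raise RuntimeError("CMA-ES covariance degenerated twice; aborting")
            # restart once from the current mean
            self.restarted = True
            self.C = np.eye(self.dim)
            self.pc[:] = 0.0
            self.ps[:] = 0.0
            self.sigma = max(self.sigma, 1e-8)
            self._decompose()


def _minimize_cmaes(func, dim: int, popsize: int, max_generations: int,
                    seed: int, sigma0: float = 0.25,
                    early_stop_window: Optional[int] = None,
                    early_stop_min_improvement: float = 0.0,
                    callback=None):
    """Minimize ``func`` over the unit cube [0,1]^dim; returns
    (best_u, best_cost, history, n_evals, stopped_early)."""
    rng = np.random.default_rng(seed)
    es = CMAES(np.full(dim, 0.5), sigma0, popsize, rng)
    best_u, best_cost = None, np.inf
    best_trace, history = [], []
    n_evals = 0
    stopped = False
    for gen in range(max_generations):
        U = es.ask()
        costs = np.empty(len(U))
        for i, u in enumerate(U):
            costs[i] = func(u)
        n_evals += len(U)
        es.tell(costs)
        gbest = int(np.argmin(costs))
        if costs[gbest] < best_cost:
            best_cost = float(costs[gbest])
            best_u = U[gbest].copy()
        best_trace.append(best_cost)
        history.append({"generation": gen, "best": float(costs[gbest]),
                        "median": float(np.median(costs)),
                        "best_ever": best_cost, "sigma": float(es.sigma)})
        if callback is not None:
            callback(history[-1])
        w = early_stop_window
        if w is not None and len(best_trace) > w \
                and best_trace[-1 - w] - best_trace[-1] <= early_stop_min_improvement:
            stopped = True
            break
    return best_u, best_cost, history, n_evals, stopped


def run_cmaes(problem: FitProblem, config: FitConfig, run_seed: int,
              progress=None) -> FitResult:
    """One CMA-ES run; returns the best particle ever seen, re-evaluated
    so its simulation output and weights are attached."""
    lo, hi = problem.space.bounds[:, 0], problem.space.bounds[:, 1]

    def to_real(u: np.ndarray) -> np.ndarray:
        return lo + u * (hi - lo)

    def func(u: np.ndarray) -> float:
        cost, *_ = evaluate_particle(to_real(u), problem)
        return cost

    best_u, best_cost, history, n_evals, stopped = _minimize_cmaes(
        func, problem.space.dim, config.lambda_, config.max_generations,
        seed=run_seed, sigma0=config.sigma0,
        early_stop_window=config.early_stop_window,
        early_stop_min_improvement=config.early_stop_min_improvement,
        callback=progress)
    if best_u is None or best_cost >= BLOWUP_COST:
        raise RuntimeError("CMA-ES run produced no evaluable particle")
    theta = to_real(best_u)
    cost, breakdown, sim, weights = evaluate_particle(theta, problem)
    gof = breakdown.gof if breakdown is not None else -np.inf
    return FitResult(best_theta=np.clip(theta, lo, hi), best_cost=best_cost,
                     best_gof=gof, best_breakdown=breakdown, history=history,
                     n_simulations=n_evals, run_seed=run_seed,
                     optimal_sim=sim, optimal_weights=weights,
                     stopped_early=stopped)


def fit_subject(problem: FitProblem, config: FitConfig,
                base_seed: int = 0, progress=None) -> tuple[FitResult, list]:
    """Run ``config.n_runs`` optimizer seeds and keep the run with the
    highest goodness of fit. Returns (winner, all run results)."""
    seeds = (list(config.run_seeds) if config.run_seeds is not None
             else [(base_seed + 1 + r) % (2 ** 31) for r in range(config.n_runs)])
    if not seeds:
        raise ValueError("at least one run seed required")
    results, errors = [], []
    for s in seeds:
        try:
            results.append(run_cmaes(problem, config, s, progress=progress))
        except RuntimeError as exc:
            errors.append(exc)
    if not results:
        raise RuntimeError(f"all {len(seeds)} fit runs failed: {errors}")
    winner = max(results, key=lambda r: r.best_gof)
    return winner, results
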