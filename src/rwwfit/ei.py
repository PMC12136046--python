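"""Regional excitation-inhibition markers and their validation experiments.

The primary in-silico E-I marker of a node is the time-averaged total
input current to its excitatory pool, <I_E> (nA), taken from the optimal
simulation after burn-in; the alternative marker is the ratio of
time-averaged synaptic gating variables <S_E>/<S_I>. Validation
harnesses: single-parameter perturbations with frozen feedback inhibition
(sign tests), ground-truth recovery of a synthetic subject, noise-seed
sensitivity, and intraclass correlation (ICC) agreement measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .constants import ModelConstants
from .fic import FICConfig
from .model import Connectome, MapSet, RegionalWeights, SimConfig, SimOutput, simulate

__all__ = ["EIMap", "PerturbationResult", "RecoveryReport", "extract_ei",
           "perturb_and_compare", "icc", "recovery_experiment", "seed_sensitivity"]


@dataclass
class EIMap:
    values: np.ndarray
    marker: str                        # "input_current" | "gating_ratio"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("E-I map contains non-finite values")


def extract_ei(sim: SimOutput, marker: str = "input_current",
               provenance: Optional[dict] = None) -> EIMap:
    """Extract the regional E-I map from a simulation's post-burn-in
    state averages. Pure function of the simulation output."""
    if marker == "input_current":
        values = sim.mean_I_E.copy()
    elif marker == "gating_ratio":
        if np.any(sim.mean_S_I == 0):
            raise ValueError("mean inhibitory gating is zero at some node; "
                             "gating_ratio undefined")
        values = sim.mean_S_E / sim.mean_S_I
    else:
        raise ValueError(f"unknown marker {marker!r}")
    prov = dict(provenance or {})
    prov.update(sim.seeds_used)
    return EIMap(values, marker, prov)


@dataclass
class PerturbationResult:
    parameter: str
    direction: float                  # signed fraction, e.g. +0.10
    t_statistic: float                # paired across nodes, input-current marker
    p_value: float
    delta_input_current: np.ndarray   # per-node change in <I_E>
    t_statistic_gating: float
    delta_gating_ratio: np.ndarray


_PERTURBABLE = ("G", "w_EE", "w_EI", "w_IE")


def perturb_and_compare(connectome: Connectome, weights: RegionalWeights,
                        G: float, config: SimConfig, parameter: str,
                        direction: float = 0.10,
                        constants: ModelConstants = ModelConstants(),
                        baseline: Optional[SimOutput] = None) -> PerturbationResult:
    """Re-simulate with exactly one parameter scaled by (1 + direction),
    keeping ``w_IE`` frozen (FIC is NOT re-run), and compare both E-I
    markers across nodes with paired t tests.
    """
    if parameter not in _PERTURBABLE:
        raise ValueError(f"parameter must be one of {_PERTURBABLE}")
    if baseline is None:
        baseline = simulate(connectome, weights, G, config,
                            constants=constants, record_bold=False)
    factor = 1.0 + direction
    G_p = G * factor if parameter == "G" else G
    pw = RegionalWeights(
        weights.w_EE * (factor if parameter == "w_EE" else 1.0),
        weights.w_EI * (factor if parameter == "w_EI" else 1.0),
        weights.w_IE * (factor if parameter == "w_IE" else 1.0))
    perturbed = simulate(connectome, pw, G_p, config,
                         constants=constants, record_bold=False)

    def paired_t(after: np.ndarray, before: np.ndarray) -> tuple[float, float]:
        if np.allclose(after, before):
            return 0.0, 1.0
        t, p = stats.ttest_rel(after, before)
        return float(t), float(p)

    d_I = perturbed.mean_I_E - baseline.mean_I_E
    t_I, p_I = paired_t(perturbed.mean_I_E, baseline.mean_I_E)
    base_g = extract_ei(baseline, "gating_ratio").values
    pert_g = extract_ei(perturbed, "gating_ratio").values
    t_g, _ = paired_t(pert_g, base_g)
    return PerturbationResult(parameter=parameter, direction=direction,
                              t_statistic=t_I, p_value=p_I,
                              delta_input_current=d_I,
                              t_statistic_gating=t_g,
                              delta_gating_ratio=pert_g - base_g)


def icc(x: np.ndarray, y: np.ndarray, form: str = "agreement") -> float:
    """Two-way single-measure intraclass correlation between two
    measurements of the same targets.

    ``form='consistency'`` is ICC(3,1) (insensitive to a constant offset
    between measurements); ``form='agreement'`` is ICC(2,1) (absolute
    agreement). Conventional interpretation bands: poor < 0.50, moderate
    0.50-0.75, good >= 0.75.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("icc requires two equal-length 1-d vectors with n >= 3")
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom_c = msr + (k - 1) * mse
    if denom_c == 0:
        raise ValueError("ICC undefined: no variance in either measurement")
    if form == "consistency":
        return float((msr - mse) / denom_c)
    if form == "agreement":
        return float((msr - mse) / (denom_c + k / n * (msc - mse)))
    raise ValueError("form must be 'agreement' or 'consistency'")


@dataclass
class RecoveryReport:
    pearson_r: float
    icc: float
    gof: float
    noise_policy: str
    recovered_ei: EIMap
    true_ei: EIMap
    fit_result: object = None


def recovery_experiment(ground_truth, connectome: Connectome,
                        maps: Optional[MapSet],
                        fit_config, sim_config: SimConfig,
                        noise_policy: str = "same",
                        alt_noise_seed: Optional[int] = None,
                        fic_config: FICConfig = FICConfig(),
                        constants: ModelConstants = ModelConstants(),
                        base_seed: int = 0,
                        variant: str = "map_based") -> RecoveryReport:
    """Fit the model to the FC/FCD of a synthetic ground-truth subject and
    report how well the regional E-I map is recovered.

    ``noise_policy='same'`` evaluates every particle with the same
    Gaussian-noise seed used by the ground-truth simulation;
    ``'different'`` uses ``alt_noise_seed`` instead, mirroring the harder
    variant of the experiment. ``variant`` selects the fitted model's
    parameter layout (map_based / homogeneous / node_based); the ground
    truth only contributes its BOLD and true E-I map, so any variant can
    be fit against any ground truth.
    """
    from .features import WindowSpec
    from .fit import FitProblem, fit_subject, model_variant

    if noise_policy == "same":
        noise_seed = ground_truth.noise_seed
    elif noise_policy == "different":
        if alt_noise_seed is None:
            raise ValueError("alt_noise_seed required for the 'different' policy")
        noise_seed = alt_noise_seed
    else:
        raise ValueError("noise_policy must be 'same' or 'different'")
    space = model_variant(variant, maps=maps, n_nodes=connectome.n_nodes)
    window = WindowSpec.from_seconds(30.0, 6.0, sim_config.TR)
    problem = FitProblem.from_bold(
        connectome, space, ground_truth.bold, window,
        sim_config.with_(noise_seed=noise_seed),
        fic_config=fic_config, constants=constants)
    winner, _runs = fit_subject(problem, fit_config, base_seed=base_seed)
    recovered = extract_ei(winner.optimal_sim,
                           provenance={"theta": winner.best_theta.tolist()})
    true_ei = ground_truth.ei_true
    r = float(np.corrcoef(recovered.values, true_ei.values)[0, 1])
    agreement = icc(recovered.values, true_ei.values, form="agreement")
    return RecoveryReport(pearson_r=r, icc=agreement, gof=winner.best_gof,
                          noise_policy=noise_policy, recovered_ei=recovered,
                          true_ei=true_ei, fit_result=winner)


def seed_sensitivity(connectome: Connectome, weights: RegionalWeights,
                     G: float, config: SimConfig, n_seeds: int,
                     seeds: Optional[np.ndarray] = None,
                     constants: ModelConstants = ModelConstants()) -> dict:
    """Re-simulate an optimal configuration under alternative noise seeds
    and quantify marker stability.

    Returns per-seed ICC (agreement, across nodes) between the default-seed
    E-I map and each alternative-seed map, their median, and the per-seed
    maps themselves.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    base = simulate(connectome, weights, G, config, constants=constants,
                    record_bold=False)
    base_ei = extract_ei(base)
    if seeds is None:
        seeds = [(int(config.noise_seed) + 104729 * (s + 1)) % (2 ** 31)
                 for s in range(n_seeds)]
    iccs, maps_out = [], []
    for s in seeds:
        out = simulate(connectome, weights, G, config.with_(noise_seed=int(s)),
                       constants=constants, record_bold=False)
        alt = extract_ei(out)
        maps_out.append(alt.values)
        if np.allclose(alt.values, base_ei.values):
            iccs.append(1.0)
        else:
            iccs.append(icc(base_ei.values, alt.values, form="agreement"))
    return {"seeds": list(map(int, seeds)), "icc": iccs,
            "median_icc": float(np.median(iccs)),
            "base_ei": base_ei.values, "alt_ei": np.asarray(maps_out)}
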