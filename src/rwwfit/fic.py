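"""Feedback inhibition control (FIC).

Tunes the regional inhibitory-to-excitatory weights ``w_IE`` so that the
excitatory pool of every node sits near the balanced working point of
~3 Hz firing (steady-state gating <S_E> ~ 0.164757, input current
<I_E> ~ 0.37738 nA). Two stages:

1. an analytical solve that assumes all nodes share the common steady
   state and inverts the excitatory current equation for ``w_IE``, with
   the steady-state inhibitory gating obtained by root-finding on the
   inhibitory self-consistency equation;
2. a numerical adjustment: short noisy trial simulations measure
   <I_E> per node, and nodes off target by more than the tolerance get
   ``w_IE`` moved proportionally, up to ``max_trials`` trials.

FIC success is deliberately not a hard constraint at fit time; residual
rate deviations are penalized softly (see :func:`rwwfit.fit.fic_penalty`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .constants import ModelConstants
from .model import Connectome, RegionalWeights, SimConfig, simulate, transfer_rate

__all__ = ["FICConfig", "FICResult", "fic_analytic", "fic_numeric_adjust", "run_fic"]

#: floor used when the adjustment would drive w_IE non-positive
_W_IE_FLOOR = 1e-6


@dataclass(frozen=True)
class FICConfig:
    target_S_E: float = 0.164757     # steady-state excitatory gating
    target_I_E: float = 0.37738      # steady-state excitatory current (nA)
    numeric_target_offset: float = -0.026  # numeric target for <I_E> - b_E (nA)
    tolerance: float = 0.005         # per-node tolerance on <I_E> (nA)
    max_trials: int = 10
    trial_duration: float = 10.0     # s
    gain: float = 5.0                # proportional adjustment gain (nA^-1)
    trust_radius: float = 0.1        # initial per-node cap on a w_IE step
    root_bracket: tuple = (0.0, 2.0)  # bracket for the inhibitory current (nA)

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")

    def validate_against(self, constants: ModelConstants) -> None:
        implied = constants.b_E + self.numeric_target_offset
        if abs(implied - self.target_I_E) > 1e-3:
            raise ValueError("numeric target b_E + offset and target_I_E disagree "
                             f"({implied} vs {self.target_I_E})")


@dataclass
class FICResult:
    w_IE: np.ndarray
    converged: np.ndarray      # per-node bool
    trials_used: int
    mean_I_E_final: np.ndarray
    max_dev_trace: list = None  # max |<I_E> - target| per trial (nA)


def _solve_inhibitory_steady_state(w_EI_i: float, constants: ModelConstants,
                                   config: FICConfig, node: int) -> tuple[float, float]:
    """Solve W_I + w_EI*<S_E> - H_I(I_I)*tau_I - I_I = 0 for <I_I>, then
    <S_I> = H_I(<I_I>)*tau_I. The left side is strictly decreasing in I_I
    over the physical range, so a bracketed root is unique."""
    c, f = constants, config

    def g(I_I: float) -> float:
        return (c.W_I + w_EI_i * f.target_S_E
                - transfer_rate(I_I, "I", c) * c.tau_I - I_I)

    lo, hi = f.root_bracket
    if g(lo) * g(hi) > 0:
        raise ValueError(f"inhibitory steady-state root not bracketed in "
                         f"{f.root_bracket} nA for node {node}")
    I_I = brentq(g, lo, hi, xtol=1e-12)
    S_I = transfer_rate(I_I, "I", c) * c.tau_I
    return I_I, S_I


def fic_analytic(w_EE: np.ndarray, w_EI: np.ndarray, G: float,
                 connectome: Connectome,
                 constants: ModelConstants = ModelConstants(),
                 config: FICConfig = FICConfig(),
                 return_steady_state: bool = False):
    """Analytical w_IE under the common-steady-state assumption.

    Constructed so that substituting the result back into the excitatory
    current equation at the steady state returns exactly ``target_I_E``.
    Non-positive results (infeasible nodes) are returned as-is; the
    numerical stage floors and flags them. With ``return_steady_state``,
    also returns the per-node steady-state inhibitory gating <S_I>.
    """
    config.validate_against(constants)
    w_EE = np.asarray(w_EE, float)
    w_EI = np.asarray(w_EI, float)
    row = connectome.row_sums()
    n = connectome.n_nodes
    S_I = np.empty(n)
    for i in range(n):
        _, S_I[i] = _solve_inhibitory_steady_state(w_EI[i], constants, config, i)
    num = (constants.W_E + w_EE * config.target_S_E
           + G * constants.J_NMDA * row * config.target_S_E - config.target_I_E)
    w_IE = num / S_I
    if return_steady_state:
        return w_IE, S_I
    return w_IE


def fic_numeric_adjust(connectome: Connectome, weights: RegionalWeights,
                       G: float, sim_config: SimConfig,
                       constants: ModelConstants = ModelConstants(),
                       config: FICConfig = FICConfig(),
                       init_S_I: Optional[np.ndarray] = None) -> FICResult:
    """Numerically adjust analytic ``w_IE`` with short trial simulations.

    The numeric target is <I_E> = b_E + numeric_target_offset. Nodes whose
    trial-averaged current is above target get more inhibition
    (w_IE increased), nodes below get less: the step is proportional to
    the deviation but capped by a per-node trust radius that halves
    whenever the deviation changes sign, because the current-to-weight
    sensitivity varies severalfold across dynamical regimes and a fixed
    gain oscillates. Trials reuse the main integrator with noise on,
    start at the analytic common steady state (so the 10 s average is not
    dominated by the onset transient), and use per-trial seeds derived
    deterministically from the configured noise seed.
    """
    n = connectome.n_nodes
    w_IE = np.asarray(weights.w_IE, float).copy()
    infeasible = w_IE <= 0
    w_IE[infeasible] = _W_IE_FLOOR
    target = constants.b_E + config.numeric_target_offset
    trial_cfg = sim_config.with_(duration=config.trial_duration, burn_in=0.0,
                                 TR=sim_config.dt_bold, velocity=None,
                                 global_input_interval=None)
    init_E = np.full(n, config.target_S_E)
    init_I = (np.full(n, config.target_S_E)
              if init_S_I is None else np.asarray(init_S_I, float))
    dev = np.zeros(n)
    trials = 0
    floored = infeasible.copy()
    radius = np.full(n, config.trust_radius)
    prev_sign = np.zeros(n)
    trace = []
    for trial in range(config.max_trials):
        seed = (int(sim_config.noise_seed) + 7919 * (trial + 1)) % (2 ** 31)
        out = simulate(connectome,
                       RegionalWeights(weights.w_EE, weights.w_EI, w_IE),
                       G, trial_cfg.with_(noise_seed=seed),
                       constants=constants, record_bold=False,
                       init_S_E=init_E, init_S_I=init_I)
        dev = out.mean_I_E - target
        trials = trial + 1
        trace.append(float(np.abs(dev).max()))
        within = np.abs(dev) <= config.tolerance
        if within.all():
            break
        sign = np.sign(dev)
        flipped = (prev_sign != 0) & (sign != prev_sign)
        radius[flipped] /= 2.0
        prev_sign = sign
        adj = ~within
        w_IE[adj] += np.clip(config.gain * dev[adj], -radius[adj], radius[adj])
        drove_neg = w_IE <= 0
        w_IE[drove_neg] = _W_IE_FLOOR
        floored |= drove_neg
    converged = (np.abs(dev) <= config.tolerance) & ~floored
    return FICResult(w_IE=w_IE, converged=converged, trials_used=trials,
                     mean_I_E_final=dev + target, max_dev_trace=trace)


def run_fic(connectome: Connectome, weights: RegionalWeights, G: float,
            sim_config: SimConfig,
            constants: ModelConstants = ModelConstants(),
            config: FICConfig = FICConfig()) -> tuple[RegionalWeights, FICResult]:
    """Two-stage FIC: analytic solve then numeric adjustment. Returns the
    completed weights (with w_IE) and the FIC diagnostics."""
    w_IE0, S_I0 = fic_analytic(weights.w_EE, weights.w_EI, G, connectome,
                               constants, config, return_steady_state=True)
    res = fic_numeric_adjust(
        connectome, RegionalWeights(weights.w_EE, weights.w_EI, w_IE0),
        G, sim_config, constants, config, init_S_I=S_I0)
    return RegionalWeights(weights.w_EE, weights.w_EI, res.w_IE), res
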