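"""Core types and numerical integration of the reduced Wong-Wang network.

Each cortical parcel is a two-pool (excitatory/inhibitory) neural mass;
excitatory pools are coupled between parcels through a structural
connectome scaled by a global coupling G and the NMDA conductance. The
regional recurrent weights ``w_EE`` and excitatory-to-inhibitory weights
``w_EI`` are parameterized as a bias times one plus a linear combination
of fixed z-scored regional heterogeneity maps; the inhibitory-to-excitatory
weights ``w_IE`` are set by feedback inhibition control (see
:mod:`rwwfit.fic`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .constants import HemoConstants, ModelConstants
from .hemo import bold_forward

__all__ = [
    "Connectome", "MapSet", "FreeParams", "RegionalWeights", "SimConfig",
    "SimOutput", "SimulationError", "coefficient_bounds",
    "expand_regional_params", "transfer_rate", "simulate",
    "simulate_with_delay", "MIN_REGIONAL_WEIGHT",
]

#: Floor applied to regional w_EE / w_EI after map expansion.
MIN_REGIONAL_WEIGHT = 1e-3

#: Default bounds of the scalar free parameters.
G_BOUNDS = (0.5, 4.0)
WB_BOUNDS = (0.05, 0.75)


class SimulationError(RuntimeError):
    """Raised when the numerical integration blows up."""


@dataclass
class Connectome:
    """Structural connectome: nonnegative coupling weights, optional
    streamline lengths (mm) and per-node hemisphere labels ('L'/'R')."""

    weights: np.ndarray
    lengths: Optional[np.ndarray] = None
    hemisphere: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).copy()
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("connectome weights must be a square matrix")
        if np.any(self.weights < 0):
            raise ValueError("connectome weights must be nonnegative")
        # self-excitation is carried by w_EE, not by the network term
        np.fill_diagonal(self.weights, 0.0)
        if self.lengths is not None:
            self.lengths = np.asarray(self.lengths, dtype=float)
            if self.lengths.shape != self.weights.shape:
                raise ValueError("lengths must match weights in shape")
            if np.any(self.lengths < 0):
                raise ValueError("lengths must be nonnegative")
            if not np.allclose(self.lengths, self.lengths.T):
                raise ValueError("lengths must be symmetric")
        if self.hemisphere is not None:
            self.hemisphere = np.asarray(self.hemisphere)
            if self.hemisphere.shape != (self.n_nodes,):
                raise ValueError("hemisphere labels must have one entry per node")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def row_sums(self) -> np.ndarray:
        return self.weights.sum(axis=1)


@dataclass
class MapSet:
    """k fixed regional heterogeneity maps, z-scored across nodes."""

    maps: np.ndarray
    names: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        k, n = self.maps.shape
        if self.names is None:
            self.names = [f"map{i + 1}" for i in range(k)]
        if len(self.names) != k:
            raise ValueError("one name per map required")
        mu = self.maps.mean(axis=1)
        sd = self.maps.std(axis=1)
        if np.any(np.abs(mu) > 1e-9) or np.any(np.abs(sd - 1.0) > 1e-9):
            raise ValueError("maps must be z-scored (mean 0, sd 1) across nodes")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.maps.shape[1]

    @classmethod
    def from_raw(cls, raw: np.ndarray, names: Optional[Sequence[str]] = None) -> "MapSet":
        """Z-score raw maps across nodes."""
        raw = np.atleast_2d(np.asarray(raw, dtype=float))
        sd = raw.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("constant map cannot be z-scored")
        return cls((raw - raw.mean(axis=1, keepdims=True)) / sd, names)


def coefficient_bounds(map_values: np.ndarray) -> tuple[float, float]:
    """Bounds [-1/max(map), -1/min(map)] for one map coefficient.

    Inside these bounds, 1 + c*M stays positive at the extreme nodes, so
    the expanded regional weight keeps the sign of its bias term.
    """
    m = np.asarray(map_values, dtype=float)
    hi, lo = m.max(), m.min()
    if hi <= 0 or lo >= 0:
        raise ValueError("coefficient bounds require a map with positive max and negative min")
    return (-1.0 / hi, -1.0 / lo)


@dataclass
class FreeParams:
    """The free-parameter vector: global coupling G, two bias terms, and
    one coefficient per map for each of w_EE and w_EI (1 + 2 + 2k values)."""

    G: float
    wb_EE: float
    wb_EI: float
    c_EE: np.ndarray
    c_EI: np.ndarray
    bounds: Optional[np.ndarray] = None  # (dim, 2)

    def __post_init__(self) -> None:
        self.c_EE = np.atleast_1d(np.asarray(self.c_EE, dtype=float))
        self.c_EI = np.atleast_1d(np.asarray(self.c_EI, dtype=float))
        if self.c_EE.shape != self.c_EI.shape:
            raise ValueError("c_EE and c_EI must have the same length")
        if self.bounds is not None:
            self.bounds = np.asarray(self.bounds, dtype=float)
            if self.bounds.shape != (self.dim, 2):
                raise ValueError("bounds must be (dim, 2)")

    @property
    def k(self) -> int:
        return self.c_EE.size

    @property
    def dim(self) -> int:
        return 3 + 2 * self.k

    def to_vector(self) -> np.ndarray:
        return np.concatenate(([self.G, self.wb_EE, self.wb_EI], self.c_EE, self.c_EI))

    @classmethod
    def from_vector(cls, v: np.ndarray, k: int,
                    bounds: Optional[np.ndarray] = None) -> "FreeParams":
        v = np.asarray(v, dtype=float)
        if v.size != 3 + 2 * k:
            raise ValueError(f"expected {3 + 2 * k} parameters, got {v.size}")
        return cls(v[0], v[1], v[2], v[3:3 + k], v[3 + k:], bounds)

    @classmethod
    def default_bounds(cls, maps: MapSet) -> np.ndarray:
        """Per-component [lo, hi]: G in [0.5, 4], biases in [0.05, 0.75],
        map coefficients from :func:`coefficient_bounds`."""
        rows = [G_BOUNDS, WB_BOUNDS, WB_BOUNDS]
        cb = [coefficient_bounds(m) for m in maps.maps]
        rows.extend(cb)   # c_EE
        rows.extend(cb)   # c_EI
        return np.asarray(rows, dtype=float)


@dataclass
class RegionalWeights:
    """Per-node local connection weights; ``w_IE`` is filled in by FIC."""

    w_EE: np.ndarray
    w_EI: np.ndarray
    w_IE: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.w_EE = np.asarray(self.w_EE, dtype=float)
        self.w_EI = np.asarray(self.w_EI, dtype=float)
        if self.w_IE is not None:
            self.w_IE = np.asarray(self.w_IE, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.w_EE.size


def _shift_to_floor(w: np.ndarray, floor: float = MIN_REGIONAL_WEIGHT) -> np.ndarray:
    """Shift a whole weight vector upward so its minimum equals the floor,
    preserving all pairwise differences; no-op if already above the floor."""
    lo = w.min()
    if lo < floor:
        return w + (floor - lo)
    return w


def expand_regional_params(theta: FreeParams, maps: MapSet) -> RegionalWeights:
    """Map-based expansion w_p = wb_p * (1 + sum_k c_k M_k), p in {EE, EI},
    followed by the min-shift rule (minimum regional weight 0.001)."""
    if theta.k != maps.k:
        raise ValueError(f"theta has {theta.k} coefficients per weight but "
                         f"{maps.k} maps were provided")
    base = np.ones(maps.n_nodes)
    w_EE = theta.wb_EE * (base + theta.c_EE @ maps.maps)
    w_EI = theta.wb_EI * (base + theta.c_EI @ maps.maps)
    return RegionalWeights(_shift_to_floor(w_EE), _shift_to_floor(w_EI))


def transfer_rate(I, population: str, constants: ModelConstants = ModelConstants()):
    """Sigmoidal transfer H(I) = x / (1 - exp(-d x)), x = a*(I - b), in Hz.

    The removable singularity at x = 0 evaluates to 1/d. Accepts scalars
    or arrays.
    """
    if population == "E":
        a, b, d = constants.a_E, constants.b_E, constants.d_E
    elif population == "I":
        a, b, d = constants.a_I, constants.b_I, constants.d_I
    else:
        raise ValueError("population must be 'E' or 'I'")
    x = a * (np.asarray(I, dtype=float) - b)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        r = np.where(np.abs(x) < 1e-8, 1.0 / d, x / (1.0 - np.exp(-d * x)))
    return float(r) if np.isscalar(I) else r


@dataclass
class SimConfig:
    """Integration settings.

    ``global_input_interval`` is how often the network input is refreshed:
    every neuronal step (0.1 ms) by default, every 1 ms when conduction
    delays are simulated. ``TR`` must be a positive multiple of ``dt_bold``.
    """

    TR: float = 3.0
    duration: float = 450.0
    burn_in: float = 30.0
    dt_neuronal: float = 1e-4
    dt_bold: float = 1e-3
    noise_seed: int = 0
    velocity: Optional[float] = None      # conduction velocity (m/s)
    global_input_interval: Optional[float] = None
    s_init: float = 0.001

    def __post_init__(self) -> None:
        if self.duration <= self.burn_in:
            raise ValueError("duration must exceed burn_in")
        if self.TR <= 0 or abs(self.TR / self.dt_bold - round(self.TR / self.dt_bold)) > 1e-9:
            raise ValueError("TR must be a positive multiple of dt_bold")
        if abs(self.dt_bold / self.dt_neuronal - round(self.dt_bold / self.dt_neuronal)) > 1e-9:
            raise ValueError("dt_bold must be a multiple of dt_neuronal")
        if self.global_input_interval is None:
            self.global_input_interval = 1e-3 if self.velocity is not None else self.dt_neuronal
        gi = self.global_input_interval / self.dt_neuronal
        if abs(gi - round(gi)) > 1e-9 or gi < 1:
            raise ValueError("global_input_interval must be a positive multiple of dt_neuronal")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt_neuronal))

    @property
    def burn_steps(self) -> int:
        return int(round(self.burn_in / self.dt_neuronal))

    @property
    def n_volumes(self) -> int:
        return int(np.floor((self.duration - self.burn_in) / self.TR))

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimOutput:
    """Post-burn-in state averages and the simulated BOLD matrix."""

    mean_I_E: np.ndarray
    mean_r_E: np.ndarray
    mean_S_E: np.ndarray
    mean_S_I: np.ndarray
    bold: Optional[np.ndarray]
    seeds_used: dict = field(default_factory=dict)


def _check_complete(weights: RegionalWeights, n: int) -> None:
    for name in ("w_EE", "w_EI", "w_IE"):
        v = getattr(weights, name)
        if v is None:
            raise ValueError(f"weights.{name} must be set before simulation (run FIC for w_IE)")
        if v.shape != (n,):
            raise ValueError(f"weights.{name} must have length {n}")


def _run(connectome: Connectome, weights: RegionalWeights, G: float,
         config: SimConfig, constants: ModelConstants,
         delays: Optional[np.ndarray], record_bold: bool,
         hemo: HemoConstants,
         init_S_E: Optional[np.ndarray] = None,
         init_S_I: Optional[np.ndarray] = None) -> SimOutput:
    n = connectome.n_nodes
    _check_complete(weights, n)
    gi_steps = int(round(config.global_input_interval / config.dt_neuronal))
    rec_stride = int(round(config.dt_bold / config.dt_neuronal)) if record_bold else 0
    D = np.zeros((n, n), dtype=np.int64) if delays is None else delays
    S_E0 = np.full(n, config.s_init) if init_S_E is None else np.asarray(init_S_E, float)
    S_I0 = np.full(n, config.s_init) if init_S_I is None else np.asarray(init_S_I, float)
    se_rec, mIE, mrE, mSE, mSI, ok = _kernels.integrate_neuronal(
        np.ascontiguousarray(connectome.weights), np.ascontiguousarray(D),
        gi_steps,
        np.ascontiguousarray(weights.w_EE), np.ascontiguousarray(weights.w_EI),
        np.ascontiguousarray(weights.w_IE),
        float(G), config.dt_neuronal, config.n_steps, config.burn_steps,
        rec_stride, np.ascontiguousarray(S_E0), np.ascontiguousarray(S_I0),
        constants.sigma_noise, int(config.noise_seed),
        constants.W_E, constants.W_I, constants.J_NMDA, constants.w_II,
        constants.a_E, constants.b_E, constants.d_E,
        constants.a_I, constants.b_I, constants.d_I,
        constants.tau_E, constants.tau_I, constants.gamma_kin,
    )
    if not ok:
        raise SimulationError("neuronal integration produced non-finite state "
                              f"(G={G}, seed={config.noise_seed})")
    bold = None
    if record_bold:
        bold = bold_forward(se_rec, hemo, TR=config.TR, burn_in=config.burn_in,
                            dt_bold=config.dt_bold)
    return SimOutput(mIE, mrE, mSE, mSI, bold,
                     seeds_used={"noise_seed": int(config.noise_seed)})


def simulate(connectome: Connectome, weights: RegionalWeights, G: float,
             config: SimConfig,
             constants: ModelConstants = ModelConstants(),
             hemo: HemoConstants = HemoConstants(),
             record_bold: bool = True,
             init_S_E: Optional[np.ndarray] = None,
             init_S_I: Optional[np.ndarray] = None) -> SimOutput:
    """Integrate the network for ``config.duration`` seconds.

    Deterministic given (inputs, ``config.noise_seed``): repeated calls are
    bit-identical. State averages and BOLD volumes exclude the first
    ``config.burn_in`` seconds. Initial gating defaults to ``config.s_init``
    at every node; per-node initial conditions may be supplied (used by the
    FIC trial simulations, which start at the analytic steady state).
    """
    return _run(connectome, weights, G, config, constants, None, record_bold,
                hemo, init_S_E, init_S_I)


def delay_matrix(connectome: Connectome, velocity: float,
                 interval: float) -> np.ndarray:
    """Integer delays in global-input intervals: round(length / velocity /
    interval), with zero allowed (a zero delay uses the current update)."""
    if velocity is None or velocity <= 0:
        raise ValueError("conduction velocity must be positive")
    if connectome.lengths is None:
        raise ValueError("connectome has no streamline lengths; delays undefined")
    # lengths in mm, velocity in m/s -> delay in s = (mm * 1e-3) / (m/s)
    delay_s = connectome.lengths * 1e-3 / velocity
    return np.round(delay_s / interval).astype(np.int64)


def simulate_with_delay(connectome: Connectome, weights: RegionalWeights,
                        G: float, config: SimConfig,
                        constants: ModelConstants = ModelConstants(),
                        hemo: HemoConstants = HemoConstants(),
                        record_bold: bool = True) -> SimOutput:
    """Like :func:`simulate` but node j's contribution to node i uses the
    excitatory gating of j at t - length_ij / velocity, rounded to the
    global-input interval (1 ms by default when a velocity is set)."""
    if config.velocity is None:
        raise ValueError("config.velocity must be set for delayed simulation")
    D = delay_matrix(connectome, config.velocity, config.global_input_interval)
    return _run(connectome, weights, G, config, constants, D, record_bold, hemo)
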