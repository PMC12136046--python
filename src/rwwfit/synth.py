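"""Synthetic study inputs: connectomes, heterogeneity maps, ground truths.

Emulates the three empirical inputs of the pipeline so every stage is
testable without imaging data: (i) a tractography-like structural
connectome with hemispheric block structure, log-normal weights and
exponential distance decay, normalized to a mean weight of 0.01; (ii)
spatially smooth z-scored regional maps (low-order harmonics of node
position on two hemispheric rings plus noise); (iii) "empirical" BOLD
produced by the package's own forward model from known parameters
(closure property), plus a Bernoulli motion-scrubbing mask.

The synthetic maps are independent across k; real heterogeneity maps are
mutually correlated, which this generator does not attempt to mimic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .constants import ModelConstants
from .ei import EIMap, extract_ei
from .fic import FICConfig, run_fic
from .io import normalize_sc
from .model import (Connectome, FreeParams, MapSet, RegionalWeights, SimConfig,
                    SimOutput, expand_regional_params, simulate)

__all__ = ["SynthSpec", "GroundTruth", "make_connectome", "make_maps",
           "make_ground_truth", "make_scrub_mask", "default_theta"]


@dataclass
class SynthSpec:
    """Desk-scale defaults: 10 nodes split over two hemispheres."""

    n_nodes: int = 10
    n_left: Optional[int] = None          # default: n_nodes // 2
    density: float = 0.7                  # fraction of nonzero edges
    weight_sigma: float = 0.6             # log-normal sigma of raw weights
    distance_decay: float = 75.0          # e-folding length of weights (mm)
    intra_hemi_boost: float = 2.0         # intra- vs interhemispheric weight ratio
    ring_radius: float = 40.0             # hemisphere ring radius (mm)
    hemisphere_gap: float = 30.0          # gap between ring centers (mm)
    k_maps: int = 6
    map_noise: float = 0.3                # sd of white noise added to harmonics
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValueError("need at least 4 nodes")
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if self.n_left is None:
            self.n_left = self.n_nodes // 2


def _node_geometry(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    """Node coordinates on two rings (one per hemisphere) and labels."""
    n_l = spec.n_left
    n_r = spec.n_nodes - n_l
    coords = np.zeros((spec.n_nodes, 2))
    labels = np.empty(spec.n_nodes, dtype="<U1")
    for idx, (count, side) in enumerate([(n_l, -1.0), (n_r, 1.0)]):
        ang = 2 * np.pi * np.arange(count) / max(count, 1)
        off = idx * n_l
        coords[off:off + count, 0] = side * (spec.hemisphere_gap / 2
                                             + spec.ring_radius) \
            + spec.ring_radius * np.cos(ang)
        coords[off:off + count, 1] = spec.ring_radius * np.sin(ang)
        labels[off:off + count] = "L" if side < 0 else "R"
    return coords, labels


def make_connectome(spec: SynthSpec = SynthSpec()) -> Connectome:
    """Synthetic structural connectome; mean weight exactly 0.01.

    Regenerates (with a warning) up to 5 times if the sampled graph is
    disconnected at the requested density.
    """
    coords, labels = _node_geometry(spec)
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    n = spec.n_nodes
    for attempt in range(5):
        rng = np.random.default_rng((spec.seed + 1000003 * attempt) % 2 ** 31)
        logw = rng.normal(0.0, spec.weight_sigma, size=(n, n))
        W = np.exp(logw) * np.exp(-dist / spec.distance_decay)
        same = labels[:, None] == labels[None, :]
        W[same] *= spec.intra_hemi_boost
        W = np.triu(W, k=1)
        if spec.density < 1:
            keep = rng.random((n, n)) < spec.density
            W *= np.triu(keep, k=1)
        W = W + W.T
        ncomp, _ = connected_components(csr_matrix(W > 0), directed=False)
        if ncomp == 1:
            W = normalize_sc(W)
            return Connectome(weights=W, lengths=dist, hemisphere=labels)
        import warnings
        warnings.warn(f"synthetic graph disconnected at density={spec.density}; "
                      f"regenerating (attempt {attempt + 1})")
    raise RuntimeError("could not sample a connected graph in 5 attempts; "
                       "increase density")


def make_maps(spec: SynthSpec = SynthSpec()) -> MapSet:
    """k spatially smooth z-scored maps: low-order harmonics of the ring
    angle per hemisphere plus Gaussian noise, z-scored across nodes."""
    if spec.k_maps < 1:
        raise ValueError("k_maps must be >= 1")
    coords, labels = _node_geometry(spec)
    rng = np.random.default_rng((spec.seed + 17) % 2 ** 31)
    theta = np.arctan2(coords[:, 1],
                       coords[:, 0] - np.sign(coords[:, 0])
                       * (spec.hemisphere_gap / 2 + spec.ring_radius))
    raw = np.zeros((spec.k_maps, spec.n_nodes))
    for k in range(spec.k_maps):
        # first harmonic dominates: on rings of only a handful of nodes,
        # higher harmonics alternate sign between neighbors (not smooth)
        phase = rng.uniform(0, 2 * np.pi)
        amp2 = rng.uniform(0.1, 0.3)
        raw[k] = (np.cos(theta + phase)
                  + amp2 * np.cos(2 * theta + rng.uniform(0, 2 * np.pi))
                  + rng.normal(0, spec.map_noise, spec.n_nodes))
    return MapSet.from_raw(raw, names=[f"synthmap{k + 1}" for k in range(spec.k_maps)])


def default_theta(maps: MapSet, seed: int = 0) -> FreeParams:
    """A ground-truth parameter vector in the dynamically balanced regime.

    Moderate global coupling, drive-to-inhibition bias at or above the
    recurrent-excitation bias, and the two coefficient vectors sharing
    one spatial pattern with a small jitter so the per-node w_EE/w_EI
    ratio stays nearly uniform. Strongly discordant per-node ratios (or
    a large uniform ratio at high G) make the 3 Hz balanced state
    bistable or unstable -- feedback inhibition control cannot converge
    there, which is legitimate for candidate particles during fitting
    but useless as a ground truth.
    """
    bounds = FreeParams.default_bounds(maps)
    rng = np.random.default_rng(seed)
    k = maps.k
    lo, hi = bounds[3:3 + k, 0], bounds[3:3 + k, 1]
    span = np.minimum(np.abs(lo), np.abs(hi))
    c_EE = 0.4 * span * rng.uniform(-1, 1, k)
    c_EI = np.clip(c_EE + 0.1 * span * rng.uniform(-1, 1, k), lo, hi)
    v = np.concatenate([[1.2, 0.40, 0.45], np.clip(c_EE, lo, hi), c_EI])
    return FreeParams.from_vector(v, k, bounds)


@dataclass
class GroundTruth:
    theta_true: object                     # FreeParams (or raw vector for
    weights_true: RegionalWeights          # the homogeneous variant); post-FIC
    ei_true: EIMap
    bold: np.ndarray
    noise_seed: int
    sim: SimOutput = None
    scrub_mask: Optional[np.ndarray] = None


def make_ground_truth(connectome: Connectome, maps: MapSet,
                      theta_true: Optional[FreeParams] = None,
                      sim_config: SimConfig = SimConfig(),
                      fic_config: FICConfig = FICConfig(),
                      constants: ModelConstants = ModelConstants(),
                      seed: int = 0) -> GroundTruth:
    """Forward-simulate a synthetic "empirical" subject with known
    parameters: expand regional weights, run FIC, simulate BOLD, and store
    the true E-I map."""
    if theta_true is None:
        theta_true = default_theta(maps, seed=seed)
    weights = expand_regional_params(theta_true, maps)
    try:
        weights, fic_res = run_fic(connectome, weights, theta_true.G,
                                   sim_config, constants, fic_config)
    except ValueError as exc:
        raise ValueError(f"FIC infeasible for the chosen ground-truth "
                         f"parameters ({exc}); pick a different theta") from exc
    sim = simulate(connectome, weights, theta_true.G, sim_config,
                   constants=constants)
    ei_true = extract_ei(sim, provenance={"theta": theta_true.to_vector().tolist(),
                                          "role": "ground_truth"})
    return GroundTruth(theta_true=theta_true, weights_true=weights,
                       ei_true=ei_true, bold=sim.bold,
                       noise_seed=int(sim_config.noise_seed), sim=sim)


def make_homogeneous_ground_truth(connectome: Connectome, G: float,
                                  w_EE: float, w_EI: float,
                                  sim_config: SimConfig = SimConfig(),
                                  fic_config: FICConfig = FICConfig(),
                                  constants: ModelConstants = ModelConstants()
                                  ) -> GroundTruth:
    """Ground truth for the three-parameter homogeneous model variant:
    uniform regional weights, FIC, forward simulation."""
    n = connectome.n_nodes
    weights = RegionalWeights(np.full(n, w_EE), np.full(n, w_EI))
    weights, _res = run_fic(connectome, weights, G, sim_config, constants,
                            fic_config)
    sim = simulate(connectome, weights, G, sim_config, constants=constants)
    ei_true = extract_ei(sim, provenance={"theta": [G, w_EE, w_EI],
                                          "role": "ground_truth"})
    return GroundTruth(theta_true=np.array([G, w_EE, w_EI]),
                       weights_true=weights, ei_true=ei_true, bold=sim.bold,
                       noise_seed=int(sim_config.noise_seed), sim=sim)


def make_scrub_mask(T: int, outlier_rate: float, seed: int = 0) -> np.ndarray:
    """Bernoulli per-volume outlier mask (True = motion outlier)."""
    if not (0 <= outlier_rate < 1):
        raise ValueError("outlier_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    return rng.random(T) < outlier_rate
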