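"""Fixed biophysical constants of the neural-mass and hemodynamic models.

The neural-mass constants parameterize the reduced Wong-Wang dynamic
mean-field model of coupled excitatory (NMDA-gated) and inhibitory
(GABA-gated) neuronal pools; the hemodynamic constants parameterize the
Balloon-Windkessel forward model with 3-T BOLD coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


def _check_positive(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if not (v > 0):
            raise ValueError(f"{type(obj).__name__}.{f.name} must be strictly positive, got {v!r}")


@dataclass(frozen=True)
class ModelConstants:
    """Fixed parameters of the two-pool neural mass.

    Units: currents in nA, rates in Hz, times in s; the transfer slopes
    ``a_E``/``a_I`` are in nC^-1 so that ``a*(I - b)`` is a rate.
    """

    W_E: float = 0.382        # baseline input current to the excitatory pool (nA)
    W_I: float = 0.267        # baseline input current to the inhibitory pool (nA)
    J_NMDA: float = 0.15      # NMDA conductance scaling the network input (nA)
    w_II: float = 1.0         # recurrent inhibitory connection weight
    a_E: float = 310.0        # excitatory transfer slope (nC^-1)
    a_I: float = 615.0        # inhibitory transfer slope (nC^-1)
    b_E: float = 0.403        # excitatory transfer threshold (nA)
    b_I: float = 0.288        # inhibitory transfer threshold (nA)
    d_E: float = 0.16         # excitatory transfer curvature
    d_I: float = 0.087        # inhibitory transfer curvature
    tau_E: float = 0.1        # NMDA gating decay time constant (s)
    tau_I: float = 0.01       # GABA gating decay time constant (s)
    gamma_kin: float = 0.641  # kinetic factor of the excitatory gating equation
    sigma_noise: float = 0.01  # amplitude of the Gaussian noise term (nA)

    def __post_init__(self) -> None:
        _check_positive(self)


@dataclass(frozen=True)
class HemoConstants:
    """Balloon-Windkessel parameters with dimensionless 3-T BOLD coefficients."""

    kappa: float = 10.65      # rate of vasodilatory signal decay (s^-1)
    gamma_hemo: float = 10.41  # rate of flow-dependent elimination (s^-1)
    tau_hemo: float = 0.98    # hemodynamic transit time (s)
    alpha_grubb: float = 0.32  # Grubb's exponent
    rho: float = 0.34         # resting oxygen extraction fraction
    V0: float = 0.02          # resting blood volume fraction
    k1: float = 3.72
    k2: float = 0.527
    k3: float = 0.53

    def __post_init__(self) -> None:
        _check_positive(self)
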