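"""Balloon-Windkessel hemodynamic forward model.

Converts the excitatory synaptic gating variable of each node into a
BOLD signal through four state variables per node -- vasodilatory signal
x, blood inflow f, blood volume v and deoxyhemoglobin content q --
integrated with the Euler method at ``dt_bold`` and read out at the
repetition time TR. The resting fixed point (x, f, v, q) = (0, 1, 1, 1)
yields identically zero BOLD.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .constants import HemoConstants

__all__ = ["bold_forward", "HemoError"]


class HemoError(RuntimeError):
    """Raised when the hemodynamic integration leaves the physical regime."""


def bold_forward(s_e_series: np.ndarray,
                 constants: HemoConstants = HemoConstants(),
                 TR: float = 3.0, burn_in: float = 0.0,
                 dt_bold: float = 1e-3) -> np.ndarray:
    """Integrate the hemodynamic states driven by ``s_e_series`` (n x T,
    sampled at ``dt_bold``) and return BOLD volumes (n x T_vol).

    Volume k is read out at biological time (k+1)*TR; volumes at or before
    ``burn_in`` seconds are discarded.
    """
    s_e_series = np.ascontiguousarray(np.atleast_2d(s_e_series), dtype=float)
    tr_stride = int(round(TR / dt_bold))
    if tr_stride < 1 or abs(TR / dt_bold - tr_stride) > 1e-9:
        raise ValueError("TR must be a positive multiple of dt_bold")
    bold, ok = _kernels.integrate_bold(
        s_e_series, dt_bold, tr_stride,
        constants.kappa, constants.gamma_hemo, constants.tau_hemo,
        1.0 / constants.alpha_grubb, constants.rho, constants.V0,
        constants.k1, constants.k2, constants.k3,
    )
    if not ok:
        raise HemoError("hemodynamic state left the physical regime "
                        "(non-positive blood flow or volume)")
    # volume k is at time (k+1)*TR; keep volumes strictly after burn_in
    first = 0
    while (first + 1) * TR <= burn_in + 1e-12:
        first += 1
    return bold[:, first:]
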