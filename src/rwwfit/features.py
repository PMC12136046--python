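"""Static FC, functional connectivity dynamics (FCD), and goodness of fit.

The fit of a simulated to an empirical BOLD dataset is scored by three
summary comparisons combined as

    gof = FC_corr - FC_diff - FCD_KS

where FC_corr is the Pearson correlation between the lower triangles of
the two static FC matrices, FC_diff the absolute difference of their mean
lower-triangular values, and FCD_KS the two-sample Kolmogorov-Smirnov
distance between the lower-triangular value distributions of the two FCD
matrices. Interhemispheric edges are excluded from the static FC terms by
default (and, optionally, from the window vectors entering FCD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import ks_2samp

__all__ = ["WindowSpec", "GofBreakdown", "compute_fc", "compute_fcd",
           "ks_distance", "goodness_of_fit", "intrahemispheric_edge_mask"]


@dataclass
class WindowSpec:
    """Sliding-window tiling for FCD, with edge-window and motion-outlier
    discard rules (windows with >= ``max_outlier_frac`` flagged volumes
    are dropped)."""

    window_len_TR: int
    step_TR: int
    drop_edge_windows: bool = True
    max_outlier_frac: float = 0.5

    def __post_init__(self) -> None:
        self.window_len_TR = int(self.window_len_TR)
        self.step_TR = int(self.step_TR)
        if self.window_len_TR < 2:
            raise ValueError("window length must be >= 2 TRs")
        if self.step_TR < 1:
            raise ValueError("window step must be >= 1 TR")

    @classmethod
    def from_seconds(cls, window_len_s: float, step_s: float, TR: float,
                     **kw) -> "WindowSpec":
        """Convert second-based window settings to TR counts by rounding
        (e.g. 30 s / 3 s TR -> 10 TRs, 30.8 s / 2.2 s TR -> 14 TRs)."""
        return cls(int(round(window_len_s / TR)), int(round(step_s / TR)), **kw)

    def window_starts(self, T: int) -> np.ndarray:
        starts = np.arange(0, T - self.window_len_TR + 1, self.step_TR)
        if self.drop_edge_windows and starts.size >= 2:
            starts = starts[1:-1]
        return starts


@dataclass
class GofBreakdown:
    fc_corr: float
    fc_diff: float
    fcd_ks: float
    gof: float
    edge_mask: Optional[np.ndarray] = None
    penalties: dict = field(default_factory=dict)

    @property
    def cost(self) -> float:
        return -self.gof + sum(self.penalties.values())


def compute_fc(bold: np.ndarray, valid_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Pearson-correlation FC of an n x T BOLD matrix.

    Volumes flagged invalid in ``valid_mask`` (True = valid) are excluded.
    Zero-variance nodes get their FC row/column set to 0 (diagonal stays 1)
    with a warning.
    """
    bold = np.atleast_2d(np.asarray(bold, dtype=float))
    if valid_mask is not None:
        valid_mask = np.asarray(valid_mask, dtype=bool)
        if valid_mask.shape != (bold.shape[1],):
            raise ValueError("valid_mask must have one entry per volume")
        bold = bold[:, valid_mask]
    if bold.shape[1] < 3:
        raise ValueError("need at least 3 valid volumes to compute FC")
    sd = bold.std(axis=1)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance node(s); FC rows set to 0")
    with np.errstate(invalid="ignore"):
        fc = np.corrcoef(bold)
    fc = np.atleast_2d(fc)
    if dead.any():
        fc[dead, :] = 0.0
        fc[:, dead] = 0.0
    np.fill_diagonal(fc, 1.0)
    return fc


def intrahemispheric_edge_mask(hemisphere: np.ndarray) -> np.ndarray:
    """Boolean n x n mask of edges joining nodes of the same hemisphere."""
    h = np.asarray(hemisphere)
    return h[:, None] == h[None, :]


def _tril_values(mat: np.ndarray, edge_mask: Optional[np.ndarray] = None) -> np.ndarray:
    n = mat.shape[0]
    rows, cols = np.tril_indices(n, k=-1)
    vals = mat[rows, cols]
    if edge_mask is not None:
        vals = vals[edge_mask[rows, cols]]
    return vals


def compute_fcd(bold: np.ndarray, spec: WindowSpec,
                outlier_mask: Optional[np.ndarray] = None,
                edge_mask: Optional[np.ndarray] = None) -> tuple[np.ndarray, np.ndarray]:
    """FCD matrix: correlations between vectorized lower-triangular FC
    patterns of sliding windows.

    ``outlier_mask`` flags invalid volumes (True = outlier); windows with
    at least ``spec.max_outlier_frac`` outliers are discarded, and within
    kept windows only valid volumes enter the window FC. Returns
    (FCD, kept window start indices).
    """
    bold = np.atleast_2d(np.asarray(bold, dtype=float))
    n, T = bold.shape
    if outlier_mask is not None:
        outlier_mask = np.asarray(outlier_mask, dtype=bool)
        if outlier_mask.shape != (T,):
            raise ValueError("outlier_mask must have one entry per volume")
    starts = spec.window_starts(T)
    kept, vectors = [], []
    for s in starts:
        sl = slice(s, s + spec.window_len_TR)
        if outlier_mask is not None:
            frac = outlier_mask[sl].mean()
            if frac >= spec.max_outlier_frac:
                continue
            valid = ~outlier_mask[sl]
        else:
            valid = None
        win_fc = compute_fc(bold[:, sl], valid_mask=valid)
        vectors.append(_tril_values(win_fc, edge_mask))
        kept.append(s)
    if len(kept) < 2:
        raise ValueError("fewer than 2 windows survive the tiling/discard rules "
                         f"(T={T}, window={spec.window_len_TR} TR, "
                         f"step={spec.step_TR} TR, edge drop={spec.drop_edge_windows})")
    fcd = np.corrcoef(np.asarray(vectors))
    np.fill_diagonal(fcd, 1.0)
    return fcd, np.asarray(kept)


def ks_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic sup|ECDF_a - ECDF_b|."""
    return float(ks_2samp(np.ravel(a), np.ravel(b), method="asymp").statistic)


def goodness_of_fit(sim_fc: np.ndarray, sim_fcd: np.ndarray,
                    emp_fc: np.ndarray, emp_fcd: np.ndarray,
                    hemisphere: Optional[np.ndarray] = None,
                    include_interhemispheric: bool = False) -> GofBreakdown:
    """Combined goodness of fit FC_corr - FC_diff - FCD_KS.

    When hemisphere labels are given and ``include_interhemispheric`` is
    False, interhemispheric edges are excluded from the static FC terms.
    The FCD matrices are compared through their pooled lower-triangular
    value distributions (window-FC edge masking, if any, happens upstream
    in :func:`compute_fcd`).
    """
    sim_fc = np.asarray(sim_fc, float)
    emp_fc = np.asarray(emp_fc, float)
    if sim_fc.shape != emp_fc.shape:
        raise ValueError("simulated and empirical FC have mismatched shapes")
    edge_mask = None
    if hemisphere is not None and not include_interhemispheric:
        edge_mask = intrahemispheric_edge_mask(hemisphere)
    sim_v = _tril_values(sim_fc, edge_mask)
    emp_v = _tril_values(emp_fc, edge_mask)
    fc_corr = float(np.corrcoef(sim_v, emp_v)[0, 1])
    fc_diff = float(abs(sim_v.mean() - emp_v.mean()))
    fcd_ks = ks_distance(_tril_values(np.asarray(sim_fcd, float)),
                         _tril_values(np.asarray(emp_fcd, float)))
    gof = fc_corr - fc_diff - fcd_ks
    return GofBreakdown(fc_corr=fc_corr, fc_diff=fc_diff, fcd_ks=fcd_ks,
                        gof=gof, edge_mask=edge_mask)
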