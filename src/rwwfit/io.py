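"""File I/O, configuration and provenance.

All matrices (connectome weights, streamline lengths, maps, BOLD) are
plain whitespace/TSV numeric text with an optional single header line of
labels; hemisphere labels are a two-column TSV (node label, L|R). Node
order must be identical across the files of one subject. Configuration is
YAML mirroring the package defaults section by section; unknown keys are
rejected. Every CLI output directory carries a JSON provenance record
(config hash, seeds, package version).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = ["read_matrix", "write_matrix", "read_hemisphere", "write_hemisphere",
           "normalize_sc", "default_config", "load_config", "config_hash",
           "provenance_record", "read_mask", "write_mask"]


def read_matrix(path) -> tuple[np.ndarray, Optional[list]]:
    """Read a whitespace/TSV numeric matrix; returns (matrix, labels).

    A first line whose tokens are not all numeric is treated as a header
    of column labels. Ragged rows, non-numeric cells and NaNs raise
    descriptive errors.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty matrix file")
    labels = None
    first = lines[0].split()
    try:
        [float(tok) for tok in first]
    except ValueError:
        labels = first
        lines = lines[1:]
        if not lines:
            raise ValueError(f"{path}: header but no data rows")
    try:
        mat = np.loadtxt(_io.StringIO("\n".join(lines)), ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse numeric matrix "
                         f"(ragged rows or non-numeric cells?): {exc}") from exc
    bad = np.argwhere(np.isnan(mat))
    if bad.size:
        r, c = bad[0]
        raise ValueError(f"{path}: NaN at row {r + 1}, column {c + 1} (1-based)")
    return mat, labels


def write_matrix(path, mat: np.ndarray, labels: Optional[Sequence[str]] = None) -> None:
    """Write a matrix as TSV with full double precision (round-trips
    bit-exactly through :func:`read_matrix`)."""
    path = Path(path)
    header = "\t".join(labels) if labels else ""
    np.savetxt(path, np.atleast_2d(mat), fmt="%.17g", delimiter="\t",
               header=header, comments="")


def read_hemisphere(path) -> np.ndarray:
    """Two-column TSV (node label, L|R) -> array of 'L'/'R' labels."""
    out = []
    for i, ln in enumerate(Path(path).read_text().splitlines()):
        if not ln.strip():
            continue
        parts = ln.split()
        if len(parts) != 2 or parts[1] not in ("L", "R"):
            raise ValueError(f"{path}: line {i + 1} must be '<node> L|R'")
        out.append(parts[1])
    if not out:
        raise ValueError(f"{path}: no hemisphere labels")
    return np.asarray(out)


def write_hemisphere(path, labels: np.ndarray) -> None:
    with open(path, "w") as fh:
        for i, lab in enumerate(labels):
            fh.write(f"node{i + 1}\t{lab}\n")


def read_mask(path) -> np.ndarray:
    """Per-volume 0/1 outlier mask, one value per line (1 = outlier)."""
    vals, _ = read_matrix(path)
    vals = vals.ravel()
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{path}: mask values must be 0 or 1")
    return vals.astype(bool)


def write_mask(path, mask: np.ndarray) -> None:
    np.savetxt(path, np.asarray(mask, dtype=int).reshape(-1, 1), fmt="%d")


def normalize_sc(weights: np.ndarray, include_diagonal: bool = True) -> np.ndarray:
    """Normalize a structural connectome by dividing by (mean * 100), so
    the normalized mean weight is exactly 0.01.

    The mean is taken over all n^2 entries (including the zero diagonal)
    by default; ``include_diagonal=False`` uses the off-diagonal mean.
    Scale-invariant and idempotent on already-normalized input.
    """
    W = np.asarray(weights, float)
    if np.any(W < 0):
        raise ValueError("connectome weights must be nonnegative")
    if include_diagonal:
        m = W.mean()
    else:
        n = W.shape[0]
        m = (W.sum() - np.trace(W)) / (n * (n - 1))
    if m == 0:
        raise ValueError("cannot normalize an all-zero connectome")
    return W / (m * 100.0)


# ---------------------------------------------------------------------------
# configuration


def default_config() -> dict:
    """Nested default configuration; every value equals the package's
    model defaults."""
    from .constants import HemoConstants, ModelConstants
    from .fic import FICConfig
    from .fit import FitConfig

    fit = FitConfig()
    return {
        "model": asdict(ModelConstants()),
        "hemo": asdict(HemoConstants()),
        "sim": {
            "TR": 3.0, "duration": 450.0, "burn_in": 30.0,
            "dt_neuronal": 1e-4, "dt_bold": 1e-3, "noise_seed": 0,
            "velocity": None, "global_input_interval": None, "s_init": 0.001,
        },
        "fic": {k: v for k, v in asdict(FICConfig()).items()},
        "features": {
            "window_len_s": 30.0, "step_s": 6.0, "drop_edge_windows": True,
            "max_outlier_frac": 0.5, "include_interhemispheric": False,
            "mask_fcd_edges": True,
        },
        "fit": {
            "lambda_": fit.lambda_, "max_generations": fit.max_generations,
            "early_stop_window": fit.early_stop_window,
            "early_stop_min_improvement": fit.early_stop_min_improvement,
            "rate_range": list(fit.rate_range), "n_runs": fit.n_runs,
            "sigma0": fit.sigma0, "variant": "map_based",
        },
    }


def _merge_strict(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        if key not in base:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge_strict(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Load a YAML config and merge it over the defaults; unknown keys
    are rejected."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
        cfg = _merge_strict(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def provenance_record(cfg: dict, command: str, seeds: dict) -> dict:
    from . import __version__
    return {"command": command, "config_hash": config_hash(cfg),
            "seeds": {k: int(v) for k, v in seeds.items()},
            "rwwfit_version": __version__}
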