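"""Goodness-of-fit metrics and grid fitting.

FC matrices are compared with the structural similarity index (SSIM,
windowed Gaussian-weighted local statistics; 1 = perfect fit).  Spectral
vectors (relative band powers) are compared with the Clarkson distance
lambda(x, y) = ||x/|x| - y/|y||/2 between unit-normalized vectors;
1 - lambda is the spectral goodness of fit.  Parameters are fitted by
exhaustive grid sweeps of simulator runs; the dual EEG+fMRI procedure
masks the grid by spectral goodness >= a threshold (default 0.85) and
maximizes the fMRI SSIM inside the mask.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .config import ModelConfig
from .hemodynamics import simulate_bold
from .model import SimulationError, simulate
from .observables import (
    BANDS,
    FCMatrix,
    SpectralVector,
    bold_fc,
    envelope_fc,
    relative_band_power,
    welch_psd,
)
from .params import SimulationProtocol

__all__ = [
    "FitSurface", "DualFitResult", "ssim", "clarkson_goodness",
    "cohens_d", "effect_size_bin", "grid_sweep", "dual_fit_select",
]


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Structural similarity between two same-shape matrices, in [0, 1]
    for same-signed data; ssim(A, A) = 1 exactly.

    Gaussian-weighted local statistics (sigma 1.5) per the standard
    windowed formulation, averaged over the matrix; the data range is
    pinned to the joint span of both inputs (necessary for
    correlation-valued matrices).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    side = min(a.shape)
    win = min(7, side if side % 2 else side - 1)
    if win < 3:
        raise ValueError("matrices must be at least 3x3 for windowed SSIM")
    rng = float(max(a.max(), b.max()) - min(a.min(), b.min()))
    if rng == 0.0:
        return 1.0 if np.array_equal(a, b) else 0.0
    return float(structural_similarity(
        a, b, gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
        data_range=rng, win_size=win,
    ))


def clarkson_goodness(x, y) -> float:
    """Spectral goodness of fit 1 - lambda(x, y) in [0, 1].

    lambda is half the Euclidean distance between the unit-normalized
    vectors, so the result is scale-invariant in each argument, 1 for
    proportional vectors and 0 for anti-parallel ones.
    """
    x = x.values if isinstance(x, SpectralVector) else np.asarray(x, dtype=float)
    y = y.values if isinstance(y, SpectralVector) else np.asarray(y, dtype=float)
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("Clarkson distance undefined for a zero vector")
    lam = 0.5 * np.linalg.norm(x / nx - y / ny)
    return float(1.0 - lam)


_D_BINS = [(0.2, "very small"), (0.5, "small"), (0.8, "moderate"),
           (1.2, "large"), (2.0, "very large")]


def effect_size_bin(d: float) -> str:
    """Qualitative label for |D|: very small < 0.2 <= small < 0.5 <= moderate
    < 0.8 <= large < 1.2 <= very large < 2 <= huge."""
    for cut, name in _D_BINS:
        if abs(d) < cut:
            return name
    return "huge"


def cohens_d(x, y) -> tuple[float, str]:
    """Cohen's D = (mean x - mean y) / pooled SD, with its qualitative bin."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    d = float((x.mean() - y.mean()) / np.sqrt(sp2))
    return d, effect_size_bin(d)


@dataclass
class FitSurface:
    """Goodness-of-fit values over a 2-D parameter grid.

    ``axes`` maps axis name -> grid values (two axes); ``values`` has
    shape (len(axis0), len(axis1)); blown-up cells are NaN.
    """

    axes: dict[str, np.ndarray]
    values: np.ndarray
    metric: str = ""
    n_seeds: int = 1

    def __post_init__(self) -> None:
        shape = tuple(len(v) for v in self.axes.values())
        if self.values.shape != shape:
            raise ValueError("surface shape does not match axes")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (axis values, metric value, n_seeds)."""
        (n0, v0), (n1, v1) = self.axes.items()
        rows = [
            {n0: a, n1: b, "value": self.values[i, j],
             "metric": self.metric, "n_seeds": self.n_seeds}
            for i, a in enumerate(v0) for j, b in enumerate(v1)
        ]
        return pd.DataFrame(rows)


@dataclass
class DualFitResult:
    """Outcome of the masked EEG+fMRI selection."""

    threshold: float
    mask: np.ndarray
    selected: dict | None         # axis name -> value, or None if no cell passes
    selected_ssim: float | None
    selected_index: tuple[int, int] | None

    @property
    def no_fit(self) -> bool:
        return self.selected is None


def dual_fit_select(eeg_surface: FitSurface, fmri_surface: FitSurface,
                    threshold: float = 0.85) -> DualFitResult:
    """Mask the grid by EEG goodness >= threshold, then argmax fMRI SSIM.

    Ties are broken toward the lowest value of the first axis, then the
    second (row-major order of the first maximal cell).  An empty mask
    returns an explicit no-fit result.
    """
    if {k: tuple(v) for k, v in eeg_surface.axes.items()} != \
       {k: tuple(v) for k, v in fmri_surface.axes.items()}:
        raise ValueError("surfaces must share identical grids")
    mask = np.asarray(eeg_surface.values >= threshold) & np.isfinite(fmri_surface.values)
    if not mask.any():
        return DualFitResult(threshold, mask, None, None, None)
    vals = np.where(mask, fmri_surface.values, -np.inf)
    idx = np.unravel_index(np.argmax(vals), vals.shape)
    names = list(eeg_surface.axes)
    sel = {names[0]: float(eeg_surface.axes[names[0]][idx[0]]),
           names[1]: float(eeg_surface.axes[names[1]][idx[1]])}
    return DualFitResult(threshold, mask, sel, float(vals[idx]), (int(idx[0]), int(idx[1])))


def _mean_band_ssim(eeg: np.ndarray, fs: float, targets: dict[str, np.ndarray]) -> float:
    """Unweighted mean SSIM between per-band envelope FCs and target FCs."""
    vals = []
    for band, tgt in targets.items():
        fc = envelope_fc(eeg, fs, BANDS[band])
        vals.append(ssim(fc.values, np.asarray(tgt)))
    return float(np.mean(vals))


def grid_sweep(cfg: ModelConfig, protocol: SimulationProtocol,
               axes: dict[str, np.ndarray], M: np.ndarray,
               targets: dict, n_seeds: int = 3, base_seed: int = 0,
               tr: float = 2.08, bold_discard: float = 10.0,
               spectral_bands=("theta", "alpha", "beta")) -> dict[str, FitSurface]:
    """Exhaustive sweep over a 2-D parameter grid.

    Parameters
    ----------
    axes : dict
        Two entries, axis name -> grid values.  Axis names are flat
        config keys ("K", "rho", "r_alpha", ...).
    targets : dict
        Any of: ``"spectral"`` -> target relative-power vector over
        ``spectral_bands`` (region-averaged EEG spectrum);
        ``"bold_fc"`` -> target BOLD FC matrix; ``"eeg_fc"`` -> dict
        band name -> target envelope-FC matrix.
    n_seeds : int
        Realizations per cell.  Per the averaging conventions, BOLD FCs
        are averaged across seeds before SSIM; EEG metrics are computed
        per seed and averaged.

    Returns one :class:`FitSurface` per requested metric, with keys
    ``"spectral"``, ``"bold_fc_ssim"``, ``"eeg_fc_ssim"``.  Cells whose
    simulations blow up are recorded as NaN, not raised.
    """
    if len(axes) != 2:
        raise ValueError("grid_sweep expects exactly two axes")
    (name0, vals0), (name1, vals1) = [(k, np.asarray(v, dtype=float)) for k, v in axes.items()]
    shape = (len(vals0), len(vals1))
    out = {}
    if "spectral" in targets:
        out["spectral"] = np.full(shape, np.nan)
    if "bold_fc" in targets:
        out["bold_fc_ssim"] = np.full(shape, np.nan)
    if "eeg_fc" in targets:
        out["eeg_fc_ssim"] = np.full(shape, np.nan)

    for (i, v0), (j, v1) in itertools.product(enumerate(vals0), enumerate(vals1)):
        cell_cfg = cfg.with_(**{name0: float(v0), name1: float(v1)})
        spec_vals, eegfc_vals, fcs = [], [], []
        failed = False
        for s in range(n_seeds):
            seed = base_seed + 977 * (i * len(vals1) + j) + s
            try:
                res = simulate(cell_cfg, protocol, M=M, seed=seed)
            except SimulationError:
                failed = True
                break
            if "spectral" in targets:
                f, pxx = welch_psd(res.eeg, res.fs)
                rbp = relative_band_power(f, pxx.mean(axis=1), bands=spectral_bands)
                spec_vals.append(clarkson_goodness(rbp, targets["spectral"]))
            if "eeg_fc" in targets:
                eegfc_vals.append(_mean_band_ssim(res.eeg, res.fs, targets["eeg_fc"]))
            if "bold_fc" in targets:
                bold = simulate_bold(res.rate_pyr, res.fs, tr=tr, t_discard=bold_discard)
                fcs.append(bold_fc(bold, tr).values)
        if failed:
            continue
        if spec_vals:
            out["spectral"][i, j] = np.mean(spec_vals)
        if eegfc_vals:
            out["eeg_fc_ssim"][i, j] = np.mean(eegfc_vals)
        if fcs:
            tgt = targets["bold_fc"]
            tgt = tgt.values if isinstance(tgt, FCMatrix) else np.asarray(tgt)
            out["bold_fc_ssim"][i, j] = ssim(np.mean(fcs, axis=0), tgt)

    axes_dict = {name0: vals0, name1: vals1}
    return {k: FitSurface(axes_dict, v, metric=k, n_seeds=n_seeds) for k, v in out.items()}
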