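"""EEG and BOLD observables: band filtering, envelopes, functional
connectivity, and power spectra.

EEG functional connectivity is amplitude-envelope correlation (AEC):
signals are band-passed with a 3rd-order Bessel filter in the canonical
bands, the Hilbert envelope is taken, high-passed at 0.5 Hz with a
3rd-order Butterworth, and Pearson-correlated across region pairs.
BOLD FC band-passes at 0.01-0.08 Hz (Bessel) before correlating.
Spectra use Welch's method with 2 s windows and 50% overlap; relative
band power normalizes by the total 0.5-30 Hz power.

All filters are applied zero-phase (forward-backward) since the FC
estimators are phase-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDefinition", "BANDS", "FCMatrix", "SpectralVector",
    "bandpass", "envelope", "envelope_fc", "bold_fc",
    "welch_psd", "normalized_psd", "relative_band_power", "dominant_frequency",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0.0 < self.low < self.high:
            raise ValueError("require 0 < low < high")


#: Canonical EEG bands.
BANDS = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
}


@dataclass
class FCMatrix:
    """Pairwise Pearson correlation matrix with band and modality tags."""

    values: np.ndarray
    band: str = ""
    modality: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FC must be symmetric")
        if np.nanmax(np.abs(v)) > 1.0 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v


@dataclass
class SpectralVector:
    """Relative power per band (fractions of the total analysis-range power)."""

    values: np.ndarray
    bands: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("relative powers must be >= 0")
        self.values = v


def _sos_bessel_bandpass(low: float, high: float, fs: float):
    return sps.bessel(3, [low, high], btype="bandpass", fs=fs, output="sos", norm="phase")


def bandpass(x: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    """Zero-phase 3rd-order Bessel band-pass along the first axis."""
    if fs <= 2.0 * band.high:
        raise ValueError(f"band {band.name} upper edge {band.high} Hz is at/above Nyquist for fs={fs}")
    sos = _sos_bessel_bandpass(band.low, band.high, fs)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def envelope(x: np.ndarray, fs: float, highpass_hz: float = 0.5) -> np.ndarray:
    """Hilbert amplitude envelope, high-passed (3rd-order Butterworth, zero-phase)."""
    env = np.abs(sps.hilbert(np.asarray(x, dtype=float), axis=0))
    sos = sps.butter(3, highpass_hz, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, env, axis=0)


def _pearson_fc(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant channel: Pearson correlation undefined")
    fc = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(fc, 1.0)
    return np.clip((fc + fc.T) / 2.0, -1.0, 1.0)


def envelope_fc(x: np.ndarray, fs: float, band: BandDefinition,
                edge_trim: float = 1.0) -> FCMatrix:
    """Amplitude-envelope-correlation FC of a (n_samples, n_channels) signal.

    ``edge_trim`` seconds are dropped at both ends of the envelopes to
    suppress Hilbert/filter edge artifacts before correlating.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a (n_samples, n_channels >= 2) array")
    env = envelope(bandpass(x, fs, band), fs)
    k = int(round(edge_trim * fs))
    if 2 * k >= env.shape[0]:
        raise ValueError("signal too short for the requested edge trim")
    env = env[k:env.shape[0] - k]
    return FCMatrix(_pearson_fc(env), band=band.name, modality="EEG-envelope")


def bold_fc(bold: np.ndarray, tr: float, low: float = 0.01, high: float = 0.08) -> FCMatrix:
    """BOLD FC: zero-phase 3rd-order Bessel band-pass (0.01-0.08 Hz) then Pearson."""
    x = np.asarray(bold, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a (n_samples, n_regions >= 2) array")
    fs = 1.0 / tr
    if x.shape[0] * tr < 2.0 / low:
        raise ValueError("BOLD series too short for the 0.01 Hz filter band")
    sos = _sos_bessel_bandpass(low, high, fs)
    filt = sps.sosfiltfilt(sos, x, axis=0)
    return FCMatrix(_pearson_fc(filt), band=f"{low}-{high}Hz", modality="BOLD")


def welch_psd(x: np.ndarray, fs: float, window_s: float = 2.0,
              overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with ``window_s``-second Hann windows and fractional overlap.

    Defaults give 0.5 Hz resolution.  Multichannel input (columns) returns
    one PSD per column.
    """
    x = np.asarray(x, dtype=float)
    nper = int(round(window_s * fs))
    if x.shape[0] < 2 * nper:
        raise ValueError("signal shorter than two Welch windows")
    f, pxx = sps.welch(x, fs=fs, nperseg=nper, noverlap=int(round(overlap * nper)),
                       window="hann", detrend="constant", axis=0)
    return f, pxx


def normalized_psd(psd: np.ndarray) -> np.ndarray:
    """Scale a PSD so its maximum is 1 (shape-preserving)."""
    psd = np.asarray(psd, dtype=float)
    m = psd.max()
    if m <= 0:
        raise ValueError("PSD has no positive maximum")
    return psd / m


def relative_band_power(freqs: np.ndarray, psd: np.ndarray,
                        bands=("theta", "alpha", "beta"),
                        total_range: tuple[float, float] = (0.5, 30.0)) -> SpectralVector:
    """Per-band power as a fraction of the total power in ``total_range``.

    Band and total powers are trapezoid integrals of the PSD over the
    frequency bins falling in each range.  When the requested bands tile
    the total range the fractions sum to 1.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    bdefs = [BANDS[b] if isinstance(b, str) else b for b in bands]
    lo, hi = total_range
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        raise ValueError("PSD does not cover the total analysis range")
    total = np.trapezoid(psd[mask], freqs[mask], axis=0)
    vals = []
    for b in bdefs:
        m = (freqs >= b.low) & (freqs <= b.high)
        if m.sum() < 2:
            raise ValueError(f"band {b.name} is empty after discretization")
        vals.append(np.trapezoid(psd[m], freqs[m], axis=0) / total)
    return SpectralVector(np.asarray(vals), tuple(b.name for b in bdefs))


def dominant_frequency(psd: tuple[np.ndarray, np.ndarray],
                       search_range: tuple[float, float] = (0.5, 60.0)) -> float:
    """Frequency of the global PSD maximum within ``search_range``.

    Ties are broken toward the lower frequency (argmax returns the first
    maximal bin).
    """
    freqs, pxx = psd
    freqs = np.asarray(freqs, dtype=float)
    pxx = np.asarray(pxx, dtype=float)
    if pxx.ndim > 1:
        pxx = pxx.mean(axis=1)
    mask = (freqs >= search_range[0]) & (freqs <= search_range[1])
    if not mask.any():
        raise ValueError("search range contains no PSD bins")
    return float(freqs[mask][np.argmax(pxx[mask])])
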