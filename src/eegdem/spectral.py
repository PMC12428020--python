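"""Welch power spectral density estimation and EEG band powers.

The spectral estimate used throughout the pipeline is Welch's method:
the signal is split into overlapping tapered segments, a periodogram is
computed per segment and the periodograms are averaged,

    S(w) = (1/L) sum_l  P_l(w),

with one-sided density scaling (integral of ``power`` over frequency
equals the mean square of the signal, up to taper correction).  Band
powers aggregate the density over the canonical EEG bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError(f"invalid band edges {self.low}-{self.high}")


#: Canonical EEG sub-bands. Band-power bins are half-open [low, high);
#: the topmost band (gamma) additionally includes its upper edge so the
#: 0.5-45 Hz analysis range is tiled without double counting.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 25.0),
    BandDefinition("gamma", 25.0, 45.0),
)

BAND_ORDER: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


@dataclass
class PSDEstimate:
    """One-sided Welch PSD of a single channel.

    ``power`` is in signal-units squared per Hz; ``freqs`` runs from 0
    to the Nyquist frequency inclusive.
    """

    freqs: np.ndarray
    power: np.ndarray
    fs: float
    seg_len: int
    n_segments: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def df(self) -> float:
        """Frequency-bin spacing in Hz."""
        return float(self.freqs[1] - self.freqs[0])

    def total_power(self) -> float:
        """Integral of the density over frequency (trapezoid-free Riemann sum)."""
        return float(np.sum(self.power) * self.df)


def welch_psd(
    x: np.ndarray,
    fs: float,
    seg_len: int | None = None,
    overlap_fraction: float = 0.75,
    window: str = "hamming",
) -> PSDEstimate:
    """Welch PSD of a single-channel signal.

    Parameters
    ----------
    x : 1-D array
        Signal samples.
    fs : float
        Sampling rate in Hz.
    seg_len : int, optional
        Samples per Welch segment. Default ``round(2 * fs)`` (2 s
        segments, 0.5 Hz resolution at 500 Hz, so the 0.5-4 Hz delta
        band contains at least 7 bins).
    overlap_fraction : float
        Fractional overlap between consecutive segments (default 0.75).
    window : str
        Taper name as understood by scipy (default Hamming).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("welch_psd expects a single-channel 1-D signal")
    if seg_len is None:
        seg_len = int(round(2 * fs))
    if seg_len < 8:
        raise ValueError("seg_len must be at least 8 samples")
    if seg_len > x.size:
        raise ValueError(
            f"seg_len {seg_len} exceeds signal length {x.size}"
        )
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    noverlap = int(round(seg_len * overlap_fraction))
    freqs, power = sps.welch(
        x, fs=fs, window=window, nperseg=seg_len, noverlap=noverlap,
        detrend=False, scaling="density", return_onesided=True,
    )
    step = seg_len - noverlap
    n_segments = 1 + (x.size - seg_len) // step
    return PSDEstimate(freqs=freqs, power=power, fs=fs,
                       seg_len=seg_len, n_segments=int(n_segments))


def band_bins(psd: PSDEstimate, band: BandDefinition,
              closed_upper: bool = False) -> np.ndarray:
    """Boolean mask of PSD bins falling inside the band.

    Bins satisfy ``low <= f < high`` (``<= high`` if *closed_upper*).
    """
    if band.low >= psd.freqs[-1] and not closed_upper:
        raise ValueError(f"band {band.name} lies above the Nyquist range")
    mask = (psd.freqs >= band.low) & (
        psd.freqs <= band.high if closed_upper else psd.freqs < band.high
    )
    return mask


def band_power(psd: PSDEstimate, band: BandDefinition,
               mode: str = "mean", closed_upper: bool = False) -> float:
    """Aggregate PSD over one band.

    ``mode="mean"`` returns the mean density over the band's bins (the
    (1/N) sum X_i form); ``mode="integral"`` returns the integrated
    power (mean x bandwidth covered). Ratios between bands are
    unaffected by the choice only when band widths are equal, so the
    mode is a config item carried by the feature stage.
    """
    mask = band_bins(psd, band, closed_upper=closed_upper)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"band {band.name} ({band.low}-{band.high} Hz) contains no "
            f"frequency bins at resolution {psd.df:.4g} Hz"
        )
    if mode == "mean":
        return float(psd.power[mask].mean())
    if mode == "integral":
        return float(psd.power[mask].sum() * psd.df)
    raise ValueError(f"unknown band power mode {mode!r}")


def band_powers(psd: PSDEstimate, bands=DEFAULT_BANDS,
                mode: str = "mean") -> dict[str, float]:
    """Band power for every band; the topmost band includes its upper edge."""
    top = max(range(len(bands)), key=lambda i: bands[i].high)
    return {
        b.name: band_power(psd, b, mode=mode, closed_upper=(i == top))
        for i, b in enumerate(bands)
    }


def band_fractions(psd: PSDEstimate, bands=DEFAULT_BANDS) -> dict[str, float]:
    """Fraction of integrated in-band power falling in each band."""
    integ = band_powers(psd, bands, mode="integral")
    total = sum(integ.values())
    if total <= 0:
        raise ValueError("signal has no in-band power")
    return {k: v / total for k, v in integ.items()}


def band_ratio(numerator_power: float, denominator_power: float) -> float:
    """Ratio of two band powers.

    Returns ``inf`` for a positive numerator over a zero denominator and
    ``nan`` for 0/0; downstream feature assembly treats both as missing.
    """
    if numerator_power < 0 or denominator_power < 0:
        raise ValueError("band powers must be non-negative")
    if denominator_power == 0:
        return math.inf if numerator_power > 0 else math.nan
    return numerator_power / denominator_power
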