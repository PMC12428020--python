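"""Synthetic resting-state EEG cohorts with class-specific band power.

The generator emulates the one property of dementia EEG the downstream
features actually measure: the distribution of power over the canonical
delta/theta/alpha/beta/gamma bands. Each channel is a sum of
band-limited Gaussian processes (white noise band-passed to each band,
variance-normalised, scaled by the profile's relative power gain) plus
a 1/f^alpha pink background. Alzheimer-type profiles shift power toward
delta/theta and away from alpha/beta ("spectral slowing"); healthy
profiles are alpha-dominant; the frontotemporal profile slows frontal
channels only.

Because the generative ground truth *is* the band-power vector, the
whole feature -> selection -> classification pipeline closes the loop:
parameter recovery is directly testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .data import CHANNELS_1020, FRONTAL_CHANNELS, Recording
from .spectral import BAND_ORDER, DEFAULT_BANDS

logger = logging.getLogger(__name__)

#: Root scale of the generated signal in microvolts (cosmetic; every
#: feature downstream is either scale-free or standardised).
_AMPLITUDE_UV = 10.0


@dataclass(frozen=True)
class ClassProfile:
    """Spectral recipe of one diagnostic class.

    Parameters
    ----------
    name : str
        Class label (``"AD"``, ``"FTD"``, ``"HC"``).
    band_gains : dict
        Relative *power* gain per band name; only ratios matter.
    gain_cv : float
        Coefficient of variation of the per-subject multiplicative gain
        jitter (0 disables between-subject variability).
    pink_exponent : float
        Spectral slope alpha of the 1/f^alpha background.
    pink_fraction : float
        Pink-background power as a fraction of the summed band-gain
        power (default 0.1; 0 disables the background).
    frontal_band_gains : dict, optional
        Override gains applied to frontal channels only (Fp1, Fp2, F7,
        F3, Fz, F4, F8), used for region-specific slowing.
    """

    name: str
    band_gains: dict[str, float]
    gain_cv: float = 0.0
    pink_exponent: float = 1.0
    pink_fraction: float = 0.1
    frontal_band_gains: dict[str, float] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.band_gains) - set(BAND_ORDER)
        if unknown:
            raise ValueError(f"unknown band names {sorted(unknown)}")
        if any(g < 0 for g in self.band_gains.values()):
            raise ValueError("band gains must be non-negative")
        if not any(g > 0 for g in self.band_gains.values()):
            raise ValueError("at least one band gain must be positive")
        if self.gain_cv < 0:
            raise ValueError("gain_cv must be non-negative")
        if self.pink_exponent < 0:
            raise ValueError("pink_exponent must be non-negative")
        if self.pink_fraction < 0:
            raise ValueError("pink_fraction must be non-negative")

    def gains_for_channel(self, channel: str) -> dict[str, float]:
        if self.frontal_band_gains is not None and channel in FRONTAL_CHANNELS:
            return self.frontal_band_gains
        return self.band_gains


def default_profiles(separation: float = 1.0, gain_cv: float = 0.1) -> list[ClassProfile]:
    """The three default class profiles.

    HC is alpha-dominant; AD is slow-shifted (delta/theta up,
    alpha/beta down); FTD applies the midpoint of the two to frontal
    channels only. ``separation`` in [0, 1] linearly interpolates every
    non-HC profile between the HC profile (0, no class structure) and
    the full effect (1, default).
    """
    hc = {"delta": 0.15, "theta": 0.15, "alpha": 0.40, "beta": 0.20, "gamma": 0.10}
    ad = {"delta": 0.30, "theta": 0.30, "alpha": 0.15, "beta": 0.15, "gamma": 0.10}

    def mix(a: dict, b: dict, t: float) -> dict:
        return {k: (1 - t) * a[k] + t * b[k] for k in a}

    ad_s = mix(hc, ad, separation)
    ftd_frontal = mix(hc, ad, 0.5 * separation)
    return [
        ClassProfile("AD", ad_s, gain_cv=gain_cv),
        ClassProfile("HC", dict(hc), gain_cv=gain_cv),
        ClassProfile("FTD", dict(hc), gain_cv=gain_cv,
                     frontal_band_gains=ftd_frontal),
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Recipe for a full synthetic cohort."""

    profiles: tuple[ClassProfile, ...] = field(
        default_factory=lambda: tuple(default_profiles())
    )
    subjects_per_class: int = 10
    duration_s_range: tuple[float, float] = (60.0, 180.0)
    fs: float = 500.0
    n_channels: int = 19
    channel_names: tuple[str, ...] = CHANNELS_1020
    shared_source_mixing: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if not self.profiles:
            raise ValueError("profile list must not be empty")
        if self.subjects_per_class < 1:
            raise ValueError("subjects_per_class must be positive")
        lo, hi = self.duration_s_range
        if not (0 < lo <= hi):
            raise ValueError("invalid duration range")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")
        if len(set(self.channel_names)) != self.n_channels:
            raise ValueError("channel names must be unique")
        if not (0 <= self.shared_source_mixing <= 1):
            raise ValueError("shared_source_mixing must lie in [0, 1]")


_BAND_EDGES = {b.name: (b.low, b.high) for b in DEFAULT_BANDS}


def _unit_band_noise(n: int, fs: float, low: float, high: float,
                     rng: np.random.Generator, order: int = 4) -> np.ndarray:
    """White Gaussian noise band-passed to [low, high], unit variance.

    4th-order Butterworth applied forward-backward (zero phase).
    """
    white = rng.standard_normal(n)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    if sd == 0:  # pragma: no cover - degenerate filter output
        raise RuntimeError("band-limited noise collapsed to zero")
    return x / sd


def _unit_pink_noise(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha noise with unit variance, synthesised in the Fourier domain."""
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-alpha / 2.0)
    spectrum = scale * (rng.standard_normal(freqs.size)
                        + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spectrum, n=n)
    return x / x.std()


def generate_recording(
    profile: ClassProfile,
    duration_s: float,
    fs: float = 500.0,
    n_channels: int = 19,
    seed: int = 0,
    channel_names: tuple[str, ...] | None = None,
    shared_source_mixing: float = 0.2,
    subject_id: str = "",
) -> Recording:
    """Generate one synthetic recording.

    Each channel is the sum of one variance-normalised band-limited
    Gaussian process per band, scaled by ``sqrt(gain * jitter)`` (gains
    are power gains), plus a pink 1/f^alpha background whose power is
    ``pink_fraction`` of the summed band-gain power. Channels share a
    per-band common source with amplitude weight
    ``sqrt(shared_source_mixing)`` to create realistic inter-channel
    correlation. Deterministic given *seed*.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration and sampling rate must be positive")
    n = int(round(duration_s * fs))
    if n < 2 * fs:
        raise ValueError("recording must be at least 2 s long")
    if channel_names is None:
        channel_names = CHANNELS_1020[:n_channels]
    if len(channel_names) != n_channels:
        raise ValueError("channel_names length must equal n_channels")

    rng = np.random.default_rng(seed)
    # Per-subject multiplicative gain jitter, one draw per band, in a
    # fixed band order so the stream is reproducible.
    jitter = {
        band: max(0.05, 1.0 + profile.gain_cv * rng.standard_normal())
        if profile.gain_cv > 0 else 1.0
        for band in BAND_ORDER
    }
    m = shared_source_mixing
    shared = {
        band: _unit_band_noise(n, fs, *_BAND_EDGES[band], rng)
        for band in BAND_ORDER
    } if m > 0 else {}

    data = np.zeros((n_channels, n))
    for ci, ch in enumerate(channel_names):
        gains = profile.gains_for_channel(ch)
        total_gain = 0.0
        x = np.zeros(n)
        for band in BAND_ORDER:
            g = gains.get(band, 0.0) * jitter[band]
            if g <= 0:
                continue
            own = _unit_band_noise(n, fs, *_BAND_EDGES[band], rng)
            if m > 0:
                src = np.sqrt(1 - m) * own + np.sqrt(m) * shared[band]
            else:
                src = own
            x += np.sqrt(g) * src
            total_gain += g
        if profile.pink_fraction > 0:
            pink = _unit_pink_noise(n, profile.pink_exponent, rng)
            x += np.sqrt(profile.pink_fraction * total_gain) * pink
        data[ci] = _AMPLITUDE_UV * x

    return Recording(
        data=data, fs=fs, channel_names=tuple(channel_names),
        label=profile.name, subject_id=subject_id or f"{profile.name}-s{seed}",
    )


def generate_cohort(config: CohortConfig) -> list[Recording]:
    """Generate ``subjects_per_class`` recordings per profile.

    Durations are drawn uniformly from ``duration_s_range``; per-subject
    seeds derive deterministically from ``config.seed``.
    """
    master = np.random.default_rng(config.seed)
    recordings: list[Recording] = []
    for profile in config.profiles:
        for i in range(config.subjects_per_class):
            lo, hi = config.duration_s_range
            duration = float(master.uniform(lo, hi))
            sub_seed = int(master.integers(0, 2**31 - 1))
            rec = generate_recording(
                profile,
                duration_s=duration,
                fs=config.fs,
                n_channels=config.n_channels,
                seed=sub_seed,
                channel_names=config.channel_names,
                shared_source_mixing=config.shared_source_mixing,
                subject_id=f"{profile.name}{i:03d}",
            )
            recordings.append(rec)
    logger.info("generated cohort: %d recordings, %d per class",
                len(recordings), config.subjects_per_class)
    return recordings


def null_cohort_config(subjects_per_class: int = 10,
                       duration_s_range: tuple[float, float] = (60.0, 180.0),
                       seed: int = 0) -> CohortConfig:
    """A zero-separation cohort: every class shares the HC profile with
    ``gain_cv = 0``, so labels carry no signal at all (used for
    chance-level calibration checks)."""
    hc = default_profiles(separation=1.0, gain_cv=0.0)[1]
    profiles = tuple(replace(hc, name=name) for name in ("AD", "HC", "FTD"))
    return CohortConfig(profiles=profiles,
                        subjects_per_class=subjects_per_class,
                        duration_s_range=duration_s_range, seed=seed)
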