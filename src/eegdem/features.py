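"""Per-channel time and spectral features and the 342-column matrix.

Eighteen features are computed per channel: seven time-domain
statistics (kurtosis, mean, RMS, skewness, standard deviation,
variance, Euclidean norm) and eleven spectral features (the five band
powers and six band-power ratios; gamma joins no ratio because the
dementia signature of interest lives below 25 Hz). Over the 19
channels of the 10-20 montage this yields 19 x 18 = 342 features per
30 s epoch, indexed channel-major: flat index
``(channel_rank - 1) * 18 + feature_rank`` (1-based).

The moment statistics follow, by default, a hybrid toolbox convention
seen in clinical EEG feature tables: population standard deviation
combined with an N-1 normaliser in skewness/kurtosis
(``moment_convention="literal"``). Under that convention the kurtosis
of a large normal sample is close to 3 * N/(N-1), not exactly 3;
``"standard"`` switches to the usual population moments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CHANNELS_1020, CLASS_ORDER, Epoch
from .spectral import DEFAULT_BANDS, BandDefinition, band_powers, band_ratio, welch_psd

logger = logging.getLogger(__name__)

#: The 18 per-channel feature codes, in table order.
FEATURE_CODES: tuple[str, ...] = (
    "KU", "AVG", "RMS", "SK", "SD", "VAR", "NOR",
    "DBP", "TBP", "ABP", "BBP", "GBP",
    "DTBPR", "DABPR", "DBBPR", "TABPR", "TBBPR", "ABBPR",
)
TIME_CODES: tuple[str, ...] = FEATURE_CODES[:7]
BAND_POWER_CODES: tuple[str, ...] = FEATURE_CODES[7:12]
RATIO_CODES: tuple[str, ...] = FEATURE_CODES[12:]

#: Band pair named by each ratio code (first-named band, second-named band).
RATIO_PAIRS: dict[str, tuple[str, str]] = {
    "DTBPR": ("delta", "theta"),
    "DABPR": ("delta", "alpha"),
    "DBBPR": ("delta", "beta"),
    "TABPR": ("theta", "alpha"),
    "TBBPR": ("theta", "beta"),
    "ABBPR": ("alpha", "beta"),
}

N_FEATURES = len(CHANNELS_1020) * len(FEATURE_CODES)  # 342


@dataclass(frozen=True)
class FeatureName:
    """One column of the feature matrix: a (channel, feature) pair."""

    channel: str
    feature: str

    @property
    def flat_index(self) -> int:
        """1-based channel-major flat index in [1, 342]."""
        return (CHANNELS_1020.index(self.channel) * len(FEATURE_CODES)
                + FEATURE_CODES.index(self.feature) + 1)

    @classmethod
    def from_flat_index(cls, idx: int) -> "FeatureName":
        if not 1 <= idx <= N_FEATURES:
            raise ValueError(f"flat index {idx} outside [1, {N_FEATURES}]")
        ch, feat = divmod(idx - 1, len(FEATURE_CODES))
        return cls(CHANNELS_1020[ch], FEATURE_CODES[feat])

    def __str__(self) -> str:
        return f"{self.channel}/{self.feature}"


def feature_names(channels: tuple[str, ...] = CHANNELS_1020) -> list[FeatureName]:
    """All 342 feature names in flat-index order."""
    return [FeatureName(ch, code) for ch in channels for code in FEATURE_CODES]


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the feature-extraction stage."""

    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    channels: tuple[str, ...] = CHANNELS_1020
    class_order: tuple[str, ...] = CLASS_ORDER
    welch_seg_seconds: float = 2.0
    welch_overlap: float = 0.75
    welch_window: str = "hamming"
    band_power_mode: str = "mean"
    #: "inverse" stores each ratio as second-named/first-named band power
    #: (theta-alpha ratio = alpha/theta), matching the arithmetic of the
    #: reference feature tables; "named" stores first/second.
    ratio_orientation: str = "inverse"
    moment_convention: str = "literal"

    def __post_init__(self) -> None:
        if self.ratio_orientation not in ("inverse", "named"):
            raise ValueError("ratio_orientation must be 'inverse' or 'named'")
        if self.moment_convention not in ("literal", "standard"):
            raise ValueError(
                "moment_convention must be 'literal' or 'standard'")


def time_features(x: np.ndarray, convention: str = "literal") -> dict[str, float]:
    """The seven time-domain statistics of one channel epoch.

    AVG, SD (population), VAR, RMS and NOR = sqrt(sum x^2) are
    convention-free. Under ``convention="literal"`` skewness and kurtosis
    divide the raw third/fourth central moment sums by (N-1) * SD^p
    with the population SD; ``"standard"`` uses the population moment
    ratios m_p / m_2^(p/2). A constant signal (SD = 0) yields NaN
    skewness/kurtosis, the other five features stay valid.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    avg = float(x.mean())
    centered = x - avg
    var = float(np.mean(centered**2))
    sd = float(np.sqrt(var))
    rms = float(np.sqrt(np.mean(x**2)))
    nor = float(np.sqrt(np.sum(x**2)))
    if sd == 0.0:
        sk = ku = float("nan")
    elif convention == "literal":
        sk = float(np.sum(centered**3) / ((n - 1) * sd**3))
        ku = float(np.sum(centered**4) / ((n - 1) * sd**4))
    else:
        sk = float(np.mean(centered**3) / sd**3)
        ku = float(np.mean(centered**4) / sd**4)
    return {"KU": ku, "AVG": avg, "RMS": rms, "SK": sk,
            "SD": sd, "VAR": var, "NOR": nor}


def spectral_features(x: np.ndarray, fs: float,
                      config: FeatureConfig = FeatureConfig()) -> dict[str, float]:
    """The eleven spectral features of one channel epoch.

    Five Welch band powers plus six pairwise ratios over
    (delta,theta), (delta,alpha), (delta,beta), (theta,alpha),
    (theta,beta), (alpha,beta); gamma participates in no ratio.
    """
    psd = welch_psd(
        x, fs,
        seg_len=int(round(config.welch_seg_seconds * fs)),
        overlap_fraction=config.welch_overlap,
        window=config.welch_window,
    )
    powers = band_powers(psd, config.bands, mode=config.band_power_mode)
    code_of_band = dict(zip(("delta", "theta", "alpha", "beta", "gamma"),
                            BAND_POWER_CODES))
    out = {code_of_band[b]: powers[b] for b in code_of_band}
    for code, (first, second) in RATIO_PAIRS.items():
        if config.ratio_orientation == "inverse":
            out[code] = band_ratio(powers[second], powers[first])
        else:
            out[code] = band_ratio(powers[first], powers[second])
    return out


def assemble_feature_vector(epoch: Epoch,
                            config: FeatureConfig = FeatureConfig()
                            ) -> tuple[np.ndarray, list[FeatureName]]:
    """The 342-vector of one epoch, channel-major, plus its column names."""
    have = set(epoch.channel_names)
    want = set(config.channels)
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise ValueError(
            f"epoch channels do not match configuration: "
            f"missing {missing}, unexpected {extra}"
        )
    row_of = {ch: i for i, ch in enumerate(epoch.channel_names)}
    values = np.empty(len(config.channels) * len(FEATURE_CODES))
    names: list[FeatureName] = []
    pos = 0
    for ch in config.channels:
        x = epoch.data[row_of[ch]]
        feats = time_features(x, convention=config.moment_convention)
        feats.update(spectral_features(x, epoch.fs, config))
        for code in FEATURE_CODES:
            values[pos] = feats[code]
            names.append(FeatureName(ch, code))
            pos += 1
    return values, names


@dataclass
class FeatureMatrix:
    """Epochs x 342 feature values with labels and row provenance."""

    values: np.ndarray
    names: list[FeatureName]
    labels: np.ndarray          # class label per row
    subject_ids: np.ndarray     # subject id per row
    epoch_indices: np.ndarray   # epoch index within the subject's recording

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.subject_ids = np.asarray(self.subject_ids)
        self.epoch_indices = np.asarray(self.epoch_indices, dtype=int)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values shape does not match column names")
        n = self.values.shape[0]
        if not (len(self.labels) == len(self.subject_ids)
                == len(self.epoch_indices) == n):
            raise ValueError("row metadata length mismatch")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def subset_columns(self, flat_indices: list[int]) -> "FeatureMatrix":
        """Column subset by 1-based flat indices (order preserved)."""
        cols = [i - 1 for i in flat_indices]
        return FeatureMatrix(self.values[:, cols],
                             [self.names[c] for c in cols],
                             self.labels, self.subject_ids, self.epoch_indices)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[str(n) for n in self.names])
        df.insert(0, "label", self.labels)
        df.insert(1, "subject_id", self.subject_ids)
        df.insert(2, "epoch_index", self.epoch_indices)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.15g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta = ["label", "subject_id", "epoch_index"]
        cols = [c for c in df.columns if c not in meta]
        names = [FeatureName(*c.split("/")) for c in cols]
        return cls(df[cols].to_numpy(dtype=np.float64), names,
                   df["label"].to_numpy(), df["subject_id"].to_numpy(),
                   df["epoch_index"].to_numpy())


def build_feature_matrix(epochs: list[Epoch],
                         config: FeatureConfig = FeatureConfig()
                         ) -> FeatureMatrix:
    """One row per epoch, 342 columns, rows ordered by
    (class in configured order, subject id, epoch index).

    Epochs yielding any non-finite feature (0/0 ratio, constant
    channel) are dropped with a logged count rather than imputed.
    """
    if not epochs:
        raise ValueError("epoch list must not be empty")
    channel_sets = {tuple(sorted(e.channel_names)) for e in epochs}
    if len(channel_sets) > 1:
        raise ValueError("epochs have heterogeneous channel sets")
    rank = {c: i for i, c in enumerate(config.class_order)}
    ordered = sorted(epochs, key=lambda e: (rank.get(e.label, len(rank)),
                                            e.subject_id, e.epoch_index))
    rows, labels, subjects, indices = [], [], [], []
    names: list[FeatureName] | None = None
    dropped = 0
    for ep in ordered:
        vec, names = assemble_feature_vector(ep, config)
        if not np.all(np.isfinite(vec)):
            dropped += 1
            continue
        rows.append(vec)
        labels.append(ep.label)
        subjects.append(ep.subject_id)
        indices.append(ep.epoch_index)
    if dropped:
        logger.warning("dropped %d epoch(s) with missing features", dropped)
    if not rows:
        raise ValueError("every epoch produced missing features")
    return FeatureMatrix(np.vstack(rows), names, np.array(labels),
                         np.array(subjects), np.array(indices))


def describe_features(config: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """The full feature dictionary: flat index, channel, code, domain, bands."""
    records = []
    for name in feature_names(config.channels):
        if name.feature in TIME_CODES:
            domain, bands = "time", ""
        elif name.feature in BAND_POWER_CODES:
            domain = "spectral"
            bands = ("delta", "theta", "alpha", "beta", "gamma")[
                BAND_POWER_CODES.index(name.feature)]
        else:
            domain = "spectral"
            bands = "/".join(RATIO_PAIRS[name.feature])
        records.append({"flat_index": name.flat_index, "channel": name.channel,
                        "feature": name.feature, "domain": domain,
                        "bands": bands})
    return pd.DataFrame.from_records(records)
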