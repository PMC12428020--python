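"""Core data containers and on-disk formats for multichannel EEG.

A :class:`Recording` is a labelled continuous multichannel signal
(channels x samples, microvolts); an :class:`Epoch` is one fixed-length
window of a recording, the unit all features are computed on.

Recordings are stored on disk as a delimited numeric matrix
(samples x channels, one header row of channel names) with a JSON
sidecar carrying the sampling rate, class label and subject id.
EDF files are read through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: The 19 scalp electrodes of the international 10-20 system, in the
#: order used throughout the pipeline (channel-major feature indexing
#: depends on this order).
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: Frontal subset, used by class profiles with region-specific slowing.
FRONTAL_CHANNELS: frozenset[str] = frozenset(
    {"Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"}
)

#: Default class-label ordering (mirrors the concatenation order of the
#: cohort the pipeline emulates: AD, then HC, then FTD).
CLASS_ORDER: tuple[str, ...] = ("AD", "HC", "FTD")


@dataclass
class Recording:
    """A labelled continuous multichannel EEG signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        One name per row of ``data``.
    label : str
        Diagnostic class label (e.g. ``"AD"``, ``"FTD"``, ``"HC"``).
    subject_id : str
        Identifier of the subject the recording belongs to.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    label: str
    subject_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """One fixed-length window of a :class:`Recording`."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    label: str
    subject_id: str
    epoch_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D channels x samples")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match channel names")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# Plain-text on-disk format
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write one recording as ``<path>.tsv`` + ``<path>.json`` sidecar.

    The matrix is samples x channels with a header row of channel names;
    the sidecar holds ``fs``, ``label`` and ``subject_id``.  Returns the
    path of the matrix file.
    """
    path = Path(path)
    if path.suffix == ".tsv":
        path = path.with_suffix("")
    tsv = path.with_suffix(".tsv")
    header = "\t".join(recording.channel_names)
    np.savetxt(tsv, recording.data.T, fmt="%.6f", delimiter="\t",
               header=header, comments="")
    sidecar = {
        "fs": recording.fs,
        "label": recording.label,
        "subject_id": recording.subject_id,
        "channel_names": list(recording.channel_names),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return tsv


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording` or an EDF file."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    if path.suffix == ".json":
        path = path.with_suffix(".tsv")
    with open(path) as fh:
        names = tuple(fh.readline().strip().split("\t"))
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    meta = json.loads(path.with_suffix(".json").read_text())
    if tuple(meta.get("channel_names", names)) != names:
        raise ValueError(f"sidecar channel names disagree with header in {path}")
    return Recording(
        data=data.T,
        fs=float(meta["fs"]),
        channel_names=names,
        label=str(meta["label"]),
        subject_id=str(meta.get("subject_id", path.stem)),
    )


def read_edf(path: str | Path, label: str = "", subject_id: str = "") -> Recording:
    """Read an EDF recording via mne (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "reading EDF files requires the optional dependency 'mne'"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        label=label,
        subject_id=subject_id or Path(path).stem,
    )


def write_cohort(recordings: list[Recording], out_dir: str | Path,
                 manifest_extra: dict | None = None) -> Path:
    """Write a cohort of recordings plus a JSON manifest; return the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        stem = rec.subject_id
        write_recording(rec, out_dir / stem)
        entries.append({
            "subject_id": rec.subject_id,
            "label": rec.label,
            "duration_s": rec.duration_s,
            "file": f"{stem}.tsv",
        })
    manifest = {"recordings": entries}
    if manifest_extra:
        manifest.update(manifest_extra)
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_cohort(directory: str | Path) -> list[Recording]:
    """Read every recording listed in a cohort manifest (or every .tsv/.edf)."""
    directory = Path(directory)
    mpath = directory / "manifest.json"
    recs: list[Recording] = []
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
        for entry in manifest["recordings"]:
            recs.append(read_recording(directory / entry["file"]))
    else:
        for f in sorted(directory.glob("*.tsv")) + sorted(directory.glob("*.edf")):
            recs.append(read_recording(f))
    if not recs:
        raise FileNotFoundError(f"no recordings found in {directory}")
    return recs
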