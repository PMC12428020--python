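"""Band-pass hygiene filtering and fixed-length epoch segmentation.

Recordings are cut into 30 s epochs with 50% overlap by default, the
sample unit of the classification task. Overlapping windows minimise
data loss on short clinical recordings at the cost of statistical
dependence between adjacent epochs (see the subject-wise split mode in
the pipeline for the leakage-free alternative).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .data import Epoch, Recording

logger = logging.getLogger(__name__)


def bandpass(recording: Recording, low: float = 0.5, high: float = 45.0,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of every channel.

    The filter is applied forward-backward (``sosfiltfilt``), doubling
    the effective order and cancelling phase distortion. Output
    dimensions are unchanged.
    """
    nyquist = recording.fs / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(f"high edge {high} Hz must be below Nyquist {nyquist} Hz")
    if recording.n_samples < 3 * order:
        raise ValueError("recording too short for the filter order")
    sos = sps.butter(order, [low, high], btype="bandpass",
                     fs=recording.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.data, axis=1)
    return Recording(
        data=filtered, fs=recording.fs,
        channel_names=recording.channel_names,
        label=recording.label, subject_id=recording.subject_id,
    )


def segment_epochs(recording: Recording, epoch_seconds: float = 30.0,
                   overlap_fraction: float = 0.5) -> list[Epoch]:
    """Cut a recording into overlapping fixed-length epochs.

    Windows are 0-based half-open ``[start, start + L)`` with
    ``L = round(epoch_seconds * fs)`` and stride
    ``S = round(epoch_seconds * (1 - overlap_fraction) * fs)``; the
    count is ``floor((N - L) / S) + 1``. Trailing samples that do not
    fill a full window are discarded. A recording shorter than one
    epoch yields an empty list with a logged warning (short recordings
    are skipped, not fatal).
    """
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    if epoch_seconds <= 0:
        raise ValueError("epoch_seconds must be positive")
    L = int(round(epoch_seconds * recording.fs))
    S = int(round(epoch_seconds * (1 - overlap_fraction) * recording.fs))
    if S < 1:
        raise ValueError("stride is below one sample; reduce the overlap")
    N = recording.n_samples
    if N < L:
        logger.warning(
            "recording %s (%.1f s) shorter than one %.0f s epoch; skipped",
            recording.subject_id, recording.duration_s, epoch_seconds)
        return []
    count = (N - L) // S + 1
    epochs = []
    for k in range(count):
        start = k * S
        epochs.append(Epoch(
            data=recording.data[:, start:start + L],
            fs=recording.fs,
            channel_names=recording.channel_names,
            label=recording.label,
            subject_id=recording.subject_id,
            epoch_index=k,
        ))
    return epochs


def segment_cohort(recordings: list[Recording], epoch_seconds: float = 30.0,
                   overlap_fraction: float = 0.5) -> list[Epoch]:
    """Segment every recording; short recordings contribute nothing."""
    out: list[Epoch] = []
    for rec in recordings:
        out.extend(segment_epochs(rec, epoch_seconds, overlap_fraction))
    return out
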