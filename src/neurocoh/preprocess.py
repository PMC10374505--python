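"""Recording I/O, epoch extraction and band-limiting.

The analysis contract downstream is: per subject, ten non-consecutive 2-s
epochs of periodic-discharge activity, sampled at 200 Hz on the 19
electrodes of the International 10-20 system. In clinical practice the
epochs are selected visually by electroencephalographers; here selection is
positional (evenly spaced with a minimum gap) by default, with a hook for a
custom selector.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sp_signal

from .bands import BandDefinition
from .synth import CHANNELS_1020, EEGRecording

__all__ = ["Epoch", "load_recording", "extract_epochs", "bandpass",
           "acquisition_bandpass"]


@dataclass
class Epoch:
    """One fixed-length analysis window of a recording."""

    data: np.ndarray  # channels x samples
    fs: float
    start_time: float
    subject_id: str
    group_label: str
    channel_labels: tuple[str, ...]
    duration: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (channels x samples)")
        expected = int(round(self.duration * self.fs))
        if self.data.shape[1] != expected:
            raise ValueError(
                f"epoch must span exactly {self.duration} s "
                f"({expected} samples at {self.fs} Hz); got {self.data.shape[1]}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("epoch contains non-finite samples")


def load_recording(
    path: str | Path,
    fmt: str | None = None,
    *,
    group_label: str = "",
    subject_id: str | None = None,
    precondition: bool = True,
) -> EEGRecording:
    """Load a recording from EDF or a numeric matrix with a JSON sidecar.

    Channels are reordered to the canonical 10-20 sequence (Fp1 ... O2) and
    non-EEG channels are dropped; a missing required electrode raises with
    its label. When ``precondition`` is true the acquisition-stage
    0.1-70 Hz bandpass is applied after loading.
    """
    from . import io as _io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if fmt == "edf":
        labels, fs, data, meta = _io.read_edf(path)
    elif fmt == "matrix":
        labels, fs, data, meta = _io.read_matrix(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    # resolve to canonical 10-20 order, dropping anything non-EEG
    lut = {lab.strip().lower(): i for i, lab in enumerate(labels)}
    # common synonyms between older and newer 10-20 nomenclature
    synonyms = {"t3": "t7", "t4": "t8", "t5": "p7", "t6": "p8"}
    for old, new in synonyms.items():
        if old not in lut and new in lut:
            lut[old] = lut[new]
    rows, missing = [], []
    for ch in CHANNELS_1020:
        idx = lut.get(ch.lower())
        if idx is None:
            missing.append(ch)
        else:
            rows.append(idx)
    if missing:
        raise ValueError(
            f"recording at {path} is missing required 10-20 electrode(s): "
            + ", ".join(missing)
        )
    data = np.asarray(data, dtype=float)[rows]
    rec = EEGRecording(
        channel_labels=CHANNELS_1020,
        fs=float(fs),
        data=data,
        group_label=group_label or meta.get("group_label", ""),
        subject_id=subject_id or meta.get("subject_id", path.stem),
    )
    if precondition:
        rec = acquisition_bandpass(rec)
    return rec


def acquisition_bandpass(
    rec: EEGRecording, low: float = 0.1, high: float = 70.0, order: int = 4
) -> EEGRecording:
    """Acquisition-stage broadband filter (default 0.1-70 Hz), zero-phase."""
    nyq = rec.fs / 2
    high = min(high, 0.99 * nyq)
    sos = sp_signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    data = sp_signal.sosfiltfilt(sos, rec.data, axis=1)
    return EEGRecording(
        channel_labels=rec.channel_labels, fs=rec.fs, data=data,
        group_label=rec.group_label, subject_id=rec.subject_id,
    )


def extract_epochs(
    rec: EEGRecording,
    n_epochs: int = 10,
    epoch_len: float = 2.0,
    min_gap: float = 1.0,
    selector: Callable[[EEGRecording, int, float, float], Sequence[float]] | None = None,
) -> list[Epoch]:
    """Extract ``n_epochs`` non-consecutive windows of ``epoch_len`` seconds.

    Windows are pairwise non-overlapping, separated by at least ``min_gap``
    seconds, and chronologically ordered. The default selector spaces them
    evenly over the recording; pass ``selector(rec, n, length, gap) ->
    start_times`` to plug in e.g. a discharge-triggered or visual-review
    selection.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    required = n_epochs * epoch_len + (n_epochs - 1) * min_gap
    if rec.duration + 1e-9 < required:
        raise ValueError(
            f"recording too short for {n_epochs} non-consecutive "
            f"{epoch_len}-s epochs with {min_gap}-s gaps: requires "
            f"{required:.1f} s, have {rec.duration:.1f} s"
        )
    if selector is None:
        if n_epochs == 1:
            starts: list[float] = [0.0]
        else:
            stride = (rec.duration - epoch_len) / (n_epochs - 1)
            starts = [i * stride for i in range(n_epochs)]
    else:
        starts = sorted(selector(rec, n_epochs, epoch_len, min_gap))
        if len(starts) != n_epochs:
            raise ValueError("selector returned the wrong number of start times")
        for a, b in zip(starts, starts[1:]):
            if b - (a + epoch_len) < min_gap - 1e-9:
                raise ValueError("selector returned overlapping or adjacent epochs")
    n_samp = int(round(epoch_len * rec.fs))
    epochs = []
    for t0 in starts:
        i0 = int(round(t0 * rec.fs))
        epochs.append(Epoch(
            data=rec.data[:, i0:i0 + n_samp], fs=rec.fs, start_time=i0 / rec.fs,
            subject_id=rec.subject_id, group_label=rec.group_label,
            channel_labels=rec.channel_labels, duration=epoch_len,
        ))
    return epochs


def bandpass(epoch: Epoch, band: BandDefinition, order: int = 4) -> Epoch:
    """Zero-phase band-limit an epoch to one analysis band.

    A Butterworth filter of the given order is applied forward and backward
    (zero phase distortion, squared magnitude response); output length
    equals input length.
    """
    band.validate_for_fs(epoch.fs)
    if band.high >= epoch.fs / 2:
        raise ValueError(
            f"band {band.name!r} upper edge {band.high} Hz must be below "
            f"Nyquist ({epoch.fs / 2} Hz) for filtering"
        )
    sos = sp_signal.butter(
        order, [band.low, band.high], btype="bandpass", fs=epoch.fs, output="sos"
    )
    data = sp_signal.sosfiltfilt(sos, epoch.data, axis=1)
    return Epoch(
        data=data, fs=epoch.fs, start_time=epoch.start_time,
        subject_id=epoch.subject_id, group_label=epoch.group_label,
        channel_labels=epoch.channel_labels, duration=epoch.duration,
    )
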