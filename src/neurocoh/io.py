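"""File formats: EDF, matrix + JSON sidecar, epoch arrays, adjacency CSV.

EDF reading goes through MNE. Writing uses a minimal EDF(+)-compatible
16-bit encoder implemented here (one data record per second, per-channel
physical scaling), sufficient for round-tripping synthetic scalp EEG.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import EEGRecording

__all__ = ["write_edf", "read_edf", "write_matrix", "read_matrix",
           "write_epochs", "read_epochs", "network_to_csv", "network_from_csv"]

_DIG_MAX = 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, rec: EEGRecording, *, phys_dim: str = "uV") -> Path:
    """Write a recording as 16-bit EDF, one data record per second.

    The sampling rate must be a positive integer; the signal is truncated
    to a whole number of seconds. Amplitude resolution is the per-channel
    peak value divided by 32767 (well below thermal EEG noise for
    microvolt-scale signals).
    """
    path = Path(path)
    fs = rec.fs
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(fs)
    n_ch = len(rec.channel_labels)
    n_records = rec.data.shape[1] // fs
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_records * fs]

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6) * (1 + 1e-4)
    scale = phys_max / _DIG_MAX
    digital = np.round(data / scale[:, None]).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad(f"X X X {rec.subject_id or 'X'}", 80),
        _pad(f"Startdate 01-JAN-2020 X X X {rec.group_label or 'X'}", 80),
        _pad("01.01.20", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    fields = []
    for spec, width in [
        ([f"EEG {ch}" for ch in rec.channel_labels], 16),
        (["" for _ in range(n_ch)], 80),
        ([phys_dim] * n_ch, 8),
        ([f"{-m:.6g}"[:8] for m in phys_max], 8),
        ([f"{m:.6g}"[:8] for m in phys_max], 8),
        ([str(-_DIG_MAX)] * n_ch, 8),
        ([str(_DIG_MAX)] * n_ch, 8),
        (["" for _ in range(n_ch)], 80),
        ([str(fs)] * n_ch, 8),
        (["" for _ in range(n_ch)], 32),
    ]:
        fields.append(b"".join(_pad(s, width) for s in spec))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        # records: channel-major within each 1-s record
        blocks = digital.reshape(n_ch, n_records, fs)
        fh.write(np.ascontiguousarray(blocks.transpose(1, 0, 2)).tobytes())
    return path


def read_edf(path: str | Path) -> tuple[list[str], float, np.ndarray, dict]:
    """Read an EDF file via MNE; returns (labels, fs, data_uV, meta)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = [ch.removeprefix("EEG ").strip() for ch in raw.ch_names]
    data = raw.get_data(units="uV")
    return labels, float(raw.info["sfreq"]), data, {}


def write_matrix(path: str | Path, rec: EEGRecording) -> Path:
    """Write a recording as a plain-text matrix plus a JSON sidecar.

    The matrix file holds one channel per row (whitespace-separated); the
    sidecar ``<path>.json`` records labels, sampling rate and identity.
    """
    path = Path(path)
    np.savetxt(path, rec.data, fmt="%.6e")
    sidecar = {
        "channel_labels": list(rec.channel_labels),
        "fs": rec.fs,
        "subject_id": rec.subject_id,
        "group_label": rec.group_label,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_matrix(path: str | Path) -> tuple[list[str], float, np.ndarray, dict]:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    data = np.loadtxt(path, ndmin=2)
    return list(meta["channel_labels"]), float(meta["fs"]), data, meta


def write_epochs(path: str | Path, epochs: list) -> Path:
    """Export epochs as a .npz (3-D array) with a JSON metadata sidecar."""
    path = Path(path)
    arr = np.stack([e.data for e in epochs])
    np.savez(path, data=arr)
    meta = {
        "fs": epochs[0].fs,
        "channel_labels": list(epochs[0].channel_labels),
        "subject_id": epochs[0].subject_id,
        "group_label": epochs[0].group_label,
        "start_times": [e.start_time for e in epochs],
        "duration": epochs[0].duration,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_epochs(path: str | Path) -> list:
    from .preprocess import Epoch

    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    arr = np.load(path if path.suffix == ".npz" else str(path) + ".npz")["data"]
    return [
        Epoch(
            data=arr[i], fs=meta["fs"], start_time=meta["start_times"][i],
            subject_id=meta["subject_id"], group_label=meta["group_label"],
            channel_labels=tuple(meta["channel_labels"]),
            duration=meta["duration"],
        )
        for i in range(arr.shape[0])
    ]


def network_to_csv(path: str | Path, net) -> Path:
    """Write an adjacency matrix as a labeled CSV (electrode rows/columns)."""
    df = pd.DataFrame(net.W, index=net.channel_labels, columns=net.channel_labels)
    df.to_csv(path)
    return Path(path)


def network_from_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return list(df.index), df.to_numpy(dtype=float)
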