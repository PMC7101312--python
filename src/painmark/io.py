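"""Readers and writers for sessions, epochs and reports.

Continuous recordings travel as EDF (European Data Format: 16-bit samples
with per-signal physical scaling, here µV at 500 Hz) plus JSON sidecars for
stimulation events and generator ground truth, and a CSV montage table.
EDF files are written by a small built-in encoder and read back through MNE,
so anything MNE can open (including real recordings) is accepted.  Epochs are
stored as an NPZ array bundle with a JSON metadata sidecar.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import numpy as np

from .montage import Montage
from .preprocess import Epochs
from .synth import ScheduleEvent

__all__ = [
    "write_edf",
    "write_session",
    "read_session",
    "write_epochs",
    "read_epochs",
    "write_montage_csv",
    "read_montage_csv",
]

_EDF_DATE = "01.01.00"  # fixed header date: outputs must be re-run stable
_EDF_TIME = "00.00.00"


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(
    path,
    data: np.ndarray,
    sampling_rate: float,
    channel_labels,
    physical_dim: str = "uV",
) -> None:
    """Write (n_channels, n_samples) physical data as EDF.

    Samples are scaled per-file to the 16-bit digital range; the tail is
    zero-padded to a whole number of 1 s data records.  Quantisation error is
    bounded by (physical range) / 65534.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be (n_channels, n_samples)")
    n_ch, n_samp = data.shape
    if len(channel_labels) != n_ch:
        raise ValueError("channel_labels must match the channel count")
    if sampling_rate <= 0 or sampling_rate != int(sampling_rate):
        raise ValueError("sampling rate must be a positive integer in Hz")
    spr = int(sampling_rate)  # samples per 1 s record
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data

    lim = float(np.max(np.abs(padded)))
    phys_max = max(np.ceil(lim), 1.0)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((padded - phys_min) * scale + dig_min).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate 01-JAN-2000 X X X", 80),
            _pad(_EDF_DATE, 8),
            _pad(_EDF_TIME, 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )
    fields = [
        b"".join(_pad(str(lb), 16) for lb in channel_labels),
        b"".join(_pad("", 80) for _ in range(n_ch)),
        b"".join(_pad(physical_dim, 8) for _ in range(n_ch)),
        b"".join(_pad(f"{phys_min:g}", 8) for _ in range(n_ch)),
        b"".join(_pad(f"{phys_max:g}", 8) for _ in range(n_ch)),
        b"".join(_pad(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(_pad(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(_pad("", 80) for _ in range(n_ch)),
        b"".join(_pad(str(spr), 8) for _ in range(n_ch)),
        b"".join(_pad("", 32) for _ in range(n_ch)),
    ]
    with open(path, "wb") as f:
        f.write(header)
        for fld in fields:
            f.write(fld)
        # data records: per record, all samples of signal 0, then signal 1, ...
        for r in range(n_rec):
            f.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def write_montage_csv(path, montage: Montage) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["label", "x", "y"])
        for lb, (x, y) in zip(montage.labels, montage.positions):
            w.writerow([lb, f"{x:.4f}", f"{y:.4f}"])


def read_montage_csv(path, groups: dict | None = None) -> Montage:
    labels, pos = [], []
    with open(path, newline="") as f:
        for row in csv.DictReader(f):
            labels.append(row["label"])
            pos.append([float(row["x"]), float(row["y"])])
    from .montage import DEFAULT_GROUPS

    if groups is None:
        groups = {
            name: members
            for name, members in DEFAULT_GROUPS.items()
            if all(m in labels for m in members)
        }
    return Montage(tuple(labels), np.asarray(pos), groups)


def write_session(
    out_dir,
    signal: np.ndarray,
    schedule,
    sidecar: dict,
    montage: Montage,
    sampling_rate: float,
) -> dict:
    """Write one session: EDF recording, events JSON, ground-truth JSON and
    montage CSV.  Returns the mapping of artifact names to paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "recording": out / "recording.edf",
        "events": out / "events.json",
        "ground_truth": out / "ground_truth.json",
        "montage": out / "montage.csv",
    }
    write_edf(paths["recording"], signal, sampling_rate, montage.labels)
    events = [
        {
            "onset_s": ev.onset_s,
            "condition": ev.condition,
            "train_duration_s": ev.train_duration_s,
        }
        for ev in schedule.events
    ]
    paths["events"].write_text(json.dumps(events, indent=1))
    paths["ground_truth"].write_text(json.dumps(sidecar, indent=1, default=float))
    write_montage_csv(paths["montage"], montage)
    return {k: str(v) for k, v in paths.items()}


def read_session(session_dir) -> tuple[np.ndarray, list[ScheduleEvent], Montage, float]:
    """Load a session directory written by :func:`write_session`.

    Returns (signal µV, events sorted by onset, montage, sampling_rate).
    Raises if the montage does not cover the recorded channels.
    """
    import mne

    d = Path(session_dir)
    raw = mne.io.read_raw_edf(d / "recording.edf", preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # MNE returns volts
    fs = float(raw.info["sfreq"])
    montage = read_montage_csv(d / "montage.csv")
    missing = [ch for ch in raw.ch_names if ch not in montage.labels]
    extra = [lb for lb in montage.labels if lb not in raw.ch_names]
    if missing or extra:
        raise ValueError(
            f"montage mismatch: recording-only channels {missing}, "
            f"montage-only channels {extra}"
        )
    order = [raw.ch_names.index(lb) for lb in montage.labels]
    signal = signal[order]
    events_raw = json.loads((d / "events.json").read_text())
    events = sorted(
        (
            ScheduleEvent(e["onset_s"], e["condition"], e["train_duration_s"])
            for e in events_raw
        ),
        key=lambda e: e.onset_s,
    )
    return signal, events, montage, fs


def write_epochs(out_dir, epochs: Epochs) -> dict:
    """Persist epochs as an NPZ array bundle plus JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    npz = out / "epochs.npz"
    meta = out / "epochs.json"
    np.savez_compressed(npz, data=epochs.data, kept_mask=epochs.kept_mask)
    meta.write_text(
        json.dumps(
            {
                "sampling_rate": epochs.sampling_rate,
                "t_start_ms": epochs.t_start_ms,
                "labels": list(epochs.labels),
                "channel_labels": list(epochs.channel_labels),
            },
            indent=1,
        )
    )
    return {"epochs": str(npz), "meta": str(meta)}


def read_epochs(in_dir) -> Epochs:
    d = Path(in_dir)
    arrays = np.load(d / "epochs.npz")
    meta = json.loads((d / "epochs.json").read_text())
    return Epochs(
        data=arrays["data"],
        sampling_rate=meta["sampling_rate"],
        t_start_ms=meta["t_start_ms"],
        labels=list(meta["labels"]),
        channel_labels=tuple(meta["channel_labels"]),
        kept_mask=arrays["kept_mask"],
    )


def report_to_json(obj) -> object:
    """Recursively convert report dataclasses/arrays to JSON-serialisable
    structures."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: report_to_json(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): report_to_json(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [report_to_json(v) for v in obj]
    return obj
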