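"""Signal conditioning for evoked-potential analysis.

Band-pass (0.5-70 Hz Butterworth, applied forward-backward so component
latencies are preserved) and 60 Hz notch filtering, event-locked epoching,
pre-stimulus baseline correction, peak-to-peak artifact rejection, condition
averaging, and the 2 s -> 2 x 1 s training-set augmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "Epochs",
    "Evoked",
    "RejectionReport",
    "bandpass",
    "notch",
    "epoch",
    "baseline_correct",
    "reject_artifacts",
    "average_evoked",
    "augment_split",
]


@dataclass
class Epochs:
    """Event-locked EEG segments: (n_trials, n_channels, n_samples) in µV."""

    data: np.ndarray
    sampling_rate: float
    t_start_ms: float  # time of the first sample relative to event onset
    labels: list[str]
    channel_labels: tuple[str, ...]
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epochs data must be (trials, channels, samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels must match channel count")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.n_samples) / self.sampling_rate * 1e3

    def kept(self) -> "Epochs":
        """View restricted to trials that survived rejection."""
        m = self.kept_mask
        return Epochs(
            self.data[m],
            self.sampling_rate,
            self.t_start_ms,
            [lb for lb, k in zip(self.labels, m) if k],
            self.channel_labels,
        )

    def copy(self) -> "Epochs":
        return Epochs(
            self.data.copy(),
            self.sampling_rate,
            self.t_start_ms,
            list(self.labels),
            self.channel_labels,
            self.kept_mask.copy(),
        )


@dataclass
class Evoked:
    """Per-condition trial average: (n_channels, n_samples) in µV."""

    condition: str
    data: np.ndarray
    n_trials_averaged: int
    sampling_rate: float
    t_start_ms: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.n_trials_averaged < 1:
            raise ValueError("n_trials_averaged must be >= 1")

    def times_ms(self) -> np.ndarray:
        return self.t_start_ms + np.arange(self.data.shape[1]) / self.sampling_rate * 1e3


@dataclass(frozen=True)
class RejectionReport:
    """Which trials were rejected, and the offending channel/value of each."""

    threshold_uv: float
    rejected: tuple[int, ...]
    worst_channel: tuple[str, ...]
    worst_value_uv: tuple[float, ...]


def _as_2d(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def bandpass(
    x: np.ndarray,
    sampling_rate: float,
    low_hz: float = 0.5,
    high_hz: float = 70.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    The filter is designed at the stated order and applied forward-backward
    (``sosfiltfilt``), which squares the magnitude response; pass-band gain
    remains ~1 and phase is exactly zero, preserving latencies.
    """
    nyq = sampling_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"band edges must satisfy 0 < {low_hz} < {high_hz} < {nyq}")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=sampling_rate,
                     output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def notch(
    x: np.ndarray, sampling_rate: float, f0_hz: float = 60.0, q: float = 30.0
) -> np.ndarray:
    """Zero-phase IIR notch at ``f0_hz`` (quality ``q``) along the last axis."""
    if not (0 < f0_hz < sampling_rate / 2.0):
        raise ValueError(f"notch frequency {f0_hz} outside (0, Nyquist)")
    b, a = sps.iirnotch(f0_hz, q, fs=sampling_rate)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float), axis=-1)


def epoch(
    signal: np.ndarray,
    sampling_rate: float,
    events,
    channel_labels,
    t_start_ms: float = -500.0,
    t_end_ms: float = 1000.0,
) -> Epochs:
    """Slice the continuous recording into event-locked epochs.

    Each event contributes the half-open window ``[onset + t_start, onset +
    t_end)``.  Events whose window falls outside the recording are skipped
    with a warning (and reported in the log), never silently dropped.

    ``events`` is an iterable of objects with ``onset_s`` and ``condition``
    attributes (e.g. :class:`painmark.synth.ScheduleEvent`) or of
    ``(onset_s, condition)`` pairs.
    """
    signal = np.asarray(signal, dtype=float)
    if t_end_ms <= t_start_ms:
        raise ValueError("t_end_ms must exceed t_start_ms")
    n_samp = int(round((t_end_ms - t_start_ms) / 1000.0 * sampling_rate))
    offset = int(round(t_start_ms / 1000.0 * sampling_rate))
    slices, labels = [], []
    for ev in events:
        if hasattr(ev, "onset_s"):
            onset, cond = ev.onset_s, ev.condition
        else:
            onset, cond = ev[0], ev[1]
        start = int(round(onset * sampling_rate)) + offset
        stop = start + n_samp
        if start < 0 or stop > signal.shape[-1]:
            warnings.warn(
                f"event at {onset:.3f}s ({cond}) too close to the recording edge; "
                "skipped",
                stacklevel=2,
            )
            continue
        slices.append(signal[:, start:stop])
        labels.append(cond)
    if not slices:
        raise ValueError("no event window lies inside the recording")
    return Epochs(
        np.stack(slices), sampling_rate, t_start_ms, labels, tuple(channel_labels)
    )


def baseline_correct(epochs: Epochs) -> Epochs:
    """Subtract each trial/channel's pre-stimulus mean (over [t_start, 0))."""
    if epochs.t_start_ms >= 0:
        raise ValueError("no pre-stimulus samples to form a baseline")
    n_pre = int(round(-epochs.t_start_ms / 1000.0 * epochs.sampling_rate))
    n_pre = min(n_pre, epochs.n_samples)
    if n_pre < 1:
        raise ValueError("no pre-stimulus samples to form a baseline")
    base = epochs.data[:, :, :n_pre].mean(axis=2, keepdims=True)
    out = epochs.copy()
    out.data = epochs.data - base
    return out


def reject_artifacts(
    epochs: Epochs, peak_to_peak_max_uv: float = 150.0
) -> tuple[Epochs, RejectionReport]:
    """Flag trials whose peak-to-peak amplitude exceeds the threshold.

    A trial is rejected iff *any* channel's max-minus-min within the epoch
    exceeds ``peak_to_peak_max_uv``.  Idempotent: the kept mask is recomputed
    from the data, and already-rejected trials stay rejected.
    """
    if peak_to_peak_max_uv <= 0:
        raise ValueError("peak-to-peak threshold must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (trials, channels)
    worst = ptp.argmax(axis=1)
    worst_val = ptp[np.arange(epochs.n_trials), worst]
    bad = worst_val > peak_to_peak_max_uv
    out = epochs.copy()
    out.kept_mask = epochs.kept_mask & ~bad
    rejected = np.flatnonzero(bad)
    report = RejectionReport(
        threshold_uv=peak_to_peak_max_uv,
        rejected=tuple(int(i) for i in rejected),
        worst_channel=tuple(epochs.channel_labels[worst[i]] for i in rejected),
        worst_value_uv=tuple(float(worst_val[i]) for i in rejected),
    )
    if not out.kept_mask.any():
        warnings.warn("all trials rejected", stacklevel=2)
    return out, report


def average_evoked(epochs: Epochs, condition: str) -> Evoked:
    """Arithmetic mean over kept trials of one condition."""
    sel = epochs.kept_mask & np.array([lb == condition for lb in epochs.labels])
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"no kept trials of condition {condition!r}")
    return Evoked(
        condition=condition,
        data=epochs.data[sel].mean(axis=0),
        n_trials_averaged=n,
        sampling_rate=epochs.sampling_rate,
        t_start_ms=epochs.t_start_ms,
        channel_labels=epochs.channel_labels,
    )


def augment_split(epochs: Epochs) -> Epochs:
    """Split each 2 s post-onset trial into two 1 s segments.

    Input epochs must cover [0, 2000) ms post-onset (a pre-stimulus span is
    allowed and ignored).  Each trial yields the segments [0, 1000) and
    [1000, 2000) with its label duplicated, doubling the trial count.
    Concatenating a trial's two output segments reproduces its post-onset
    samples exactly.  Baseline correction, if any, is inherited from the
    parent trial (segments are plain slices).
    """
    fs = epochs.sampling_rate
    if epochs.t_start_ms > 0:
        raise ValueError("augmentation requires epochs starting at or before 0 ms")
    end_ms = epochs.t_start_ms + epochs.n_samples / fs * 1000.0
    if end_ms < 2000.0 - 1e-6:
        raise ValueError("augmentation requires epochs spanning [0, 2000) ms")
    i0 = int(round(-epochs.t_start_ms / 1000.0 * fs))
    n_seg = int(round(1.0 * fs))
    kept = epochs.kept()
    first = kept.data[:, :, i0 : i0 + n_seg]
    second = kept.data[:, :, i0 + n_seg : i0 + 2 * n_seg]
    # interleave: trial i -> output rows 2i (first second) and 2i+1 (second)
    data = np.stack([first, second], axis=1).reshape(
        2 * kept.n_trials, kept.n_channels, n_seg
    )
    labels = [lb for lb in kept.labels for _ in range(2)]
    return Epochs(data, fs, 0.0, labels, epochs.channel_labels)
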