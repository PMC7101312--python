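"""Max-amplitude feature extraction over 100 ms post-stimulus windows.

The decoding feature of a trial is, per channel, the maximum (signed, by
default) voltage within a fixed 100 ms window, giving one 64-dimensional
vector per trial.  "Signed" keeps positive enhancements distinct from
negative depressions; an absolute-value variant is available via ``mode``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Epochs

__all__ = ["TimeWindow", "FeatureMatrix", "window_grid", "max_amplitude_features"]


@dataclass(frozen=True)
class TimeWindow:
    """Half-open [start, end) window in ms post-stimulus."""

    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_ms < self.end_ms):
            raise ValueError(f"need 0 <= start < end, got [{self.start_ms}, {self.end_ms})")

    @property
    def width_ms(self) -> float:
        return self.end_ms - self.start_ms

    def __str__(self) -> str:
        return f"[{self.start_ms:g}, {self.end_ms:g}) ms"


@dataclass
class FeatureMatrix:
    """(n_trials, n_channels) feature values with their labels and window."""

    values: np.ndarray
    window: TimeWindow
    channel_labels: tuple[str, ...]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.channel_labels)):
            raise ValueError("feature matrix shape must be (trials, channels)")


def window_grid(
    start_ms: float = 50.0, stop_ms: float = 950.0, width_ms: float = 100.0
) -> list[TimeWindow]:
    """Consecutive non-overlapping windows covering [start, stop).

    ``width`` must divide the span exactly; the default grid is the nine
    100 ms windows [50, 150), [150, 250), ..., [850, 950).
    """
    span = stop_ms - start_ms
    n = span / width_ms
    if span <= 0 or abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"window width {width_ms} must divide the span [{start_ms}, {stop_ms})"
        )
    return [
        TimeWindow(start_ms + k * width_ms, start_ms + (k + 1) * width_ms)
        for k in range(int(round(n)))
    ]


def max_amplitude_features(
    epochs: Epochs, window: TimeWindow, mode: str = "max"
) -> FeatureMatrix:
    """Per-trial, per-channel maximum over the window's samples.

    ``mode="max"`` takes the signed maximum; ``mode="absmax"`` the value of
    largest magnitude.  Only kept trials contribute rows.
    """
    if mode not in ("max", "absmax"):
        raise ValueError(f"unknown mode {mode!r}")
    fs = epochs.sampling_rate
    i0 = int(round((window.start_ms - epochs.t_start_ms) / 1000.0 * fs))
    i1 = int(round((window.end_ms - epochs.t_start_ms) / 1000.0 * fs))
    if i0 < 0 or i1 > epochs.n_samples:
        raise ValueError(f"window {window} outside the epoch span")
    if i1 <= i0:
        raise ValueError(f"window {window} contains no samples")
    kept = epochs.kept()
    seg = kept.data[:, :, i0:i1]
    if mode == "max":
        values = seg.max(axis=2)
    else:
        idx = np.abs(seg).argmax(axis=2)
        values = np.take_along_axis(seg, idx[:, :, None], axis=2)[:, :, 0]
    return FeatureMatrix(values, window, epochs.channel_labels, list(kept.labels))
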