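"""Global field power, spatio-temporal peak detection and group statistics.

Global field power (GFP) is the spatial standard deviation of the potential
map at each time sample,

    GFP(t) = sqrt( (1/N) * sum_i (u_i(t) - u_bar(t))^2 ),

a reference-free summary of momentary field strength (high GFP marks peak
evoked activity and steep topographic gradients).  Peak detection returns the
channel, latency and amplitude of the extremal value in a spatio-temporal
slab of an evoked response.  The statistical battery is the nonparametric
chain appropriate for non-normal per-trial amplitude samples: one-sample
Kolmogorov-Smirnov normality check, Mann-Whitney U, Kruskal-Wallis across
conditions, and Tukey-HSD post-hoc comparisons on rank-transformed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sst

from .features import TimeWindow
from .preprocess import Evoked

__all__ = [
    "GFPSeries",
    "PeakInfo",
    "StatReport",
    "gfp",
    "find_peak",
    "topomap_values",
    "ks_normality",
    "mann_whitney",
    "kruskal_wallis",
    "posthoc_pairwise",
]


@dataclass
class GFPSeries:
    """Non-negative GFP (µV) per time sample of an evoked response."""

    values: np.ndarray
    sampling_rate: float
    t_start_ms: float
    condition: str = ""

    def times_ms(self) -> np.ndarray:
        return self.t_start_ms + np.arange(len(self.values)) / self.sampling_rate * 1e3

    def mean_post_stimulus(self) -> float:
        """Mean GFP over t >= 0."""
        return float(self.values[self.times_ms() >= 0].mean())


@dataclass(frozen=True)
class PeakInfo:
    channel: str
    latency_ms: float
    amplitude_uv: float


@dataclass
class StatReport:
    """One test's outcome, with pairwise post-hoc p-values where relevant."""

    test: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    pairwise_p: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def gfp(evoked: Evoked) -> GFPSeries:
    """Spatial standard deviation of the potential map at each time sample."""
    data = evoked.data
    if data.shape[0] < 2:
        raise ValueError("GFP requires at least two channels")
    values = data.std(axis=0, ddof=0)  # sqrt(mean((u_i - u_bar)^2))
    return GFPSeries(
        values=values,
        sampling_rate=evoked.sampling_rate,
        t_start_ms=evoked.t_start_ms,
        condition=evoked.condition,
    )


def find_peak(
    evoked: Evoked,
    window: TimeWindow | None = None,
    channels=None,
    mode: str = "max",
) -> PeakInfo:
    """Channel/latency/amplitude of the extremum in a spatio-temporal slab.

    ``window`` restricts the search in time (half-open, ms post-stimulus;
    default: all t >= 0), ``channels`` restricts it to a subset of labels.
    ``mode="max"`` finds the signed maximum, ``"absmax"`` the largest
    magnitude.  Ties resolve to the earliest latency, then the lowest channel
    index.
    """
    if mode not in ("max", "absmax"):
        raise ValueError(f"unknown mode {mode!r}")
    fs = evoked.sampling_rate
    times = evoked.times_ms()
    if window is None:
        t_mask = times >= 0
    else:
        t_mask = (times >= window.start_ms - 1e-9) & (times < window.end_ms - 1e-9)
    t_idx = np.flatnonzero(t_mask)
    if t_idx.size == 0:
        raise ValueError("the time window contains no samples")
    if channels is None:
        ch_idx = np.arange(len(evoked.channel_labels))
    else:
        lookup = {lb: i for i, lb in enumerate(evoked.channel_labels)}
        try:
            ch_idx = np.array([lookup[lb] for lb in channels], dtype=int)
        except KeyError as err:
            raise KeyError(f"channel {err.args[0]!r} not in evoked") from None
        if ch_idx.size == 0:
            raise ValueError("channel subset is empty")
    slab = evoked.data[np.ix_(ch_idx, t_idx)]
    score = np.abs(slab) if mode == "absmax" else slab
    # argmax over time-major order -> earliest latency wins ties, then lowest
    # channel index (ch_idx is in montage order)
    flat = np.argmax(score.T)  # transpose: time-major
    t_i, c_i = np.unravel_index(flat, score.T.shape)
    return PeakInfo(
        channel=evoked.channel_labels[ch_idx[c_i]],
        latency_ms=float(times[t_idx[t_i]]),
        amplitude_uv=float(slab[c_i, t_i]),
    )


def topomap_values(evoked: Evoked, latency_ms: float) -> np.ndarray:
    """Per-channel values at the sample nearest to ``latency_ms``."""
    times = evoked.times_ms()
    if latency_ms < times[0] - 1e-9 or latency_ms > times[-1] + 1e-9:
        raise ValueError(f"latency {latency_ms} ms outside the evoked span")
    idx = int(np.argmin(np.abs(times - latency_ms)))
    return evoked.data[:, idx].copy()


def ks_normality(sample) -> StatReport:
    """One-sample Kolmogorov-Smirnov test of the standardised sample against
    the standard normal distribution."""
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample")
    z = (x - x.mean()) / sd
    stat, p = sst.kstest(z, "norm")
    return StatReport("ks_normality", float(stat), float(p), (x.size,))


def mann_whitney(a, b) -> StatReport:
    """Two-sided Mann-Whitney U with midrank ties, normal approximation and
    continuity correction.  The reported statistic is U of the first sample."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sst.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return StatReport("mann_whitney", float(res.statistic), float(res.pvalue),
                      (a.size, b.size))


def kruskal_wallis(groups) -> StatReport:
    """Kruskal-Wallis H with tie correction; p from chi-square(k-1).

    Degenerate input with every value identical yields H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return StatReport("kruskal_wallis", 0.0, 1.0, tuple(g.size for g in groups))
    stat, p = sst.kruskal(*groups)
    return StatReport("kruskal_wallis", float(stat), float(p),
                      tuple(g.size for g in groups))


def posthoc_pairwise(groups, use_ranks: bool = True) -> StatReport:
    """Tukey HSD pairwise comparisons following a Kruskal-Wallis test.

    By default the HSD is applied to the pooled rank-transformed data, which
    respects the nonparametric setting of the omnibus test; ``use_ranks=False``
    applies plain Tukey HSD to the raw values.  The reported statistic/p-value
    are those of the omnibus Kruskal-Wallis test; ``pairwise_p`` is the
    symmetric matrix of pairwise p-values (unit diagonal).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("post-hoc comparison needs >= 3 groups")
    omnibus = kruskal_wallis(groups)
    if use_ranks:
        pooled = np.concatenate(groups)
        ranks = sst.rankdata(pooled)
        out, i = [], 0
        for g in groups:
            out.append(ranks[i : i + g.size])
            i += g.size
        test_groups = out
    else:
        test_groups = groups
    if all(np.all(g == g[0]) for g in test_groups) and len(
        {g[0] for g in test_groups}
    ) == 1:
        pair = np.ones((len(groups), len(groups)))
    else:
        res = sst.tukey_hsd(*test_groups)
        pair = np.asarray(res.pvalue, dtype=float)
        np.fill_diagonal(pair, 1.0)
    return StatReport(
        "kruskal_wallis+tukey_hsd" + ("_ranks" if use_ranks else ""),
        omnibus.statistic,
        omnibus.p_value,
        tuple(g.size for g in groups),
        pairwise_p=pair,
    )
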