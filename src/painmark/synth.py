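"""Synthetic evoked-EEG session generator.

Emulates a phantom-limb stimulation experiment: blocks of transcutaneous
electrical nerve stimulation (TENS) pulse trains in three graded conditions —
innocuous (INNO), moderately intense (MOD) and noxious (NOX) — recorded with a
64-channel extended 10-20 montage at 500 Hz.  Each condition plants a known
spatio-temporal evoked pattern on top of 1/f ("pink") background noise, white
sensor noise and an optional common-phase 60 Hz line component:

* all conditions evoke an early parietal response (~54 ms Gaussian bump);
* MOD adds a sustained parietal plateau plus a late parietal hump, strongest
  in the P2/P4/P6 group;
* NOX adds a central (Cz/C4/C6) plateau in the 450-750 ms window topped by a
  late hump, making the vertex the spatio-temporal maximum.

The evoked kernel of a condition is defined over one 1 s cycle and repeated
once per second of the 2 s pulse train, i.e. the response is modelled as
steady-state over the sustained stimulation.  Every planted component is
recorded in a ground-truth sidecar so downstream stages can be tested against
exactly what was injected rather than against assumptions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage, default_montage

__all__ = [
    "StimulationCondition",
    "ScheduleEvent",
    "StimulationSchedule",
    "TemplateComponent",
    "EvokedTemplate",
    "GeneratorConfig",
    "CONDITIONS",
    "CONDITION_ORDER",
    "build_schedule",
    "central_selection_config",
    "make_template",
    "default_templates",
    "generate_background",
    "generate_session",
]

CONDITION_ORDER: tuple[str, ...] = ("INNO", "MOD", "NOX")


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class StimulationCondition:
    """A TENS stimulation condition (pulse width, rate, current)."""

    name: str
    pulse_width_ms: float
    frequency_hz: float
    amplitude_ma: float = 1.6


#: The three graded stimulation conditions of the experiment.
CONDITIONS: dict[str, StimulationCondition] = {
    "INNO": StimulationCondition("INNO", pulse_width_ms=1.0, frequency_hz=45.0),
    "MOD": StimulationCondition("MOD", pulse_width_ms=5.0, frequency_hz=4.0),
    "NOX": StimulationCondition("NOX", pulse_width_ms=20.0, frequency_hz=20.0),
}


@dataclass(frozen=True)
class ScheduleEvent:
    onset_s: float
    condition: str
    train_duration_s: float


@dataclass(frozen=True)
class StimulationSchedule:
    """Ordered stimulation events grouped into per-condition blocks."""

    events: tuple[ScheduleEvent, ...]
    #: per block: (condition name, tuple of event indices)
    blocks: tuple[tuple[str, tuple[int, ...]], ...]

    def __len__(self) -> int:
        return len(self.events)

    def onsets(self) -> np.ndarray:
        return np.array([e.onset_s for e in self.events])

    def labels(self) -> list[str]:
        return [e.condition for e in self.events]

    def condition_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            out[e.condition] = out.get(e.condition, 0) + 1
        return out


@dataclass(frozen=True)
class TemplateComponent:
    """One spatio-temporal evoked component.

    The temporal kernel is either a Gaussian bump (``centre_ms`` ±
    ``width_ms`` interpreted as one standard deviation) or a plateau of total
    width ``width_ms`` centred on ``centre_ms`` with raised-cosine edges.
    Spatial weights fall off with squared scalp distance from ``centre_channel``
    and are zero outside ``group`` channels.
    """

    group: str
    centre_channel: str
    centre_ms: float
    width_ms: float
    amplitude_uv: float
    shape: str = "gaussian"  # or "plateau"
    spatial_scale: float = 0.3
    edge_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "plateau"):
            raise ConfigError(f"unknown kernel shape {self.shape!r}")
        # amplitude may be negative: a depression (blue topography)
        if self.width_ms <= 0 or self.spatial_scale <= 0:
            raise ConfigError("component widths must be positive")

    def spatial_weights(self, montage: Montage) -> np.ndarray:
        """Unitless weights in [0, 1]; zero outside the component's group."""
        d = montage.distances_from(self.centre_channel)
        w = np.exp(-((d / self.spatial_scale) ** 2))
        mask = np.zeros(montage.n_channels)
        mask[montage.group_indices(self.group)] = 1.0
        return w * mask

    def kernel(self, t_ms: np.ndarray) -> np.ndarray:
        """Temporal kernel in µV; identically zero for t < 0."""
        t = np.asarray(t_ms, dtype=float)
        if self.shape == "gaussian":
            k = self.amplitude_uv * np.exp(
                -((t - self.centre_ms) ** 2) / (2.0 * self.width_ms**2)
            )
        else:
            half = self.width_ms / 2.0
            lo, hi = self.centre_ms - half, self.centre_ms + half
            k = np.zeros_like(t)
            inside = (t >= lo) & (t <= hi)
            k[inside] = 1.0
            if self.edge_ms > 0:
                rise = (t >= lo) & (t < lo + self.edge_ms)
                fall = (t > hi - self.edge_ms) & (t <= hi)
                k[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - lo) / self.edge_ms))
                k[fall] = 0.5 * (1 - np.cos(np.pi * (hi - t[fall]) / self.edge_ms))
            k *= self.amplitude_uv
        return np.where(t < 0, 0.0, k)


@dataclass(frozen=True)
class EvokedTemplate:
    """Per-condition evoked pattern: a sum of spatio-temporal components."""

    condition: str
    components: tuple[TemplateComponent, ...]
    cycle_ms: float = 1000.0

    def render(self, montage: Montage, sampling_rate: float) -> np.ndarray:
        """Noiseless (n_channels, n_samples) pattern over one cycle."""
        n = int(round(self.cycle_ms / 1000.0 * sampling_rate))
        t_ms = np.arange(n) / sampling_rate * 1000.0
        out = np.zeros((montage.n_channels, n))
        for comp in self.components:
            out += np.outer(comp.spatial_weights(montage), comp.kernel(t_ms))
        return out

    def peak(self, montage: Montage, sampling_rate: float) -> tuple[str, float, float]:
        """(channel, latency_ms, amplitude) of the rendered spatio-temporal max."""
        rendered = self.render(montage, sampling_rate)
        ch, samp = np.unravel_index(np.argmax(rendered), rendered.shape)
        return montage.labels[ch], samp / sampling_rate * 1000.0, rendered[ch, samp]


# calibrated default component amplitudes (µV); negative = depression
_DEFAULT_AMPS: dict[str, dict[str, float]] = {
    "INNO": {"early": 4.0, "parietal_plateau": 0.6,
             "central_plateau": 0.0, "central_hump": 0.0},
    "MOD": {"early": 7.0, "parietal_plateau": 1.5,
            "central_plateau": 0.0, "central_hump": -9.0},
    "NOX": {"early": 4.5, "parietal_plateau": 0.0,
            "central_plateau": 6.5, "central_hump": 13.0},
}


def make_template(
    condition: StimulationCondition | str,
    montage: Montage,
    *,
    early_uv: float | None = None,
    parietal_plateau_uv: float | None = None,
    central_plateau_uv: float | None = None,
    central_hump_uv: float | None = None,
    cycle_ms: float = 1000.0,
) -> EvokedTemplate:
    """Build the default evoked template for one stimulation condition.

    Every condition carries the early parietal bump (Gaussian at 54 ms);
    INNO and MOD add a sustained parietal plateau (100-950 ms, MOD's larger);
    MOD adds a central *depression* (negative plateau 450-750 ms plus a
    negative hump at 700 ms); NOX adds the central plateau 450-750 ms topped
    by a 700 ms hump, making Cz its spatio-temporal maximum.  Amplitude
    overrides scale or remove (0) single components; ``None`` keeps the
    calibrated defaults:

    ========= ===== ================ =============== ============
    condition early parietal plateau central plateau central hump
    ========= ===== ================ =============== ============
    INNO      4.0   0.6              --              --
    MOD       7.0   1.5              --              -9.0 (wide)
    NOX       4.5   --               6.5             13.0
    ========= ===== ================ =============== ============
    """
    name = condition if isinstance(condition, str) else condition.name
    if name not in CONDITION_ORDER:
        raise ConfigError(f"unknown condition {name!r}")
    amps = dict(_DEFAULT_AMPS[name])
    for key, val in (
        ("early", early_uv),
        ("parietal_plateau", parietal_plateau_uv),
        ("central_plateau", central_plateau_uv),
        ("central_hump", central_hump_uv),
    ):
        if val is not None:
            amps[key] = val

    comps: list[TemplateComponent] = []
    if amps["early"] != 0:
        comps.append(
            TemplateComponent("parietal", "P4", 54.0, 12.0, amps["early"],
                              "gaussian", 0.3)
        )
    if amps["parietal_plateau"] != 0:
        comps.append(
            TemplateComponent("parietal", "P4", 525.0, 850.0,
                              amps["parietal_plateau"], "plateau", 0.3)
        )
    if amps["central_plateau"] != 0:
        comps.append(
            TemplateComponent("central", "Cz", 600.0, 300.0,
                              amps["central_plateau"], "plateau", 0.8)
        )
    if amps["central_hump"] != 0:
        # the MOD depression is wide (sigma 60 ms) so the signed window max
        # stays deeply negative across a 100 ms window; the NOX activation
        # is a sharper peak (sigma 30 ms)
        width = 60.0 if amps["central_hump"] < 0 else 30.0
        comps.append(
            TemplateComponent("central", "Cz", 700.0, width,
                              amps["central_hump"], "gaussian", 0.8)
        )
    return EvokedTemplate(condition=name, components=tuple(comps), cycle_ms=cycle_ms)


def default_templates(montage: Montage) -> dict[str, EvokedTemplate]:
    return {name: make_template(name, montage) for name in CONDITION_ORDER}


def central_selection_config(
    seed: int,
    amplitude_uv: float = 3.0,
    blocks_per_condition: int = 24,
) -> "GeneratorConfig":
    """Controlled benchmark for channel-selection recovery.

    Plants discriminative signal *only* on the central group {Cz, C4, C6}
    (near-uniform weights): NOX carries a +amplitude 700 ms bump, MOD the
    mirrored depression, INNO nothing.  Sessions use short (1 s) trains with
    1 s gaps and white sensor noise, giving many trials per condition so the
    greedy selector's cross-validated gains dominate selection luck.  A
    correct selector must place all three central channels among its picks.
    """
    montage = default_montage()

    def probe(amp: float) -> EvokedTemplate:
        if amp == 0:
            return EvokedTemplate("INNO", ())
        comp = TemplateComponent(
            "central", "Cz", 700.0, 30.0, amp, "gaussian", spatial_scale=10.0
        )
        return EvokedTemplate("probe", (comp,))

    templates = {
        "INNO": probe(0.0),
        "MOD": probe(-amplitude_uv),
        "NOX": probe(+amplitude_uv),
    }
    return GeneratorConfig(
        seed=seed,
        montage=montage,
        templates=templates,
        pink_uv=0.0,
        white_uv=3.2,
        blocks_per_condition=blocks_per_condition,
        train_duration_s=1.0,
        mean_delay_s=1.0,
        inter_block_gap_s=1.0,
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to synthesise one recording session."""

    sampling_rate: float = 500.0
    montage: Montage = field(default_factory=default_montage)
    conditions: tuple[str, ...] = CONDITION_ORDER
    templates: dict[str, EvokedTemplate] | None = None  # None -> defaults
    pink_uv: float = 3.0  # RMS of the 1/f background per channel
    pink_spatial_scale: float = 0.25  # correlation length of the 1/f field
    pink_knee_hz: float = 1.0  # spectrum flattens below this frequency
    white_uv: float = 1.0  # RMS of white sensor noise per channel
    line_uv: float = 1.0  # amplitude of the common-phase 60 Hz component
    line_freq: float = 60.0
    trains_per_block: int = 5
    blocks_per_condition: int = 4
    train_duration_s: float = 2.0
    mean_delay_s: float = 4.0
    jitter: float = 0.25
    inter_block_gap_s: float = 5.0
    lead_in_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.pink_uv, self.white_uv, self.line_uv) < 0:
            raise ConfigError("noise amplitudes must be >= 0")
        if self.pink_spatial_scale < 0:
            raise ConfigError("pink_spatial_scale must be >= 0")
        if not (0 <= self.jitter < 1):
            raise ConfigError("jitter fraction must lie in [0, 1)")
        if self.trains_per_block < 1 or self.blocks_per_condition < 1:
            raise ConfigError("need at least one train per block and one block")
        if min(self.train_duration_s, self.mean_delay_s, self.sampling_rate) <= 0:
            raise ConfigError("durations, delays and rate must be positive")
        if self.inter_block_gap_s < 0 or self.lead_in_s < 0:
            raise ConfigError("gaps must be >= 0")
        unknown = [c for c in self.conditions if c not in CONDITION_ORDER]
        if unknown:
            raise ConfigError(f"unknown conditions {unknown}")

    def resolved_templates(self) -> dict[str, EvokedTemplate]:
        if self.templates is not None:
            return dict(self.templates)
        return {name: make_template(name, self.montage) for name in self.conditions}

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def _seeds(seed: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed)


def build_schedule(config: GeneratorConfig) -> StimulationSchedule:
    """Randomised block schedule of stimulation pulse trains.

    Blocks (``blocks_per_condition`` per condition, ``trains_per_block``
    trains each) are presented in a seeded random order.  Within a block,
    consecutive train onsets are separated by the train duration plus a delay
    drawn uniformly from ``mean_delay_s * [1 - jitter, 1 + jitter]``.
    """
    rng = np.random.default_rng(_seeds(config.seed).spawn(1)[0])
    block_conditions = [
        c for c in config.conditions for _ in range(config.blocks_per_condition)
    ]
    order = rng.permutation(len(block_conditions))
    events: list[ScheduleEvent] = []
    blocks: list[tuple[str, tuple[int, ...]]] = []
    t = config.lead_in_s
    for bi in order:
        cond = block_conditions[bi]
        idx: list[int] = []
        for k in range(config.trains_per_block):
            if k > 0:
                delay = rng.uniform(
                    config.mean_delay_s * (1 - config.jitter),
                    config.mean_delay_s * (1 + config.jitter),
                )
                t += config.train_duration_s + delay
            idx.append(len(events))
            events.append(ScheduleEvent(t, cond, config.train_duration_s))
        blocks.append((cond, tuple(idx)))
        t += config.train_duration_s + config.inter_block_gap_s
    return StimulationSchedule(events=tuple(events), blocks=tuple(blocks))


def generate_background(
    n_samples: int, config: GeneratorConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """(n_channels, n_samples) background: per-channel pink + white noise plus
    a common-phase line-frequency sinusoid."""
    if n_samples < 1:
        raise ConfigError("n_samples must be >= 1")
    if rng is None:
        rng = np.random.default_rng(_seeds(config.seed).spawn(2)[1])
    n_ch = config.montage.n_channels
    out = np.zeros((n_ch, n_samples))

    if config.line_uv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n_samples) / config.sampling_rate
        out += config.line_uv * np.sin(2 * np.pi * config.line_freq * t + phase)

    if config.pink_uv > 0:
        from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

        # pad to a fast FFT length, truncate after shaping
        n_fast = next_fast_len(n_samples)
        white = rng.standard_normal((n_ch, n_fast))
        spec = rfft(white, axis=1)
        freqs = rfftfreq(n_fast, d=1.0 / config.sampling_rate)
        shaping = np.zeros_like(freqs)
        # power ~ 1/f above the knee; flat below (EEG spectra plateau at
        # very low frequency, and unbounded drift would swamp any baseline)
        knee = max(config.pink_knee_hz, freqs[1] if len(freqs) > 1 else 1.0)
        shaping[1:] = 1.0 / np.sqrt(np.maximum(freqs[1:], knee))
        pink = irfft(spec * shaping, n=n_fast, axis=1)[:, :n_samples]
        rms = np.sqrt(np.mean(pink**2, axis=1, keepdims=True))
        pink = pink / rms
        if config.pink_spatial_scale > 0:
            # volume conduction: smooth the 1/f field across the scalp by
            # mixing per-channel sources with a distance kernel (rows are
            # L2-normalised to preserve per-channel RMS)
            pos = config.montage.positions
            d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
            mix = np.exp(-d2 / config.pink_spatial_scale**2)
            mix /= np.sqrt((mix**2).sum(axis=1, keepdims=True))
            pink = mix @ pink
        out += config.pink_uv * pink

    if config.white_uv > 0:
        out += config.white_uv * rng.standard_normal((n_ch, n_samples))
    return out


def generate_session(
    config: GeneratorConfig,
) -> tuple[np.ndarray, StimulationSchedule, dict]:
    """Synthesise one full recording.

    Returns the continuous (n_channels, n_samples) signal in µV, the
    stimulation schedule, and a ground-truth sidecar describing every planted
    component (channel group, centre latency, amplitude) plus each condition's
    noiseless spatio-temporal peak.  The evoked kernel is added once per
    second of each pulse train.
    """
    schedule = build_schedule(config)
    templates = config.resolved_templates()
    fs = config.sampling_rate
    last = schedule.events[-1]
    n_samples = int(round((last.onset_s + last.train_duration_s + 2.0) * fs))

    rng = np.random.default_rng(_seeds(config.seed).spawn(2)[1])
    signal = generate_background(n_samples, config, rng=rng)

    rendered = {name: tpl.render(config.montage, fs) for name, tpl in templates.items()}
    for ev in schedule.events:
        tpl = rendered[ev.condition]
        n_cycles = max(1, int(round(ev.train_duration_s * 1000.0
                                    / templates[ev.condition].cycle_ms)))
        for k in range(n_cycles):
            start = int(round(ev.onset_s * fs)) + k * tpl.shape[1]
            stop = min(start + tpl.shape[1], n_samples)
            if start < n_samples:
                signal[:, start:stop] += tpl[:, : stop - start]

    sidecar = {
        "sampling_rate": fs,
        "n_samples": n_samples,
        "conditions": {},
        "events": [dataclasses.asdict(e) for e in schedule.events],
        "condition_counts": schedule.condition_counts(),
    }
    for name, tpl in templates.items():
        ch, lat, amp = tpl.peak(config.montage, fs)
        sidecar["conditions"][name] = {
            "components": [
                {
                    "group": c.group,
                    "centre_channel": c.centre_channel,
                    "centre_ms": c.centre_ms,
                    "width_ms": c.width_ms,
                    "amplitude_uv": c.amplitude_uv,
                    "shape": c.shape,
                }
                for c in tpl.components
            ],
            "peak_channel": ch,
            "peak_latency_ms": lat,
            "peak_amplitude_uv": amp,
            "cycle_ms": tpl.cycle_ms,
        }
    return signal, schedule, sidecar
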