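"""End-to-end pipeline: simulate -> preprocess -> decode -> stats -> report.

A single :class:`PipelineConfig` (YAML round-trippable, unknown keys
rejected) drives every stage; one global seed fans out deterministically to
the generator and to every cross-validation shuffle, so re-running a config
reproduces identical numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import decode as dec
from . import erpstats as es
from . import io as pio
from .features import max_amplitude_features, window_grid
from .preprocess import (
    Epochs,
    augment_split,
    average_evoked,
    bandpass,
    baseline_correct,
    epoch,
    notch,
    reject_artifacts,
)
from .synth import CONDITION_ORDER, GeneratorConfig, generate_session

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "preprocess_session"]

log = logging.getLogger("painmark")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "painmark_out"
    # generator overrides, validated against GeneratorConfig field names
    generator: dict = field(default_factory=dict)
    # preprocessing
    band_low_hz: float = 0.5
    band_high_hz: float = 70.0
    band_order: int = 4
    notch_hz: float = 60.0
    notch_q: float = 30.0
    ptp_max_uv: float = 150.0
    epoch_start_ms: float = -500.0
    epoch_end_ms: float = 1000.0
    # window grid
    window_start_ms: float = 50.0
    window_stop_ms: float = 950.0
    window_width_ms: float = 100.0
    # decoding overrides, validated against DecodeConfig field names
    decode: dict = field(default_factory=dict)
    # statistics
    stats_channel: str = "Cz"
    background_window_ms: tuple[float, float] = (-150.0, -50.0)

    def __post_init__(self) -> None:
        gen_fields = {f.name for f in dataclasses.fields(GeneratorConfig)}
        unknown = set(self.generator) - gen_fields
        if unknown:
            raise ValueError(f"unknown generator keys {sorted(unknown)}")
        dec_fields = {f.name for f in dataclasses.fields(dec.DecodeConfig)}
        unknown = set(self.decode) - dec_fields
        if unknown:
            raise ValueError(f"unknown decode keys {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        d = dict(d)
        if "background_window_ms" in d:
            d["background_window_ms"] = tuple(d["background_window_ms"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["background_window_ms"] = list(self.background_window_ms)
        return d

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(seed=self.seed, **self.generator)

    def decode_config(self) -> dec.DecodeConfig:
        kwargs = dict(self.decode)
        kwargs.setdefault("seed", self.seed)
        return dec.DecodeConfig(**kwargs)


@dataclass
class ReportBundle:
    manifest: dict
    decode_report: dict
    stats_report: dict
    gfp_report: dict
    rejection: dict
    paths: dict = field(default_factory=dict)


def preprocess_session(
    signal: np.ndarray,
    events,
    channel_labels,
    sampling_rate: float,
    config: PipelineConfig,
):
    """Filter, epoch, baseline-correct and artifact-reject one session.

    Returns (analysis_epochs, augmented_epochs, rejection_report): the
    original 1 s analysis epochs (with 500 ms pre-stimulus) and the
    augmented 2 x 1 s training epochs, both baseline-corrected to the
    pre-train mean and screened at the same peak-to-peak threshold.
    """
    filtered = bandpass(
        signal, sampling_rate, config.band_low_hz, config.band_high_hz,
        config.band_order,
    )
    filtered = notch(filtered, sampling_rate, config.notch_hz, config.notch_q)

    analysis = epoch(
        filtered, sampling_rate, events, channel_labels,
        config.epoch_start_ms, config.epoch_end_ms,
    )
    analysis = baseline_correct(analysis)
    analysis, report = reject_artifacts(analysis, config.ptp_max_uv)
    if not analysis.kept_mask.any():
        raise RuntimeError("preprocess: all trials rejected")

    long = epoch(filtered, sampling_rate, events, channel_labels,
                 config.epoch_start_ms, 2000.0)
    long = baseline_correct(long)
    long, _ = reject_artifacts(long, config.ptp_max_uv)
    long.kept_mask &= analysis.kept_mask  # keep the two trial sets aligned
    augmented = augment_split(long)
    return analysis, augmented, report


def _stats_battery(
    analysis: Epochs, window, config: PipelineConfig
) -> dict:
    """Nonparametric battery on per-trial window maxima at one channel.

    Groups are the three conditions plus pre-stimulus background activity at
    the same channel.
    """
    ch = analysis.channel_labels.index(config.stats_channel)
    feats = max_amplitude_features(analysis, window)
    y = np.asarray(feats.labels)
    groups = {c: feats.values[y == c, ch] for c in CONDITION_ORDER if (y == c).any()}

    b0, b1 = config.background_window_ms
    fs = analysis.sampling_rate
    i0 = int(round((b0 - analysis.t_start_ms) / 1000.0 * fs))
    i1 = int(round((b1 - analysis.t_start_ms) / 1000.0 * fs))
    kept = analysis.kept()
    groups["background"] = kept.data[:, ch, i0:i1].max(axis=1)

    names = list(groups)
    samples = [groups[n] for n in names]
    out: dict = {"channel": config.stats_channel, "window": str(window),
                 "groups": names, "n": [int(len(s)) for s in samples]}
    out["normality"] = {
        n: pio.report_to_json(es.ks_normality(s)) for n, s in groups.items()
    }
    if len(samples) >= 2:
        out["mann_whitney_first_pair"] = pio.report_to_json(
            es.mann_whitney(samples[0], samples[1])
        )
    if len(samples) >= 3:
        out["kruskal_posthoc"] = pio.report_to_json(es.posthoc_pairwise(samples))
    return out


def run_pipeline(config: PipelineConfig, write: bool = True) -> ReportBundle:
    """Execute the full study on one synthetic session."""
    out = Path(config.out_dir)
    gen = config.generator_config()

    log.info("simulate: seed=%d", config.seed)
    signal, schedule, sidecar = generate_session(gen)
    log.info("simulate: %d events, %d samples", len(schedule), signal.shape[1])

    paths: dict = {}
    if write:
        paths.update(
            pio.write_session(out / "session", signal, schedule, sidecar,
                              gen.montage, gen.sampling_rate)
        )

    analysis, augmented, rejection = preprocess_session(
        signal, schedule.events, gen.montage.labels, gen.sampling_rate, config
    )
    log.info(
        "preprocess: %d/%d trials kept, %d augmented",
        int(analysis.kept_mask.sum()), analysis.n_trials, augmented.n_trials,
    )
    if write:
        paths.update(pio.write_epochs(out / "epochs", analysis))

    windows = window_grid(
        config.window_start_ms, config.window_stop_ms, config.window_width_ms
    )
    dcfg = config.decode_config()
    sweep = dec.sweep_windows(analysis, dcfg, windows)
    log.info("decode: best window %s", sweep.best_window)

    best_feats = max_amplitude_features(analysis, sweep.best_window)
    selected = dec.sequential_forward_selection(
        best_feats.values,
        np.asarray(best_feats.labels),
        n_select=dcfg.n_select,
        k=dcfg.k_folds,
        seed=dcfg.seed,
        classifier=dcfg.selection_classifier,
        channel_labels=analysis.channel_labels,
    )
    final = dec.final_test(augmented, sweep.best_window, dcfg)
    log.info("decode: test bACC %.3f", final.test_bacc)

    decode_report = {
        "windows": [str(w) for w in sweep.windows],
        "fold_baccs": [
            {name: scores.tolist() for name, scores in row.items()}
            for row in sweep.fold_baccs
        ],
        "window_means": sweep.window_means().tolist(),
        "best_window": str(sweep.best_window),
        "best_window_index": sweep.best_window_index,
        "selected_channels": list(selected),
        "final": pio.report_to_json(final),
    }

    evokeds = {
        c: average_evoked(analysis, c)
        for c in CONDITION_ORDER
        if any(lb == c and k for lb, k in zip(analysis.labels, analysis.kept_mask))
    }
    gfp_report = {
        c: {
            "mean_post_stimulus_uv": es.gfp(ev).mean_post_stimulus(),
            "peak": pio.report_to_json(es.find_peak(ev)),
        }
        for c, ev in evokeds.items()
    }
    stats_report = _stats_battery(analysis, sweep.best_window, config)

    manifest = {
        "package": "painmark",
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_trials": analysis.n_trials,
        "n_kept": int(analysis.kept_mask.sum()),
        "n_augmented": augmented.n_trials,
    }
    bundle = ReportBundle(
        manifest=manifest,
        decode_report=decode_report,
        stats_report=stats_report,
        gfp_report=gfp_report,
        rejection=pio.report_to_json(rejection),
        paths=paths,
    )
    if write:
        rep = out / "report"
        rep.mkdir(parents=True, exist_ok=True)
        files = {
            "decode.json": decode_report,
            "stats.json": stats_report,
            "gfp.json": gfp_report,
            "rejection.json": bundle.rejection,
        }
        for name, payload in files.items():
            (rep / name).write_text(json.dumps(payload, indent=1, sort_keys=True))
            paths[name] = str(rep / name)
        conf = np.asarray(final.confusion)
        with open(rep / "confusion.csv", "w") as f:
            f.write("," + ",".join(dec.CLASS_ORDER) + "\n")
            for lab, row in zip(dec.CLASS_ORDER, conf):
                f.write(lab + "," + ",".join(str(int(v)) for v in row) + "\n")
        paths["confusion.csv"] = str(rep / "confusion.csv")
        manifest["files"] = sorted(paths)
        (rep / "manifest.json").write_text(
            json.dumps(pio.report_to_json(manifest), indent=1, sort_keys=True)
        )
        paths["manifest.json"] = str(rep / "manifest.json")
    return bundle
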