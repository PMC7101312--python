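import numpy as np
import pytest

from painmark import decode as dec
from painmark import erpstats as es
from painmark.features import max_amplitude_features
from painmark.pipeline import PipelineConfig, preprocess_session
from painmark.preprocess import average_evoked
from painmark.synth import CONDITION_ORDER, generate_session


@pytest.fixture(scope="session")
def default_montage_fixture():
    from painmark.montage import default_montage

    return default_montage()


def run_twin(seed: int) -> dict:
    """One full study on the default synthetic session: preprocess, window
    sweep, held-out test, per-condition GFP means and early peaks."""
    cfg = PipelineConfig(seed=seed)
    gen = cfg.generator_config()
    signal, schedule, sidecar = generate_session(gen)
    analysis, augmented, _ = preprocess_session(
        signal, schedule.events, gen.montage.labels, gen.sampling_rate, cfg
    )
    sweep = dec.sweep_windows(analysis, cfg.decode_config())
    final = dec.final_test(augmented, sweep.best_window, cfg.decode_config())
    out = {
        "seed": seed,
        "best_window_index": sweep.best_window_index,
        "best_window": sweep.best_window,
        "test_bacc": final.test_bacc,
        "confusion": final.confusion,
        "gfp_mean": {},
        "early_peak": {},
    }
    from painmark.features import TimeWindow

    for c in CONDITION_ORDER:
        ev = average_evoked(analysis, c)
        out["gfp_mean"][c] = es.gfp(ev).mean_post_stimulus()
        out["early_peak"][c] = es.find_peak(ev, TimeWindow(0.0, 150.0))
    return out


@pytest.fixture(scope="session")
def twin_results():
    """The simulation twin evaluated over 20 generator seeds."""
    return [run_twin(seed) for seed in range(1, 21)]


@pytest.fixture(scope="session")
def small_session():
    """A compact default-template session (2 blocks/condition, 30 trials)
    for unit tests that need realistic epochs quickly."""
    cfg = PipelineConfig(seed=11, generator={"blocks_per_condition": 2})
    gen = cfg.generator_config()
    signal, schedule, sidecar = generate_session(gen)
    analysis, augmented, report = preprocess_session(
        signal, schedule.events, gen.montage.labels, gen.sampling_rate, cfg
    )
    return {
        "config": cfg,
        "generator": gen,
        "signal": signal,
        "schedule": schedule,
        "sidecar": sidecar,
        "analysis": analysis,
        "augmented": augmented,
    }
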