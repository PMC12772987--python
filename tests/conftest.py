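import numpy as np
import pytest

from apneaflow.simulate import SimConfig, simulate_record
from apneaflow.workflow import localization_summary, run_desk_study


@pytest.fixture(scope="session")
def default_record():
    """One moderately severe annotated recording shared across tests."""
    cfg = SimConfig(duration=3600.0, target_event_rate=8.0, seed=17)
    return simulate_record(cfg, subject_id="S017")


@pytest.fixture(scope="session")
def desk_study():
    """The scaled-down end-to-end study: 80/20/30 subjects, 1-h recordings,
    desk-preset CNN on 10-min segments. Trained once per session."""
    return run_desk_study(seed=1)


@pytest.fixture(scope="session")
def desk_localization(desk_study):
    return localization_summary(desk_study, max_segments=30, background_size=50)


def rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def event_rms_ratio(record, annotation, flank_s: float = 30.0) -> float:
    """Sliding-window RMS oracle: event-window RMS over flanking-baseline RMS."""
    fs = record.fs
    i0, i1 = int(annotation.onset * fs), int(annotation.end * fs)
    w = record.samples[i0:i1]
    f0 = record.samples[max(0, int((annotation.onset - flank_s) * fs)) : i0]
    f1 = record.samples[i1 : int((annotation.end + flank_s) * fs)]
    flank = np.concatenate([f0, f1])
    return rms(w) / rms(flank)
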