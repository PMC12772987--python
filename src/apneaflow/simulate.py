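"""Synthetic pediatric airflow simulator with annotated apneic events.

Generates overnight single-channel (thermistor-like) airflow recordings in
which apneas, hypopneas, movement artifacts and wake periods are injected at
known locations, so that every downstream stage — preprocessing, the
event-count CNN, AHI correction, diagnostics and attribution — can be
exercised against exact ground truth.

The breathing model is deliberately simple: a sinusoid with per-breath
frequency jitter and a slow amplitude envelope, plus Gaussian noise. Apneas
suppress the local flow amplitude to <=10% of baseline and hypopneas to
20-55% of baseline, mirroring the AASM pediatric amplitude criteria
(apnea: >=90% reduction; hypopnea: 30-90% reduction, lasting at least two
missed breaths). Events are ramped in and out with a 1-s cosine taper placed
just *outside* the annotated window, so the annotated interval is fully
suppressed while abrupt onset/offset transitions exist for attribution
methods to localize.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "EventAnnotation",
    "AirflowRecord",
    "simulate_record",
    "simulate_cohort",
    "RESPIRATORY_KINDS",
]

RESPIRATORY_KINDS = ("apnea", "hypopnea")
ANNOTATION_KINDS = ("apnea", "hypopnea", "artifact", "wake")

# Amplitude gains realizing the AASM bands with margin for the +/-10%
# slow envelope: apnea residual 5% of baseline, hypopnea 20-55%.
_APNEA_GAIN = 0.05
_HYPOPNEA_GAIN_RANGE = (0.20, 0.55)
_ENVELOPE_DEPTH = 0.10
_ENVELOPE_PERIOD_RANGE = (30.0, 120.0)
_BREATH_JITTER = 0.10
_TAPER_S = 1.0
# clearance between events / artifacts / wake edges keeps the 30-s flanking
# baseline of every event free of other disturbances
_CLEARANCE_S = 35.0


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the airflow simulator.

    Rates are per hour; ``wake_fraction`` may be a scalar or a ``(lo, hi)``
    interval sampled per record.
    """

    fs_out: float = 32.0
    duration: float = 3600.0
    breath_rate_range: tuple[float, float] = (15.0, 30.0)
    target_event_rate: float = 5.0
    apnea_fraction: float = 0.3
    event_duration_range: tuple[float, float] = (8.0, 20.0)
    artifact_rate: float = 2.0
    wake_fraction: float | tuple[float, float] = (0.1, 0.2)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_out <= 0:
            raise ValueError("fs_out must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name in ("target_event_rate", "artifact_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.apnea_fraction <= 1.0:
            raise ValueError("apnea_fraction must be in [0, 1]")
        lo, hi = self.wake_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("wake_fraction must lie in [0, 1)")
        blo, bhi = self.breath_rate_range
        if not 0 < blo <= bhi:
            raise ValueError("breath_rate_range must be positive and ordered")
        dlo, dhi = self.event_duration_range
        if not 0 < dlo <= dhi:
            raise ValueError("event_duration_range must be positive and ordered")
        # pediatric scoring: an event lasts at least two breath cycles
        slowest_period = 60.0 / blo
        if dlo < 2.0 * slowest_period:
            raise ValueError(
                "event_duration_range lower bound must be >= 2 breath periods "
                f"at the slowest breath rate ({2 * slowest_period:.1f} s)"
            )

    @property
    def wake_range(self) -> tuple[float, float]:
        w = self.wake_fraction
        if isinstance(w, (int, float)):
            return (float(w), float(w))
        return (float(w[0]), float(w[1]))


@dataclass(frozen=True)
class EventAnnotation:
    """One scored interval: respiratory event, artifact or wake block."""

    onset: float
    duration: float
    kind: str

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class AirflowRecord:
    """A single-channel airflow recording with ground-truth annotations."""

    subject_id: str
    samples: np.ndarray
    fs: float
    duration: float
    sleep_time: float
    annotations: list[EventAnnotation]
    true_ahi: float

    def respiratory_events(self) -> list[EventAnnotation]:
        return [a for a in self.annotations if a.kind in RESPIRATORY_KINDS]


def _breathing_phase(rng: np.random.Generator, t: np.ndarray, bpm: float) -> np.ndarray:
    """Cumulative breathing phase with +/-10% per-breath period jitter."""
    period = 60.0 / bpm
    n_breaths = int(np.ceil(t[-1] / (period * (1 - _BREATH_JITTER)))) + 2
    periods = period * (1.0 + rng.uniform(-_BREATH_JITTER, _BREATH_JITTER, n_breaths))
    bounds = np.concatenate([[0.0], np.cumsum(periods)])
    # fractional breath index at each sample -> phase
    idx = np.interp(t, bounds, np.arange(bounds.size, dtype=float))
    return 2.0 * np.pi * idx


def _wake_blocks(
    rng: np.random.Generator, duration: float, wake_total: float
) -> list[tuple[float, float]]:
    """Wake as blocks at record start and end plus one mid-night block."""
    if wake_total <= 0:
        return []
    props = rng.dirichlet([4.0, 3.0, 3.0])  # start / mid / end shares
    w_start, w_mid, w_end = props * wake_total
    blocks = []
    if w_start > 1.0:
        blocks.append((0.0, w_start))
    if w_end > 1.0:
        blocks.append((duration - w_end, w_end))
    if w_mid > 1.0:
        lo = w_start + 2 * _CLEARANCE_S
        hi = duration - w_end - w_mid - 2 * _CLEARANCE_S
        if hi > lo:
            blocks.append((rng.uniform(lo, hi), w_mid))
        else:  # record too short for a mid block; fold into the start block
            blocks = [(0.0, w_start + w_mid)] + [b for b in blocks if b[0] > 0.0]
    return sorted(blocks)


def _sleep_intervals(
    duration: float, wake: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    edges = [0.0]
    for onset, dur in sorted(wake):
        edges.extend([onset, onset + dur])
    edges.append(duration)
    out = []
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a > 0:
            out.append((a, b))
    return out


def _place_intervals(
    rng: np.random.Generator,
    usable: list[tuple[float, float]],
    durations: Sequence[float],
    occupied: list[tuple[float, float]],
    clearance: float,
    what: str,
) -> list[tuple[float, float]]:
    """Randomly place non-overlapping intervals with mutual clearance.

    Raises when the requested intervals cannot be placed, naming the
    limiting constraint.
    """
    placed: list[tuple[float, float]] = []
    for dur in durations:
        spans = [(a, b - dur) for a, b in usable if b - dur > a]
        if not spans:
            raise ValueError(
                f"duration too short to place requested {what}: no usable span "
                f"of {dur:.1f} s remains within sleep after clearances"
            )
        weights = np.array([hi - lo for lo, hi in spans])
        ok = False
        for _ in range(400):
            span = spans[rng.choice(len(spans), p=weights / weights.sum())]
            onset = rng.uniform(span[0], span[1])
            clashes = any(
                (onset < o + d + clearance) and (o < onset + dur + clearance)
                for o, d in placed + occupied
            )
            if not clashes:
                placed.append((onset, dur))
                ok = True
                break
        if not ok:
            raise ValueError(
                f"duration too short to place requested {what}: could not fit "
                f"{len(durations)} intervals with {clearance:.0f} s clearance "
                f"into the available sleep time"
            )
    return placed


def simulate_record(config: SimConfig, subject_id: str = "S000") -> AirflowRecord:
    """Generate one annotated airflow recording.

    Deterministic given ``config.seed``. Respiratory events are placed only
    during sleep, with enough clearance that the 30-s flanking baseline of
    every event is undisturbed; the stored ``true_ahi`` is exactly
    ``3600 * n_events / sleep_time``.
    """
    rng = np.random.default_rng(config.seed)
    fs, duration = config.fs_out, config.duration
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    wlo, whi = config.wake_range
    wake_fraction = rng.uniform(wlo, whi)
    wake_total = wake_fraction * duration
    sleep_time = duration - wake_total
    wake = _wake_blocks(rng, duration, wake_total)
    sleep = _sleep_intervals(duration, wake)

    n_events = int(round(config.target_event_rate * sleep_time / 3600.0))
    n_apneas = int(round(config.apnea_fraction * n_events))
    n_artifacts = int(round(config.artifact_rate * duration / 3600.0))

    # events need their flanking baseline inside sleep
    margin = _CLEARANCE_S
    usable = [(a + margin, b - margin) for a, b in sleep if b - a > 2 * margin]
    dlo, dhi = config.event_duration_range
    event_durs = rng.uniform(dlo, dhi, n_events)
    events = _place_intervals(rng, usable, event_durs, [], _CLEARANCE_S, "events")
    kinds = np.array(["apnea"] * n_apneas + ["hypopnea"] * (n_events - n_apneas))
    rng.shuffle(kinds)

    art_durs, art_kinds = [], []
    for _ in range(n_artifacts):
        if rng.uniform() < 0.5:
            art_durs.append(rng.uniform(2.0, 5.0))
            art_kinds.append("burst")
        else:
            art_durs.append(rng.uniform(5.0, 15.0))
            art_kinds.append("flatline")
    art_usable = [(2.0, duration - 2.0 - 1.0)]
    artifacts = (
        _place_intervals(rng, art_usable, art_durs, events, _CLEARANCE_S, "artifacts")
        if n_artifacts
        else []
    )

    # --- base breathing signal ---------------------------------------
    bpm = rng.uniform(*config.breath_rate_range)
    phase = _breathing_phase(rng, t, bpm)
    env_period = rng.uniform(*_ENVELOPE_PERIOD_RANGE)
    envelope = 1.0 + _ENVELOPE_DEPTH * np.sin(
        2 * np.pi * t / env_period + rng.uniform(0, 2 * np.pi)
    )
    clean = envelope * np.sin(phase)
    noise = config.noise_sd * rng.standard_normal(n)

    # --- multiplicative gain: events + flatline artifacts -------------
    gain = np.ones(n)

    def _apply_gain(onset: float, dur: float, g: float) -> None:
        # cosine tapers sit just outside [onset, onset+dur]
        i0, i1 = int(round(onset * fs)), int(round((onset + dur) * fs))
        k = max(1, int(round(_TAPER_S * fs)))
        ramp = 0.5 * (1 + np.cos(np.linspace(0, np.pi, k)))  # 1 -> 0
        lo = max(0, i0 - k)
        gain[lo:i0] = np.minimum(gain[lo:i0], (g + (1 - g) * ramp)[k - (i0 - lo):])
        gain[i0:i1] = g
        hi = min(n, i1 + k)
        gain[i1:hi] = np.minimum(gain[i1:hi], (g + (1 - g) * ramp[::-1])[: hi - i1])

    annotations: list[EventAnnotation] = []
    for (onset, dur), kind in zip(events, kinds):
        if kind == "apnea":
            g = _APNEA_GAIN
        else:
            g = rng.uniform(*_HYPOPNEA_GAIN_RANGE)
        _apply_gain(onset, dur, g)
        annotations.append(EventAnnotation(onset, dur, str(kind)))

    burst = np.zeros(n)
    for (onset, dur), akind in zip(artifacts, art_kinds):
        i0, i1 = int(round(onset * fs)), int(round((onset + dur) * fs))
        if akind == "flatline":
            _apply_gain(onset, dur, 0.01)
        else:
            amp = rng.uniform(3.0, 6.0)
            w = np.hanning(max(i1 - i0, 3))
            burst[i0:i1] += amp * w[: i1 - i0] * rng.standard_normal(i1 - i0)
        annotations.append(EventAnnotation(onset, dur, "artifact"))

    # wake: larger, more irregular flow (movement), no scored events
    wake_mask = np.zeros(n, dtype=bool)
    for onset, dur in wake:
        i0, i1 = int(round(onset * fs)), int(round((onset + dur) * fs))
        wake_mask[i0:i1] = True
        annotations.append(EventAnnotation(onset, dur, "wake"))

    flow = gain * (clean + noise)
    flow[wake_mask] *= 1.2
    flow[wake_mask] += 0.3 * rng.standard_normal(int(wake_mask.sum()))
    flow += burst

    annotations.sort(key=lambda a: (a.onset, a.kind))
    true_ahi = 3600.0 * n_events / sleep_time
    return AirflowRecord(
        subject_id=subject_id,
        samples=flow,
        fs=fs,
        duration=duration,
        sleep_time=sleep_time,
        annotations=annotations,
        true_ahi=true_ahi,
    )


def simulate_cohort(
    n_subjects: int,
    ahi_levels: Sequence[float],
    base_config: SimConfig,
) -> list[AirflowRecord]:
    """Simulate one record per subject at the requested target AHI levels.

    Per-subject seeds derive from ``base_config.seed + index``, so the same
    base seed reproduces the identical cohort.
    """
    if n_subjects != len(ahi_levels):
        raise ValueError("n_subjects must equal len(ahi_levels)")
    records = []
    for i, target in enumerate(ahi_levels):
        if target < 0:
            raise ValueError(f"target AHI must be >= 0 (subject {i}: {target})")
        cfg = replace(base_config, target_event_rate=float(target), seed=base_config.seed + i)
        records.append(simulate_record(cfg, subject_id=f"S{i:03d}"))
    return records
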