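"""Synthetic visit simulator with known ground truth.

Emulates the raw output of a nest-box scale monitoring a 100-190 g
animal:

* empty-pan stretches at the tare level with slow linear drift, Gaussian
  read noise and sporadic out-of-range wind spikes;
* visit patterns — true weight plus a movement-induced AR(1) oscillation
  plus read noise — whose duration is lognormal with a 23.18 s mean;
* in a configurable 15% of visits, one quiet plateau where the oscillation
  is suppressed, which is what lets the stability tagger fire;
* a stability tagger standing in for the proprietary device rule: a sample
  is flagged stable iff the spread (max - min) of the trailing k raw
  readings is at most a tolerance delta.

Every generated stream comes with its ground-truth visit events so the
whole pipeline (tare, segmentation, features, estimation, training) can be
scored without field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "SimulatorConfig",
    "SeasonTrend",
    "Bird",
    "VisitEvent",
    "simulate_pattern",
    "simulate_stream",
    "simulate_season",
]


@dataclass
class SimulatorConfig:
    """Generative model parameters (grams, seconds, per-hour rates).

    ``osc_amplitude`` is the ~2-sigma envelope of the movement signal: the
    AR(1) oscillation's stationary standard deviation is ``amplitude / 2``.
    """

    sps: int = 16
    true_weight_range: tuple[float, float] = (100.0, 190.0)
    duration_mean_s: float = 23.18
    duration_sigma_log: float = 0.5
    stable_pattern_fraction: float = 0.15
    osc_amplitude: float = 12.0
    osc_ar_coeff: float = 0.9
    noise_sd: float = 0.2
    plateau_duration_range: tuple[float, float] = (2.0, 6.0)
    tagger_window: int = 8
    tagger_tol: float = 1.0
    tare_level: float = 10.0
    tare_drift_per_hour: float = 1.0 / 24.0  # ~1 g/day of dirt build-up
    wind_spike_rate_per_hour: float = 2.0
    wind_spike_range: tuple[float, float] = (320.0, 500.0)
    gap_mean_s: float = 10.0
    gap_min_s: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.true_weight_range
        if not lo < hi:
            raise ValueError("true_weight_range must be ordered")
        for name in ("stable_pattern_fraction", "wind_spike_rate_per_hour",
                     "noise_sd", "osc_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def osc_sd(self) -> float:
        return self.osc_amplitude / 2.0


@dataclass(frozen=True)
class VisitEvent:
    """Ground truth for one simulated visit."""

    true_weight: float
    arrival_tick: int
    departure_tick: int
    rfid: Optional[str] = None
    had_stable_run: bool = False

    def __post_init__(self) -> None:
        if self.departure_tick <= self.arrival_tick:
            raise ValueError("departure must come after arrival")


@dataclass(frozen=True)
class SeasonTrend:
    """Per-bird body-weight trajectory over a breeding season.

    Linear trend with an optional breakpoint (slope changes at
    ``breakpoint_day``); females are offset ``sex_offset`` grams above
    males, the usual dimorphism in small falcons.
    """

    slope_before: float = -0.2  # g/day
    slope_after: Optional[float] = None  # None -> purely linear
    breakpoint_day: int = 30
    base_weight_male: float = 135.0
    base_weight_female_offset: float = 15.0
    individual_sd: float = 6.0
    visits_per_day: int = 3

    def weight(self, base: float, day: float) -> float:
        if self.slope_after is None or day <= self.breakpoint_day:
            return base + self.slope_before * day
        return (base + self.slope_before * self.breakpoint_day
                + self.slope_after * (day - self.breakpoint_day))


@dataclass(frozen=True)
class Bird:
    rfid: str
    sex: str  # "F" | "M"
    base_weight: float


def _stability_flags(raw: np.ndarray, k: int, tol: float) -> np.ndarray:
    """Device-rule stand-in: stable iff max-min of the trailing k samples
    (the sample itself included) is <= tol.  The first k-1 samples are
    always unstable."""
    n = len(raw)
    flags = np.zeros(n, dtype=bool)
    if n >= k:
        win = np.lib.stride_tricks.sliding_window_view(raw, k)
        flags[k - 1:] = (win.max(axis=1) - win.min(axis=1)) <= tol
    return flags


def _ar1(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), n)
    innov[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -phi], innov)


def _draw_duration_samples(cfg: SimulatorConfig, rng: np.random.Generator) -> int:
    sig = cfg.duration_sigma_log
    mu = np.log(cfg.duration_mean_s) - 0.5 * sig**2
    dur = rng.lognormal(mu, sig)
    return max(int(round(dur * cfg.sps)), 2)


def simulate_pattern(
    cfg: SimulatorConfig,
    true_weight: float,
    rng: np.random.Generator,
    start_tick: int = 0,
    tare: Optional[float] = None,
    nest_id: str = "nest-01",
    rfid: Optional[str] = None,
) -> tuple[dict, VisitEvent]:
    """Generate the raw samples of one visit.

    Returns a columnar dict (``ticks``, ``raw``, ``stable``) plus the
    ground-truth :class:`VisitEvent`.  Raw readings are
    ``tare + true_weight + oscillation + noise``; during a plateau (drawn
    with probability ``stable_pattern_fraction``) the oscillation is
    suppressed so the stability tagger can fire.
    """
    if tare is None:
        tare = cfg.tare_level
    n = _draw_duration_samples(cfg, rng)
    osc = _ar1(n, cfg.osc_sd, cfg.osc_ar_coeff, rng)
    if rng.random() < cfg.stable_pattern_fraction:
        lo, hi = cfg.plateau_duration_range
        plen = min(int(round(rng.uniform(lo, hi) * cfg.sps)), n)
        pstart = rng.integers(0, n - plen + 1)
        osc[pstart:pstart + plen] = 0.0
    raw = tare + true_weight + osc + rng.normal(0.0, cfg.noise_sd, n)
    flags = _stability_flags(raw, cfg.tagger_window, cfg.tagger_tol)
    ticks = start_tick + np.arange(n, dtype=np.int64)
    event = VisitEvent(
        true_weight=float(true_weight),
        arrival_tick=int(ticks[0]),
        departure_tick=int(ticks[-1]),
        rfid=rfid,
        had_stable_run=bool(flags.any()),
    )
    samples = {"ticks": ticks, "raw": raw, "stable": flags,
               "nest_id": nest_id, "rfid": rfid}
    return samples, event


def _empty_segment(
    cfg: SimulatorConfig, n: int, start_tick: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Empty-pan raw readings with drift, noise and Poisson wind spikes."""
    ticks = start_tick + np.arange(n, dtype=np.int64)
    hours = ticks / (3600.0 * cfg.sps)
    raw = (cfg.tare_level + cfg.tare_drift_per_hour * hours
           + rng.normal(0.0, cfg.noise_sd, n))
    p_spike = cfg.wind_spike_rate_per_hour / (3600.0 * cfg.sps)
    spikes = rng.random(n) < p_spike
    if spikes.any():
        lo, hi = cfg.wind_spike_range
        raw[spikes] = rng.uniform(lo, hi, int(spikes.sum()))
    flags = _stability_flags(raw, cfg.tagger_window, cfg.tagger_tol)
    return ticks, raw, flags


def _draw_gap_samples(cfg: SimulatorConfig, rng: np.random.Generator) -> int:
    gap = cfg.gap_min_s + rng.exponential(max(cfg.gap_mean_s - cfg.gap_min_s, 0.0))
    return max(int(round(gap * cfg.sps)), 1)


def simulate_stream(
    cfg: SimulatorConfig,
    n_visits: int,
    rng: np.random.Generator,
    nest_id: str = "nest-01",
) -> tuple["SampleLog", list[VisitEvent]]:
    """Alternating empty-pan gaps and visit patterns on a contiguous tick
    axis, with per-visit ground truth.

    Visits draw independent true weights uniform over
    ``true_weight_range`` and sequential RFID tags.
    """
    from .io import SampleLog  # local import to avoid a cycle

    lo, hi = cfg.true_weight_range
    tick = 0
    tick_chunks: list[np.ndarray] = []
    raw_chunks: list[np.ndarray] = []
    flag_chunks: list[np.ndarray] = []
    rfid_spans: list[tuple[int, int, Optional[str]]] = []  # (start idx, n, rfid)
    events: list[VisitEvent] = []
    idx = 0

    def add_gap() -> None:
        nonlocal tick, idx
        n = _draw_gap_samples(cfg, rng)
        t, r, f = _empty_segment(cfg, n, tick, rng)
        tick_chunks.append(t)
        raw_chunks.append(r)
        flag_chunks.append(f)
        rfid_spans.append((idx, n, None))
        tick += n
        idx += n

    add_gap()
    for i in range(n_visits):
        w = rng.uniform(lo, hi)
        rfid = f"tag-{i:05d}"
        tare_now = cfg.tare_level + cfg.tare_drift_per_hour * tick / (3600.0 * cfg.sps)
        samples, event = simulate_pattern(
            cfg, w, rng, start_tick=tick, tare=tare_now,
            nest_id=nest_id, rfid=rfid,
        )
        n = len(samples["ticks"])
        tick_chunks.append(samples["ticks"])
        raw_chunks.append(samples["raw"])
        flag_chunks.append(samples["stable"])
        rfid_spans.append((idx, n, rfid))
        events.append(event)
        tick += n
        idx += n
        add_gap()

    ticks = np.concatenate(tick_chunks)
    raws = np.concatenate(raw_chunks)
    flags = np.concatenate(flag_chunks)
    rfids: list[Optional[str]] = [None] * len(ticks)
    for start, n, rfid in rfid_spans:
        if rfid is not None:
            rfids[start:start + n] = [rfid] * n
    log = SampleLog(ticks=ticks, raw_weights=raws, stable=flags,
                    nest_ids=[nest_id] * len(ticks), rfids=rfids)
    return log, events


def simulate_season(
    cfg: SimulatorConfig,
    n_birds: int,
    days: int,
    rng: np.random.Generator,
    trend: SeasonTrend = SeasonTrend(),
    nest_id: str = "nest-01",
) -> tuple["SampleLog", list[VisitEvent], list[Bird]]:
    """Per-bird daily weight trajectories over a season.

    Each bird visits ``trend.visits_per_day`` times a day at random
    daytime instants; its true weight follows the sex-specific trend.  The
    log is event-windowed: only a short empty-pan stretch is recorded
    around each visit and the tick axis jumps between events, the way a
    field logger stores activity windows.  Ticks still encode absolute
    time (day = tick / (86400 * sps)), so trend recovery from the
    estimates is a pure pipeline exercise.
    """
    from .io import SampleLog

    if n_birds < 1:
        raise ValueError("n_birds must be >= 1")
    birds = []
    for b in range(n_birds):
        sex = "F" if b % 2 == 0 else "M"
        base = trend.base_weight_male + (
            trend.base_weight_female_offset if sex == "F" else 0.0
        ) + rng.normal(0.0, trend.individual_sd)
        birds.append(Bird(rfid=f"PIT-{b:04d}", sex=sex, base_weight=base))

    ticks_per_day = 86400 * cfg.sps
    # schedule: (absolute arrival tick, bird index)
    schedule: list[tuple[int, int]] = []
    for day in range(days):
        for b in range(n_birds):
            for _ in range(trend.visits_per_day):
                frac = rng.uniform(0.25, 0.75)  # daylight hours
                schedule.append((int((day + frac) * ticks_per_day), b))
    schedule.sort()

    tick_chunks: list[np.ndarray] = []
    raw_chunks: list[np.ndarray] = []
    flag_chunks: list[np.ndarray] = []
    rfids: list[Optional[str]] = []
    events: list[VisitEvent] = []
    pre_n = 2 * cfg.sps   # empty-pan window before each visit
    post_n = cfg.sps      # and after, enough to close the pattern
    last_tick = -1
    for arrival, b in schedule:
        bird = birds[b]
        start = arrival - pre_n
        if start <= last_tick:  # overlapping windows: skip this visit
            continue
        day = arrival / ticks_per_day
        w = trend.weight(bird.base_weight, day)
        t0, r0, f0 = _empty_segment(cfg, pre_n, start, rng)
        tare_now = cfg.tare_level + cfg.tare_drift_per_hour * arrival / (3600.0 * cfg.sps)
        samples, event = simulate_pattern(
            cfg, w, rng, start_tick=arrival, tare=tare_now,
            nest_id=nest_id, rfid=bird.rfid,
        )
        n_vis = len(samples["ticks"])
        t1, r1, f1 = _empty_segment(cfg, post_n, arrival + n_vis, rng)
        tick_chunks += [t0, samples["ticks"], t1]
        raw_chunks += [r0, samples["raw"], r1]
        flag_chunks += [f0, samples["stable"], f1]
        rfids += [None] * pre_n + [bird.rfid] * n_vis + [None] * post_n
        events.append(event)
        last_tick = arrival + n_vis + post_n - 1

    ticks = np.concatenate(tick_chunks)
    log = SampleLog(
        ticks=ticks,
        raw_weights=np.concatenate(raw_chunks),
        stable=np.concatenate(flag_chunks),
        nest_ids=[nest_id] * len(ticks),
        rfids=rfids,
    )
    return log, events, birds
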