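"""Raw-stream acquisition: tare auto-calibration, gain calibration and
pattern segmentation.

The scale emits 16 raw readings per second, each tagged stable/unstable.
While the pan is empty the running tare (the empty-pan reading) is tracked
with a robust IRLS location estimate over a short sliding window, so that
slow drift from dirt accumulating on the pan is followed while wind-induced
spikes are ignored.  When the calibrated weight (gain-corrected reading
minus tare) exceeds a start threshold a *pattern* opens: the contiguous
block of samples recorded while an animal stands on the pan.  The pattern
closes once enough consecutive readings fall back below the threshold, and
the trailing below-threshold readings are stripped so a pattern never ends
on an empty-pan sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "RawSample",
    "TareState",
    "GainCalibration",
    "AcquisitionConfig",
    "Pattern",
    "update_tare",
    "apply_calibration",
    "fit_gain",
    "is_in_range",
    "segment_stream",
    "validate_pattern",
]


@dataclass(frozen=True)
class RawSample:
    """One scale reading: tick index, raw grams and the device stability flag."""

    tick: int
    raw_weight: float
    stable: bool = False
    nest_id: str = ""
    rfid: Optional[str] = None


@dataclass(frozen=True)
class GainCalibration:
    """Linear map from raw readings to reference masses.

    ``calibrated-before-tare = gain * raw + offset``.  Identity by default;
    refit once per year against certified weights with :func:`fit_gain`.
    """

    gain: float = 1.0
    offset: float = 0.0
    residual_rms: float = 0.0

    def correct(self, raw_weight: float) -> float:
        return self.gain * raw_weight + self.offset


IDENTITY_GAIN = GainCalibration()


@dataclass
class AcquisitionConfig:
    """Segmentation and calibration controls.

    start_threshold
        Calibrated grams above which a pattern opens (50 g for a 100-190 g
        study species).
    end_consecutive_below
        The pattern closes on the Nth consecutive below-threshold sample
        ("more than four" readings below threshold, i.e. the 5th triggers).
    min_pattern_samples
        Valid patterns must last longer than one second: strictly more than
        16 samples at 16 sps, i.e. at least 17.
    valid_range
        Plausible single-sample weights in grams; readings above the range
        while a pattern is open are dropped as wind-induced outliers.
    """

    start_threshold: float = 50.0
    end_consecutive_below: int = 5
    min_pattern_samples: int = 17
    valid_range: tuple[float, float] = (50.0, 300.0)
    sps: int = 16
    tare_window: int = 64
    irls_max_iter: int = 10
    irls_tol: float = 1e-6

    def __post_init__(self) -> None:
        low, high = self.valid_range
        if not low < high:
            raise ValueError(f"valid_range must be ordered, got {self.valid_range}")
        if self.end_consecutive_below < 1 or self.tare_window < 1:
            raise ValueError("counts must be >= 1")


class TareState:
    """Running robust estimate of the empty-pan reading.

    Keeps a bounded ring buffer of recent gain-corrected empty-pan readings
    and the current IRLS location estimate.  Updated in place by
    :func:`update_tare` (the returned state is the same object).
    """

    __slots__ = ("tare", "_buf", "_n", "_pos", "n_updates")

    def __init__(self, tare: float = 0.0, window: int = 64):
        self.tare = float(tare)
        self._buf = np.empty(window, dtype=float)
        self._n = 0
        self._pos = 0
        self.n_updates = 0

    @property
    def buffer(self) -> np.ndarray:
        """Buffered readings, oldest first."""
        if self._n < len(self._buf):
            return self._buf[: self._n].copy()
        return np.roll(self._buf, -self._pos).copy()

    def _push(self, value: float) -> None:
        self._buf[self._pos] = value
        self._pos = (self._pos + 1) % len(self._buf)
        self._n = min(self._n + 1, len(self._buf))

    def __repr__(self) -> str:  # pragma: no cover
        return f"TareState(tare={self.tare:.3f}, n={self._n}, updates={self.n_updates})"


# Huber tuning constant: 95% Gaussian efficiency.
_HUBER_C = 1.345
_MAD_TO_SD = 1.4826


def _irls_location(x: np.ndarray, start: float, max_iter: int, tol: float) -> float:
    """Robust location by IRLS with Huber weights, warm-started at ``start``.

    The scale is frozen at the MAD of the window; a (near-)constant window
    degenerates gracefully to the median.
    """
    med = float(np.median(x))
    scale = _MAD_TO_SD * float(np.median(np.abs(x - med)))
    if scale < 1e-9:
        return med
    c = _HUBER_C * scale
    mu = start
    for _ in range(max_iter):
        r = np.abs(x - mu)
        np.maximum(r, c, out=r)          # |r| floored at c ...
        w = c / r                         # ... so w = min(1, c/|r|)
        mu_new = float(np.dot(w, x) / w.sum())
        if abs(mu_new - mu) < tol:
            return mu_new
        mu = mu_new
    return mu


def update_tare(
    state: TareState,
    sample: RawSample,
    cfg: AcquisitionConfig,
    gain_cal: GainCalibration = IDENTITY_GAIN,
) -> TareState:
    """Fold one empty-pan reading into the running tare estimate.

    Precondition (checked by the caller): the sample's calibrated weight is
    below ``cfg.start_threshold``, i.e. no animal is on the pan.  Robust to
    wind spikes by construction: Huber IRLS down-weights readings far from
    the bulk of the window.
    """
    corrected = gain_cal.correct(sample.raw_weight)
    state._push(corrected)
    n = state._n
    if n == 1:
        state.tare = corrected
    else:
        buf = state._buf[:n] if n < len(state._buf) else state._buf
        start = state.tare if state.n_updates else float(np.median(buf))
        state.tare = _irls_location(buf, start, cfg.irls_max_iter, cfg.irls_tol)
    state.n_updates += 1
    return state


def apply_calibration(
    raw_weight: float, tare: float, gain_cal: GainCalibration = IDENTITY_GAIN
) -> float:
    """Calibrated grams: ``gain * raw + offset - tare``."""
    return gain_cal.gain * raw_weight + gain_cal.offset - tare


def fit_gain(readings: Iterable[tuple[float, float]]) -> GainCalibration:
    """Annual gain calibration: OLS line mapping raw readings to reference
    masses, fitted from certified-weight measurements.

    Parameters
    ----------
    readings
        Pairs ``(reference_mass_g, mean_raw_reading_g)``.
    """
    pairs = list(readings)
    masses = np.array([p[0] for p in pairs], dtype=float)
    raws = np.array([p[1] for p in pairs], dtype=float)
    if len(np.unique(masses)) < 2 or len(np.unique(raws)) < 2:
        raise DegenerateInputError(
            "gain calibration needs at least two distinct reference masses"
        )
    A = np.column_stack([raws, np.ones_like(raws)])
    (gain, offset), *_ = np.linalg.lstsq(A, masses, rcond=None)
    resid = masses - (gain * raws + offset)
    rms = float(np.sqrt(np.mean(resid**2)))
    return GainCalibration(gain=float(gain), offset=float(offset), residual_rms=rms)


def is_in_range(weight: float, cfg: AcquisitionConfig) -> bool:
    """True iff the calibrated weight lies in the plausible range (inclusive)."""
    low, high = cfg.valid_range
    return low <= weight <= high


@dataclass
class Pattern:
    """Samples recorded from an animal's arrival on the pan to its departure.

    Calibrated weights, the device stability flags and tick indices are kept
    as parallel arrays.  Brief sub-threshold dips are retained; readings
    above the valid range were dropped during segmentation.
    """

    weights: np.ndarray
    stable: np.ndarray
    ticks: np.ndarray
    nest_id: str = ""
    rfid: Optional[str] = None
    sps: int = 16
    truncated: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.stable = np.asarray(self.stable, dtype=bool)
        self.ticks = np.asarray(self.ticks, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def start_tick(self) -> int:
        return int(self.ticks[0])

    @property
    def end_tick(self) -> int:
        return int(self.ticks[-1])

    @property
    def duration_s(self) -> float:
        return (self.end_tick - self.start_tick + 1) / self.sps

    @property
    def has_stable(self) -> bool:
        return bool(self.stable.any())

    def stable_weights(self) -> np.ndarray:
        return self.weights[self.stable]

    def unstable_weights(self) -> np.ndarray:
        return self.weights[~self.stable]


def validate_pattern(
    p: Pattern, cfg: AcquisitionConfig, allow_truncated: bool = False
) -> bool:
    """A pattern is valid when it outlasts the minimum duration (strictly
    more than 16 samples at the default rate) and was not cut off by the
    end of the stream."""
    if p.truncated and not allow_truncated:
        return False
    return len(p) >= cfg.min_pattern_samples


def segment_stream(
    stream,
    state: TareState,
    cfg: AcquisitionConfig,
    gain_cal: GainCalibration = IDENTITY_GAIN,
) -> tuple[list[Pattern], TareState]:
    """Split a raw stream into patterns while tracking the tare.

    State machine:

    * pan empty — every sample updates the tare; the first calibrated
      weight strictly above ``start_threshold`` opens a pattern (tare is
      frozen until it closes);
    * pattern open — in-range samples are appended; above-range samples are
      dropped as wind outliers (they still break a below-threshold run:
      the pan is not empty); below-threshold samples are appended
      tentatively and counted, and when the count reaches
      ``end_consecutive_below`` consecutive samples the pattern closes
      with every trailing below-threshold sample stripped;
    * end of stream while open — the pattern closes the same way but is
      flagged ``truncated``.

    ``stream`` may be an iterable of :class:`RawSample` or a columnar
    :class:`~nestscale.io.SampleLog`; ticks must be strictly increasing.
    Returns the patterns in order plus the final tare state.
    """
    ticks, raws, stables, nest_ids, rfids = _as_columns(stream)
    n = len(ticks)
    patterns: list[Pattern] = []
    low, high = cfg.valid_range
    thr = cfg.start_threshold
    gain = gain_cal.gain
    offset = gain_cal.offset
    identity = gain == 1.0 and offset == 0.0

    open_w: list[float] = []
    open_s: list[bool] = []
    open_t: list[int] = []
    open_nest = ""
    open_rfid: Optional[str] = None
    below_run = 0
    is_open = False
    n_dropped = 0
    n_empty_patterns = 0

    def close(truncated: bool) -> None:
        nonlocal is_open, below_run, n_empty_patterns
        # strip every trailing below-threshold sample
        k = len(open_w)
        while k and open_w[k - 1] <= thr:
            k -= 1
        if k:
            patterns.append(
                Pattern(
                    weights=np.array(open_w[:k]),
                    stable=np.array(open_s[:k], dtype=bool),
                    ticks=np.array(open_t[:k], dtype=np.int64),
                    nest_id=open_nest,
                    rfid=open_rfid,
                    sps=cfg.sps,
                    truncated=truncated,
                )
            )
        else:
            n_empty_patterns += 1
        open_w.clear()
        open_s.clear()
        open_t.clear()
        is_open = False
        below_run = 0

    for i in range(n):
        raw = raws[i]
        corrected = raw if identity else gain * raw + offset
        cal = corrected - state.tare
        if not is_open:
            if cal > thr:
                is_open = True
                below_run = 0
                open_nest = nest_ids[i]
                open_rfid = rfids[i]
                if cal <= high:
                    open_w.append(cal)
                    open_s.append(stables[i])
                    open_t.append(ticks[i])
                else:
                    n_dropped += 1
            else:
                # empty pan: fold the corrected reading into the tare
                state._push(corrected)
                if state._n == 1:
                    state.tare = corrected
                else:
                    buf = (
                        state._buf[: state._n]
                        if state._n < len(state._buf)
                        else state._buf
                    )
                    state.tare = _irls_location(
                        buf, state.tare, cfg.irls_max_iter, cfg.irls_tol
                    )
                state.n_updates += 1
        else:
            if open_rfid is None and rfids[i] is not None:
                open_rfid = rfids[i]
            if cal <= thr:
                below_run += 1
                open_w.append(cal)
                open_s.append(stables[i])
                open_t.append(ticks[i])
                if below_run >= cfg.end_consecutive_below:
                    close(truncated=False)
            elif cal <= high:
                below_run = 0
                open_w.append(cal)
                open_s.append(stables[i])
                open_t.append(ticks[i])
            else:
                # wind outlier above range: dropped from the pattern, but
                # the pan is plainly not empty, so the consecutive
                # below-threshold run is broken
                below_run = 0
                n_dropped += 1

    if is_open:
        close(truncated=True)

    logger.info(
        "segment_stream: %d samples -> %d patterns "
        "(%d outliers dropped, %d empty openings, %d tare updates, tare=%.3f g)",
        n, len(patterns), n_dropped, n_empty_patterns, state.n_updates, state.tare,
    )
    return patterns, state


def _as_columns(stream):
    """Normalize a stream to parallel columns (ticks, raw, stable, nest, rfid)."""
    if hasattr(stream, "ticks"):  # SampleLog-like columnar store
        ticks = np.asarray(stream.ticks, dtype=np.int64)
        raws = np.asarray(stream.raw_weights, dtype=float)
        stables = np.asarray(stream.stable, dtype=bool)
        nest_ids = stream.nest_ids
        rfids = stream.rfids
    else:
        samples: Sequence[RawSample] = list(stream)
        ticks = np.array([s.tick for s in samples], dtype=np.int64)
        raws = np.array([s.raw_weight for s in samples], dtype=float)
        stables = np.array([s.stable for s in samples], dtype=bool)
        nest_ids = [s.nest_id for s in samples]
        rfids = [s.rfid for s in samples]
    if len(ticks) > 1 and not (np.diff(ticks) > 0).all():
        raise ValueError("stream ticks must be strictly increasing")
    if not np.isfinite(raws).all():
        raise ValueError("raw weights must be finite")
    return ticks, raws, stables, nest_ids, rfids
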