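"""End-to-end glue: stream -> patterns -> estimates / training examples.

Used by the command-line interface and by evaluation scripts; each step is
the corresponding module operation, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .acquisition import (AcquisitionConfig, GainCalibration, IDENTITY_GAIN,
                          Pattern, TareState, segment_stream, validate_pattern)
from .estimator import MLPParameters, WeightEstimate, estimate_weight
from .simulator import VisitEvent
from .training import TrainConfig, TrainingExample, build_training_set

__all__ = [
    "extract_valid_patterns",
    "estimate_stream",
    "match_events",
    "pipeline_errors",
]


def extract_valid_patterns(
    stream,
    acq: AcquisitionConfig,
    gain_cal: GainCalibration = IDENTITY_GAIN,
    initial_tare: float = 0.0,
) -> tuple[list[Pattern], TareState, int]:
    """Segment a stream and keep only valid patterns.

    Returns (valid patterns, final tare state, number discarded).
    """
    state = TareState(tare=initial_tare, window=acq.tare_window)
    patterns, state = segment_stream(stream, state, acq, gain_cal)
    valid = [p for p in patterns if validate_pattern(p, acq)]
    return valid, state, len(patterns) - len(valid)


def estimate_stream(
    stream,
    acq: AcquisitionConfig,
    params: MLPParameters,
    step: float = 1.0,
    gain_cal: GainCalibration = IDENTITY_GAIN,
) -> list[WeightEstimate]:
    """One estimate per valid pattern of a raw stream."""
    valid, _, _ = extract_valid_patterns(stream, acq, gain_cal)
    return [estimate_weight(p, params, step=step) for p in valid]


def match_events(
    patterns: Sequence[Pattern], events: Sequence[VisitEvent]
) -> list[tuple[Pattern, VisitEvent]]:
    """Pair each pattern with the ground-truth visit containing its start
    tick (patterns born from wind artefacts stay unmatched)."""
    pairs = []
    starts = np.array([e.arrival_tick for e in events])
    ends = np.array([e.departure_tick for e in events])
    for p in patterns:
        i = np.searchsorted(starts, p.start_tick, side="right") - 1
        if i >= 0 and p.start_tick <= ends[i]:
            pairs.append((p, events[i]))
    return pairs


def pipeline_errors(
    patterns: Sequence[Pattern],
    events: Sequence[VisitEvent],
    params: MLPParameters,
    step: float = 1.0,
) -> np.ndarray:
    """Signed estimation errors (grams) of matched patterns vs ground truth."""
    pairs = match_events(patterns, events)
    errs = [estimate_weight(p, params, step=step).grams - e.true_weight
            for p, e in pairs]
    return np.array(errs)
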