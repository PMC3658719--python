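import numpy as np
import pytest

from nestscale import AcquisitionConfig, SimulatorConfig, TareState


@pytest.fixture
def acq() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture
def simcfg() -> SimulatorConfig:
    return SimulatorConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def zero_tare() -> TareState:
    return TareState(tare=0.0, window=64)


# ---------------------------------------------------------------------------
# Independent brute-force references (kept deliberately naive and separate
# from the implementation they check).

def brute_force_features(seq, step=1.0):
    """Frequency/run-length reference via Counter + groupby."""
    from collections import Counter
    from itertools import groupby

    q = []
    for w in seq:
        sign = -1.0 if w < 0 else 1.0
        q.append(sign * np.floor(abs(w) / step + 0.5) * step)
    freq = sorted(Counter(q).items(), key=lambda kv: (kv[1], kv[0]),
                  reverse=True)
    runs = sorted(((k, len(list(g))) for k, g in groupby(q)),
                  key=lambda kv: (kv[1], kv[0]), reverse=True)
    max_1, n_1 = freq[0]
    max_2, n_2 = freq[1] if len(freq) > 1 else (0.0, 0)
    (max_c1, nc_1) = runs[0]
    (max_c2, nc_2) = runs[1] if len(runs) > 1 else (0.0, 0)
    return [max_1, n_1, max_2, n_2, max_c1, nc_1, max_c2, nc_2, len(q)]


def reference_segment(weights, thr=50.0, end_below=5, high=300.0):
    """Two-pass segmentation reference on pre-calibrated weights.

    Finds maximal above-threshold regions allowing sub-critical dips,
    trims trailing below-threshold samples and drops above-range samples.
    Valid only for streams whose tare stays at zero (all empty-pan values
    exactly 0).  Returns (patterns as lists of (index, weight), spans as
    (open_index, last_processed_index), truncated flags).
    """
    n = len(weights)
    patterns, spans, trunc = [], [], []
    i = 0
    while i < n:
        if weights[i] > thr:
            start = i
            below = 0
            j = i
            closed = False
            while j < n:
                if weights[j] <= thr:
                    below += 1
                    if below >= end_below:
                        closed = True
                        break
                else:
                    below = 0
                j += 1
            end = j if closed else n - 1  # last index consumed by the pattern
            kept = [(k, weights[k]) for k in range(start, end + 1)
                    if weights[k] <= high]
            while kept and kept[-1][1] <= thr:
                kept.pop()
            if kept:
                patterns.append(kept)
                trunc.append(not closed)
            spans.append((start, end))
            i = end + 1
        else:
            i += 1
    return patterns, spans, trunc
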