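"""The nine pattern-summary variables feeding the MLP estimator.

A weight pattern is summarized by frequency and run-length statistics of
its quantized readings: the two most repeated values and their counts
(``max_1``/``n_1``, ``max_2``/``n_2``), the two longest runs of identical
consecutive values (``max_c1``/``nc_1``, ``max_c2``/``nc_2``) and the total
number of measurements ``n_el``.  Every tie resolves to the larger weight
value.  When the pattern holds fewer than two distinct values (or runs) the
second-place slots are zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import Pattern
from .errors import DegenerateInputError

__all__ = ["FeatureVector", "quantize", "extract_features", "FEATURE_NAMES"]

FEATURE_NAMES = (
    "max_1", "n_1", "max_2", "n_2",
    "max_c1", "nc_1", "max_c2", "nc_2", "n_el",
)


@dataclass(frozen=True)
class FeatureVector:
    """Nine summary variables of one weight pattern (grams and counts)."""

    max_1: float
    n_1: int
    max_2: float
    n_2: int
    max_c1: float
    nc_1: int
    max_c2: float
    nc_2: int
    n_el: int

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.max_1, self.n_1, self.max_2, self.n_2,
             self.max_c1, self.nc_1, self.max_c2, self.nc_2, self.n_el],
            dtype=float,
        )

    @classmethod
    def from_array(cls, a) -> "FeatureVector":
        a = np.asarray(a, dtype=float)
        if a.shape != (9,):
            raise ValueError(f"expected 9 features, got shape {a.shape}")
        return cls(
            max_1=float(a[0]), n_1=int(a[1]), max_2=float(a[2]), n_2=int(a[3]),
            max_c1=float(a[4]), nc_1=int(a[5]), max_c2=float(a[6]), nc_2=int(a[7]),
            n_el=int(a[8]),
        )


def quantize(weights, step: float = 1.0) -> np.ndarray:
    """Round each weight to the nearest multiple of ``step``.

    Exact half-way ties round away from zero (150.5 -> 151 at 1 g), which is
    how a device with a fixed display resolution reports.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    w = np.asarray(weights, dtype=float)
    return np.sign(w) * np.floor(np.abs(w) / step + 0.5) * step


def extract_features(
    p: Pattern | np.ndarray,
    step: float = 1.0,
    exclude_stable: bool = False,
) -> FeatureVector:
    """Compute the nine summary variables of a pattern.

    Parameters
    ----------
    p
        A segmented :class:`~nestscale.acquisition.Pattern`, or a bare
        weight sequence.
    step
        Quantization step in grams applied before counting repetitions.
    exclude_stable
        Drop the stable-flagged samples first (used when building training
        targets, where the stable mean is the target and the features must
        describe only the unstable remainder).
    """
    if isinstance(p, Pattern):
        weights = p.unstable_weights() if exclude_stable else p.weights
    else:
        if exclude_stable:
            raise ValueError("exclude_stable requires a Pattern with flags")
        weights = np.asarray(p, dtype=float)
    if len(weights) == 0:
        raise DegenerateInputError("no measurements left to extract features from")

    q = quantize(weights, step)

    # frequency features over distinct values; count ties -> larger value
    vals, counts = np.unique(q, return_counts=True)
    order = np.lexsort((vals, counts))  # ascending by (count, value)
    max_1, n_1 = float(vals[order[-1]]), int(counts[order[-1]])
    if len(vals) > 1:
        max_2, n_2 = float(vals[order[-2]]), int(counts[order[-2]])
    else:
        max_2, n_2 = 0.0, 0

    # run-length features; length ties -> larger value
    change = np.nonzero(np.diff(q))[0]
    starts = np.concatenate(([0], change + 1))
    lengths = np.diff(np.concatenate((starts, [len(q)])))
    rvals = q[starts]
    rorder = np.lexsort((rvals, lengths))
    max_c1, nc_1 = float(rvals[rorder[-1]]), int(lengths[rorder[-1]])
    if len(rvals) > 1:
        max_c2, nc_2 = float(rvals[rorder[-2]]), int(lengths[rorder[-2]])
    else:
        max_c2, nc_2 = 0.0, 0

    return FeatureVector(
        max_1=max_1, n_1=n_1, max_2=max_2, n_2=n_2,
        max_c1=max_c1, nc_1=nc_1, max_c2=max_c2, nc_2=nc_2,
        n_el=int(len(q)),
    )
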