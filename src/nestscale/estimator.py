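"""Per-pattern weight estimation and the accuracy metric.

Two estimation paths, dispatched on the device stability flags:

* ``stable_mean`` — when the pattern contains stable readings, the weight
  is their arithmetic mean (the scale is trusted to be unbiased while the
  animal stands still);
* ``mlp`` — otherwise, the nine pattern features are fed through a small
  feed-forward sigmoid network (9 inputs, one hidden layer, 1 output) and
  the output activation is rescaled to grams by a resample factor R.

Accuracy against a manual capture is reported as
``100 * (1 - |manual - estimated| / manual)`` percent, two decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .acquisition import Pattern
from .errors import ConfigurationError, DegenerateInputError
from .features import FeatureVector, extract_features

__all__ = [
    "InputScaling",
    "MLPParameters",
    "WeightEstimate",
    "stable_mean",
    "mlp_forward",
    "forward_scaled",
    "estimate_weight",
    "accuracy_percent",
    "reference_parameters",
    "save_parameters",
    "load_parameters",
]


@dataclass(frozen=True)
class InputScaling:
    """How raw feature values are mapped into the network's input range.

    Weight-valued features (max_1, max_2, max_c1, max_c2) are divided by
    ``weight_divisor`` (grams); count-valued features (n_1, n_2, nc_1,
    nc_2, n_el) by ``count_divisor`` (samples, default 2048 = 128 s at
    16 sps).
    """

    weight_divisor: float = 300.0
    count_divisor: float = 2048.0

    def scale(self, f: FeatureVector) -> np.ndarray:
        a = f.to_array()
        d = np.array([self.weight_divisor, self.count_divisor] * 4
                     + [self.count_divisor])
        return a / d


@dataclass
class MLPParameters:
    """Weights of the 9-H-1 sigmoid perceptron plus its I/O conventions.

    ``hidden_weights`` has shape (9, H) — entry [j, k] multiplies input j
    into hidden neuron k; ``output_weights`` has shape (H,).  The output
    neuron's (0, 1) activation times ``resample_factor`` (R, grams) is the
    estimate.  ``sigmoid_orientation`` selects the standard logistic
    sigma(x) = 1/(1+exp(-x)) or the reversed ``as_printed`` variant
    1/(1+exp(x)) kept for fidelity experiments.
    """

    hidden_weights: np.ndarray
    hidden_biases: np.ndarray
    output_weights: np.ndarray
    output_bias: float
    resample_factor: float = 300.0
    input_scaling: InputScaling = field(default_factory=InputScaling)
    sigmoid_orientation: str = "standard"

    def __post_init__(self) -> None:
        self.hidden_weights = np.asarray(self.hidden_weights, dtype=float)
        self.hidden_biases = np.asarray(self.hidden_biases, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        n_in, h = self.hidden_weights.shape
        if self.hidden_biases.shape != (h,) or self.output_weights.shape != (h,):
            raise ConfigurationError("inconsistent layer shapes")
        if self.resample_factor <= 0:
            raise ConfigurationError("resample_factor must be > 0")
        if self.sigmoid_orientation not in ("standard", "as_printed"):
            raise ConfigurationError(
                f"unknown sigmoid orientation {self.sigmoid_orientation!r}"
            )

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        n_in, h = self.hidden_weights.shape
        return (n_in, h, 1)

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.layer_sizes),
            "hidden_weights": self.hidden_weights.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_bias": self.output_bias,
            "resample_factor": self.resample_factor,
            "input_scaling": {
                "weight_divisor": self.input_scaling.weight_divisor,
                "count_divisor": self.input_scaling.count_divisor,
            },
            "sigmoid_orientation": self.sigmoid_orientation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPParameters":
        return cls(
            hidden_weights=np.array(d["hidden_weights"], dtype=float),
            hidden_biases=np.array(d["hidden_biases"], dtype=float),
            output_weights=np.array(d["output_weights"], dtype=float),
            output_bias=float(d["output_bias"]),
            resample_factor=float(d.get("resample_factor", 300.0)),
            input_scaling=InputScaling(**d.get("input_scaling", {})),
            sigmoid_orientation=d.get("sigmoid_orientation", "standard"),
        )


@dataclass(frozen=True)
class WeightEstimate:
    """One estimated body weight with its provenance.

    ``stable_tag`` is true exactly when the estimate came from averaging
    stable readings; it travels with the telemetry record so downstream
    analyses can weight the two estimate classes differently.
    """

    grams: float
    method: str  # "stable_mean" | "mlp"
    stable_tag: bool
    nest_id: str = ""
    rfid: Optional[str] = None
    tick_range: tuple[int, int] = (0, 0)


def stable_mean(p: Pattern) -> WeightEstimate:
    """Arithmetic mean of the pattern's stable readings."""
    sw = p.stable_weights()
    if len(sw) == 0:
        raise DegenerateInputError("pattern has no stable samples")
    return WeightEstimate(
        grams=float(sw.mean()),
        method="stable_mean",
        stable_tag=True,
        nest_id=p.nest_id,
        rfid=p.rfid,
        tick_range=(p.start_tick, p.end_tick),
    )


def _sigmoid(z: np.ndarray, orientation: str) -> np.ndarray:
    if orientation == "as_printed":
        z = -z
    return 1.0 / (1.0 + np.exp(-z))


def forward_scaled(x: np.ndarray, params: MLPParameters) -> float:
    """Feed an already-scaled input vector through the network.

    Returns grams: R times the output neuron's activation, hence bounded
    in (0, R) for any finite input.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.layer_sizes[0],):
        raise ConfigurationError(
            f"expected {params.layer_sizes[0]} inputs, got shape {x.shape}"
        )
    h = _sigmoid(x @ params.hidden_weights + params.hidden_biases,
                 params.sigmoid_orientation)
    out = _sigmoid(np.array([h @ params.output_weights + params.output_bias]),
                   params.sigmoid_orientation)[0]
    return float(params.resample_factor * out)


def mlp_forward(f: FeatureVector, params: MLPParameters) -> float:
    """Scale a feature vector per ``params.input_scaling`` and run the net."""
    return forward_scaled(params.input_scaling.scale(f), params)


def estimate_weight(
    p: Pattern, params: MLPParameters, step: float = 1.0
) -> WeightEstimate:
    """Estimate one validated pattern: stable mean if any stable sample
    exists, MLP regression on the nine features otherwise."""
    if p.has_stable:
        return stable_mean(p)
    f = extract_features(p, step=step, exclude_stable=False)
    return WeightEstimate(
        grams=mlp_forward(f, params),
        method="mlp",
        stable_tag=False,
        nest_id=p.nest_id,
        rfid=p.rfid,
        tick_range=(p.start_tick, p.end_tick),
    )


def accuracy_percent(manual: float, estimated: float) -> float:
    """Percent agreement with a manual capture, two decimals:
    ``100 * (1 - |manual - estimated| / manual)``."""
    if manual <= 0:
        raise ValueError("manual weight must be > 0")
    return round(100.0 * (1.0 - abs(manual - estimated) / manual), 2)


_REFERENCE_FILE = "reference_mlp.json"


def reference_parameters() -> MLPParameters:
    """The published 9-3-1 network weights shipped with the package.

    These connection weights come from the original field training (six
    decimals); the original input scaling and resample factor were never
    published, so this fixture verifies the forward pass, while
    gram-accurate estimation on new data requires retraining under the
    declared :class:`InputScaling`.
    """
    text = resources.files("nestscale.data").joinpath(_REFERENCE_FILE).read_text()
    return MLPParameters.from_dict(json.loads(text))


def save_parameters(params: MLPParameters, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=1)


def load_parameters(path) -> MLPParameters:
    with open(path) as fh:
        return MLPParameters.from_dict(json.load(fh))
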