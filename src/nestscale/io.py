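"""File formats and configuration.

One CSV dialect per record type, each with a JSON-lines mirror:

* sample log — ``tick,raw_weight_g,stable,nest_id,rfid`` (stable is 0/1,
  missing rfid is an empty field);
* ground-truth events —
  ``rfid,true_weight_g,arrival_tick,departure_tick,had_stable_run``;
* estimates — ``nest_id,rfid,start_tick,end_tick,weight_g,method,stable_tag``.

Configuration is a single YAML file whose sections mirror the module
config dataclasses (``acquisition``, ``simulator``, ``training``,
``features``, ``telemetry``); key names equal field names.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
import yaml

from .acquisition import AcquisitionConfig, RawSample
from .estimator import WeightEstimate
from .simulator import SimulatorConfig, VisitEvent

__all__ = [
    "SampleLog",
    "RunConfig",
    "load_config",
    "write_sample_log",
    "read_sample_log",
    "write_events",
    "read_events",
    "write_estimates",
    "read_estimates",
]

SAMPLE_COLUMNS = ["tick", "raw_weight_g", "stable", "nest_id", "rfid"]
EVENT_COLUMNS = ["rfid", "true_weight_g", "arrival_tick", "departure_tick",
                 "had_stable_run"]
ESTIMATE_COLUMNS = ["nest_id", "rfid", "start_tick", "end_tick", "weight_g",
                    "method", "stable_tag"]


@dataclass
class SampleLog:
    """Columnar raw sample stream (the fast in-memory mirror of the CSV)."""

    ticks: np.ndarray
    raw_weights: np.ndarray
    stable: np.ndarray
    nest_ids: list[str]
    rfids: list[Optional[str]]

    def __post_init__(self) -> None:
        self.ticks = np.asarray(self.ticks, dtype=np.int64)
        self.raw_weights = np.asarray(self.raw_weights, dtype=float)
        self.stable = np.asarray(self.stable, dtype=bool)
        n = len(self.ticks)
        if not (len(self.raw_weights) == len(self.stable)
                == len(self.nest_ids) == len(self.rfids) == n):
            raise ValueError("SampleLog columns must have equal length")

    def __len__(self) -> int:
        return len(self.ticks)

    def __iter__(self) -> Iterator[RawSample]:
        for i in range(len(self)):
            yield RawSample(
                tick=int(self.ticks[i]),
                raw_weight=float(self.raw_weights[i]),
                stable=bool(self.stable[i]),
                nest_id=self.nest_ids[i],
                rfid=self.rfids[i],
            )

    @classmethod
    def from_samples(cls, samples) -> "SampleLog":
        samples = list(samples)
        return cls(
            ticks=np.array([s.tick for s in samples], dtype=np.int64),
            raw_weights=np.array([s.raw_weight for s in samples]),
            stable=np.array([s.stable for s in samples], dtype=bool),
            nest_ids=[s.nest_id for s in samples],
            rfids=[s.rfid for s in samples],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tick": self.ticks,
            "raw_weight_g": self.raw_weights,
            "stable": self.stable.astype(int),
            "nest_id": self.nest_ids,
            "rfid": ["" if r is None else r for r in self.rfids],
        })


def write_sample_log(log: SampleLog, path, fmt: str = "csv") -> None:
    df = log.to_frame()
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.3f")
    elif fmt == "jsonl":
        df.to_json(path, orient="records", lines=True)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_sample_log(path, fmt: str = "csv") -> SampleLog:
    """Read a sample log; a malformed row raises with its line number."""
    if fmt == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif fmt == "jsonl":
        df = pd.read_json(path, orient="records", lines=True, dtype=str)
        df = df.fillna("")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ticks = _strict_numeric(df["tick"], "tick", int)
    raws = _strict_numeric(df["raw_weight_g"], "raw_weight_g", float)
    stable = _strict_numeric(df["stable"], "stable", int)
    if not np.isin(stable, (0, 1)).all():
        bad = int(np.flatnonzero(~np.isin(stable, (0, 1)))[0])
        raise ValueError(f"{path}: line {bad + 2}: stable flag must be 0 or 1")
    rfids = [None if r == "" else str(r) for r in df["rfid"]]
    return SampleLog(
        ticks=ticks,
        raw_weights=raws,
        stable=stable.astype(bool),
        nest_ids=[str(x) for x in df["nest_id"]],
        rfids=rfids,
    )


def _strict_numeric(col: pd.Series, name: str, kind):
    converted = pd.to_numeric(col, errors="coerce")
    bad = converted.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(f"line {line}: bad {name} value {col.iloc[line - 2]!r}")
    arr = converted.to_numpy()
    return arr.astype(np.int64) if kind is int else arr.astype(float)


def write_events(events: list[VisitEvent], path) -> None:
    df = pd.DataFrame(
        [{
            "rfid": e.rfid or "",
            "true_weight_g": e.true_weight,
            "arrival_tick": e.arrival_tick,
            "departure_tick": e.departure_tick,
            "had_stable_run": int(e.had_stable_run),
        } for e in events],
        columns=EVENT_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.3f")


def read_events(path) -> list[VisitEvent]:
    df = pd.read_csv(path, dtype={"rfid": str}, keep_default_na=False)
    return [
        VisitEvent(
            true_weight=float(r.true_weight_g),
            arrival_tick=int(r.arrival_tick),
            departure_tick=int(r.departure_tick),
            rfid=r.rfid or None,
            had_stable_run=bool(int(r.had_stable_run)),
        )
        for r in df.itertuples()
    ]


def write_estimates(estimates: list[WeightEstimate], path, fmt: str = "csv") -> None:
    df = pd.DataFrame(
        [{
            "nest_id": e.nest_id,
            "rfid": e.rfid or "",
            "start_tick": e.tick_range[0],
            "end_tick": e.tick_range[1],
            "weight_g": round(e.grams, 3),
            "method": e.method,
            "stable_tag": int(e.stable_tag),
        } for e in estimates],
        columns=ESTIMATE_COLUMNS,
    )
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "jsonl":
        df.to_json(path, orient="records", lines=True)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_estimates(path, fmt: str = "csv") -> list[WeightEstimate]:
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"rfid": str, "nest_id": str},
                         keep_default_na=False)
    else:
        df = pd.read_json(path, orient="records", lines=True)
    return [
        WeightEstimate(
            grams=float(r.weight_g),
            method=str(r.method),
            stable_tag=bool(int(r.stable_tag)),
            nest_id=str(r.nest_id),
            rfid=(str(r.rfid) or None) if r.rfid != "" else None,
            tick_range=(int(r.start_tick), int(r.end_tick)),
        )
        for r in df.itertuples()
    ]


@dataclass
class RunConfig:
    """Top-level configuration tying the pipeline together."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    training: "TrainConfig" = None  # type: ignore[assignment]
    telemetry: "LinkConfig" = None  # type: ignore[assignment]
    feature_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.training is None:
            from .training import TrainConfig
            self.training = TrainConfig()
        if self.telemetry is None:
            from .telemetry import LinkConfig
            self.telemetry = LinkConfig()


def _build(cls, data: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")
    # YAML lists for tuple-typed fields
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def load_config(path=None, seed: Optional[int] = None) -> RunConfig:
    """Load a YAML run configuration; omitted keys keep their defaults."""
    from .telemetry import LinkConfig
    from .training import TrainConfig

    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    known = {"acquisition", "simulator", "training", "telemetry",
             "feature_step", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    cfg = RunConfig(
        acquisition=_build(AcquisitionConfig, raw.get("acquisition", {}),
                           "acquisition"),
        simulator=_build(SimulatorConfig, raw.get("simulator", {}), "simulator"),
        training=_build(TrainConfig, raw.get("training", {}), "training"),
        telemetry=_build(LinkConfig, raw.get("telemetry", {}), "telemetry"),
        feature_step=float(raw.get("feature_step", 1.0)),
        seed=int(raw.get("seed", 0)),
    )
    if seed is not None:
        cfg.seed = seed
    return cfg
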