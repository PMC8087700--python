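"""Curve containers and their CSV dialect.

Every CSV written by the package starts with a single ``#``-prefixed line
holding a JSON document with the configuration needed to reproduce it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def _write_csv(path, df: pd.DataFrame, meta: dict):
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(meta, default=str) + "\n")
        df.to_csv(fh, index=False)


def _read_csv(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        first = fh.readline()
        if first.startswith("#"):
            meta = json.loads(first.lstrip("# "))
        else:
            fh.seek(pos)
        df = pd.read_csv(fh, comment="#")
    return df, meta


@dataclass
class TheoryCurve:
    """S(parameter) from the deterministic solver."""

    param_name: str
    grid: np.ndarray
    S: np.ndarray
    u: np.ndarray
    branching: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_csv(self, path):
        df = pd.DataFrame({
            "param": self.param_name,
            "value": self.grid,
            "S_theory": self.S,
            "u": self.u,
            "branching_factor": self.branching,
        })
        _write_csv(path, df, {"type": "theory_curve",
                              "param": self.param_name, **self.meta})

    @classmethod
    def from_csv(cls, path) -> "TheoryCurve":
        df, meta = _read_csv(path)
        return cls(param_name=str(df["param"].iloc[0]),
                   grid=df["value"].to_numpy(float),
                   S=df["S_theory"].to_numpy(float),
                   u=df["u"].to_numpy(float),
                   branching=df["branching_factor"].to_numpy(float),
                   meta=meta)


@dataclass
class EnsembleCurve:
    """Mean simulated S over a parameter sweep, with standard errors."""

    param_name: str
    grid: np.ndarray
    S_mean: np.ndarray
    S_se: np.ndarray
    n_reps: int
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.S_mean = np.asarray(self.S_mean, dtype=float)
        self.S_se = np.asarray(self.S_se, dtype=float)
        if np.any(self.S_mean < -1e-12) or np.any(self.S_mean > 1 + 1e-12):
            raise ValueError("mean S outside [0, 1]")
        if np.any(self.S_se < 0):
            raise ValueError("negative standard error")

    @property
    def degenerate(self) -> bool:
        """True when a single replicate makes the spread meaningless."""
        return self.n_reps < 2

    def to_csv(self, path):
        df = pd.DataFrame({
            "param": self.param_name,
            "value": self.grid,
            "S_mean": self.S_mean,
            "S_se": self.S_se,
            "n_reps": self.n_reps,
        })
        _write_csv(path, df, {"type": "ensemble_curve", "seed": self.seed,
                              "param": self.param_name, **self.meta})

    @classmethod
    def from_csv(cls, path) -> "EnsembleCurve":
        df, meta = _read_csv(path)
        return cls(param_name=str(df["param"].iloc[0]),
                   grid=df["value"].to_numpy(float),
                   S_mean=df["S_mean"].to_numpy(float),
                   S_se=df["S_se"].to_numpy(float),
                   n_reps=int(df["n_reps"].iloc[0]),
                   seed=meta.get("seed"), meta=meta)
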