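"""Per-frame scalar observables and distance histograms."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class TimeSeries:
    """A windowed per-frame scalar observable with units."""

    times: np.ndarray  # ns
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    def mean(self) -> float:
        return float(np.mean(self.values))

    def std(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self) > 1 else 0.0

    def to_frame(self, value_column: str = "value") -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, value_column: self.values})


@dataclass
class Histogram:
    """Binned distances: ``counts[i]`` covers ``edges[i] <= x < edges[i+1]``."""

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(np.diff(self.edges) <= 0):
            raise ValidationError("histogram edges must be strictly increasing")
        if self.counts.size != self.edges.size - 1:
            raise ValidationError("need one count per bin")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_values(cls, values: np.ndarray, edges: np.ndarray) -> "Histogram":
        counts, _ = np.histogram(values, bins=edges)
        return cls(edges, counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.edges[:-1],
            "bin_right": self.edges[1:],
            "count": self.counts,
        })
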