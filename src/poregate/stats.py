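"""Replicate-level statistics: one-way ANOVA and replicate-count sizing.

Channel states are compared across replicate simulations by pooling one
summary value per replicate (by default the mean gate distance over the
trailing 5 ns window) per condition and testing with a classical one-way
ANOVA. Power-based sizing answers how many replicate simulations per
condition a given effect requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegeneracyError, ValidationError


@dataclass(frozen=True)
class ReplicateSet:
    """condition label -> per-replicate summary values."""

    groups: Mapping[str, Sequence[float]]

    def __post_init__(self):
        if len(self.groups) < 2:
            raise ValidationError("need at least 2 conditions for testing")
        for label, vals in self.groups.items():
            if len(vals) < 2:
                raise ValidationError(
                    f"condition {label!r} needs at least 2 replicates"
                )

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.groups.values())


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float


def one_way_anova(replicates: ReplicateSet) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA: F = MS_between / MS_within."""
    arrays = [np.asarray(v, dtype=float) for v in replicates.groups.values()]
    if all(np.allclose(a, a[0]) for a in arrays):
        raise DegeneracyError("zero within-group variance in every group")
    f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = replicates.n_total
    return AnovaResult(F=float(f), df_between=k - 1, df_within=n - k,
                       p_value=float(p))


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Conservative family-wise correction applied when several gates or
    conditions are tested in one run."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample sizing inputs: effect delta and noise sigma share units."""

    delta: float
    sigma: float
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if not (0.0 < self.power < 1.0):
            raise ValidationError("power must lie in (0, 1)")
        if self.delta == 0:
            raise ValidationError("a zero effect cannot be powered")


def required_replicates(spec: PowerSpec, refine_t: bool = False) -> int:
    """Minimum replicates per condition (two-sided two-sample comparison).

    Normal approximation n = ceil(2 ((z_{1-alpha/2} + z_{power}) sigma /
    delta)^2), floored at 2; ``refine_t`` iterates the same formula with t
    quantiles at the implied degrees of freedom until stable.
    """
    z_a = sps.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = sps.norm.ppf(spec.power)
    ratio = spec.sigma / abs(spec.delta)
    n = max(2, math.ceil(2.0 * ((z_a + z_b) * ratio) ** 2))
    if refine_t:
        for _ in range(10):
            df = max(1, 2 * n - 2)
            t_a = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
            t_b = sps.t.ppf(spec.power, df)
            n_new = max(2, math.ceil(2.0 * ((t_a + t_b) * ratio) ** 2))
            if n_new == n:
                break
            n = n_new
    return n
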