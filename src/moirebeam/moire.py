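"""Closed-form moire-fringe analytics for pairs of rotated line gratings.

Two multi-slit collimators with periods ``T1`` and ``T2`` overlaid at a
relative angle ``theta`` produce a moire pattern whose period is

    T = T1 * T2 / sqrt(T1**2 + T2**2 - 2*T1*T2*cos(theta))

which for equal periods reduces to ``T / (2 sin(theta/2))``.  The moire
period equals the geometric center-to-center distance (CTC) of the dose
pattern a dual-collimator system produces, so these closed forms are the
design primitives: forward period prediction, inverse angle design for a
target CTC, and parameter sweep tables.

Angles are degrees at the API boundary and radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "GratingPairSpec",
    "MoireResult",
    "moire_period",
    "solve_angle_for_ctc",
    "analytic_sweep",
]


@dataclass(frozen=True)
class GratingPairSpec:
    """Periods (mm) of the two gratings and their relative angle (degrees).

    The triple ``T1 == T2`` with ``theta == 0`` is geometrically degenerate:
    the two gratings coincide and the moire period is infinite.
    """

    period1: float
    period2: float
    angle_deg: float

    def __post_init__(self) -> None:
        if not (self.period1 > 0 and self.period2 > 0):
            raise ValueError(
                f"grating periods must be positive, got "
                f"({self.period1}, {self.period2})"
            )
        if not (0.0 <= self.angle_deg <= 90.0):
            raise ValueError(
                f"relative angle must lie in [0, 90] degrees, got {self.angle_deg}"
            )

    @property
    def degenerate(self) -> bool:
        return self.angle_deg == 0.0 and self.period1 == self.period2


@dataclass(frozen=True)
class MoireResult:
    """Moire period in mm; ``math.inf`` with ``degenerate=True`` when the
    gratings coincide."""

    period: float
    degenerate: bool


def moire_period(spec: GratingPairSpec) -> MoireResult:
    """Moire period of two line gratings overlaid at a relative angle.

    Uses the symmetric form ``T1*T2 / sqrt(T1^2 + T2^2 - 2 T1 T2 cos θ)``
    (algebraically identical to dividing through by ``T2``), which is exactly
    swap-symmetric in floating point as well.
    """
    t1, t2 = spec.period1, spec.period2
    theta = math.radians(spec.angle_deg)
    denom_sq = t1 * t1 + t2 * t2 - 2.0 * t1 * t2 * math.cos(theta)
    if denom_sq <= 0.0:
        # only reachable for T1 == T2, theta == 0 (identical aligned gratings)
        return MoireResult(period=math.inf, degenerate=True)
    return MoireResult(period=t1 * t2 / math.sqrt(denom_sq), degenerate=False)


def _period_bounds(t1: float, t2: float) -> tuple[float, float]:
    """Achievable (min, max) moire period for angles in (0, 90]."""
    pmin = moire_period(GratingPairSpec(t1, t2, 90.0)).period
    if t1 == t2:
        pmax = math.inf
    else:
        pmax = t1 * t2 / abs(t1 - t2)  # theta -> 0 limit
    return pmin, pmax


def solve_angle_for_ctc(
    period1: float, period2: float, target_period: float
) -> float:
    """Invert the moire-period formula: the angle (degrees) at which two
    gratings produce a moire period equal to ``target_period`` mm.

    The period is strictly decreasing in angle on (0, 90], so the solution
    is unique; it is found by bracketed root finding to ~1e-9 mm in period.

    Raises
    ------
    ValueError
        If the target lies outside the achievable period interval.
    """
    if target_period <= 0:
        raise ValueError(f"target period must be positive, got {target_period}")
    pmin, pmax = _period_bounds(period1, period2)
    if not (pmin <= target_period <= pmax):
        raise ValueError(
            f"target period {target_period} mm is not achievable for "
            f"T1={period1}, T2={period2}; achievable interval is "
            f"[{pmin:.6g}, {pmax:.6g}] mm"
        )

    def f(angle_deg: float) -> float:
        return moire_period(GratingPairSpec(period1, period2, angle_deg)).period - target_period

    lo = 1e-9
    if f(lo) < 0:  # target above what the numeric lower bracket reaches
        return lo
    return float(brentq(f, lo, 90.0, xtol=1e-12, rtol=8.9e-16))


def analytic_sweep(
    period1: float,
    period2: float,
    angles_deg: Iterable[float] | None = None,
    periods: Iterable[float] | None = None,
    angle_deg: float | None = None,
) -> pd.DataFrame:
    """Sweep table of analytical moire periods.

    Two modes:

    * angle sweep: fixed ``(period1, period2)``, one row per angle in
      ``angles_deg``;
    * period sweep: fixed ``angle_deg``, one row per collimator period in
      ``periods`` (the same period is assigned to both gratings).

    Returns a DataFrame with columns ``(parameter, analytical_period_mm)``;
    degenerate rows carry ``inf``.  Invalid entries raise with the row index.
    """
    if (angles_deg is None) == (periods is None):
        raise ValueError("provide exactly one of angles_deg or periods")

    rows: list[tuple[float, float]] = []
    if angles_deg is not None:
        for i, ang in enumerate(angles_deg):
            try:
                res = moire_period(GratingPairSpec(period1, period2, float(ang)))
            except ValueError as exc:
                raise ValueError(f"sweep row {i}: {exc}") from exc
            rows.append((float(ang), res.period))
    else:
        if angle_deg is None:
            raise ValueError("period sweep requires angle_deg")
        for i, per in enumerate(periods):  # type: ignore[union-attr]
            try:
                res = moire_period(GratingPairSpec(float(per), float(per), angle_deg))
            except ValueError as exc:
                raise ValueError(f"sweep row {i}: {exc}") from exc
            rows.append((float(per), res.period))
    if not rows:
        raise ValueError("empty sweep list")
    return pd.DataFrame(rows, columns=["parameter", "analytical_period_mm"])
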