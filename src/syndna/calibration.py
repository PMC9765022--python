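"""Per-sample spike-in calibration curves.

Each library's synDNA read counts, together with the known assigned
concentrations of the pool, define a standard curve.  The curve is fitted
by ordinary least squares on the log10–log10 scale —

    log10(mass) = intercept + slope × log10(CPM)

— matching the way spike-in dilution series behave over four decades of
concentration.  Inverting the fitted line converts any feature's CPM into
a DNA mass ("read weight"), the first step of absolute quantification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .pools import PoolSpec
from .seqio import SampleCounts, cpm

__all__ = [
    "CalibrationPoint",
    "CalibrationModel",
    "CalibrationError",
    "DegenerateDesignError",
    "fit_calibration",
    "predict_mass",
    "fit_all",
]


class CalibrationError(RuntimeError):
    """Calibration could not be fitted (too few usable points)."""


class DegenerateDesignError(CalibrationError):
    """All masses (or all CPM values) identical: slope undetermined."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One spike-in observation: assigned input mass vs observed CPM."""

    syndna_id: str
    mass: float
    cpm: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("assigned mass must be positive")
        if self.cpm < 0:
            raise ValueError("CPM cannot be negative")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted standard curve for one sample.

    ``slope`` and ``intercept`` parameterize
    log10(mass/ng) = intercept + slope × log10(x), with x on the scale
    named by ``x_scale`` (CPM by default).  ``log_scale=False`` marks a
    model fitted on the raw (linear) scale instead.
    """

    sample_id: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int
    x_scale: str = "cpm"
    log_scale: bool = True


def fit_calibration(
    points: Sequence[CalibrationPoint],
    min_points: int = 3,
    *,
    log_scale: bool = True,
    sample_id: str = "",
) -> CalibrationModel:
    """Ordinary least squares of log10(mass) on log10(CPM).

    Points with zero CPM are dropped (log10 undefined) with a warning.
    Raises :class:`CalibrationError` if fewer than ``min_points`` usable
    points remain, :class:`DegenerateDesignError` if all masses or all
    CPM values coincide.  ``log_scale=False`` fits mass ~ CPM on the raw
    scale instead (for comparison only).
    """
    usable = [p for p in points if p.cpm > 0]
    dropped = len(points) - len(usable)
    if dropped:
        warnings.warn(f"dropped {dropped} zero-CPM calibration point(s)")
    if len(usable) < min_points:
        raise CalibrationError(
            f"only {len(usable)} usable calibration points (need {min_points})"
        )
    masses = np.array([p.mass for p in usable], dtype=float)
    cpms = np.array([p.cpm for p in usable], dtype=float)
    if np.all(masses == masses[0]):
        raise DegenerateDesignError("all assigned masses identical")
    if np.all(cpms == cpms[0]):
        raise DegenerateDesignError("all CPM values identical")

    if log_scale:
        x, y = np.log10(cpms), np.log10(masses)
    else:
        x, y = cpms, masses
    fit = stats.linregress(x, y)
    return CalibrationModel(
        sample_id=sample_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_points=len(usable),
        log_scale=log_scale,
    )


def predict_mass(model: CalibrationModel, x: float | None) -> float | None:
    """Invert the standard curve: signal x (CPM) → DNA mass in ng.

    Returns None for missing or non-positive input (log10 undefined);
    strictly increasing in x when the slope is positive.
    """
    if x is None or (model.log_scale and x <= 0):
        return None
    if model.log_scale:
        return 10.0 ** (model.intercept + model.slope * math.log10(x))
    return model.intercept + model.slope * x


def fit_all(
    counts: SampleCounts | Sequence[SampleCounts],
    pool: PoolSpec,
    *,
    min_points: int = 3,
    average_replicates: bool = True,
    zero_policy: str = "drop",
    log_scale: bool = True,
) -> CalibrationModel:
    """Build calibration points from a pool's assignments and fit the curve.

    Accepts a single library or a list of replicate libraries.  With
    ``average_replicates`` (default) replicate CPM values are averaged on
    the log scale (geometric mean) before fitting, one point per synDNA;
    otherwise all replicate points enter the fit jointly.
    ``zero_policy="pseudocount"`` adds 0.5 reads to every synDNA count
    before computing CPM instead of dropping zero-CPM points.
    """
    if isinstance(counts, SampleCounts):
        replicates = [counts]
    else:
        replicates = list(counts)
    if zero_policy not in ("drop", "pseudocount"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")

    per_id_cpms: dict[str, list[float]] = {sid: [] for sid in pool.assignments}
    for sc in replicates:
        for sid in pool.assignments:
            if zero_policy == "pseudocount":
                value = 1e6 * (sc.counts.get(sid, 0) + 0.5) / sc.total_reads
            else:
                value = cpm(sc, sid)
            per_id_cpms[sid].append(value)

    points: list[CalibrationPoint] = []
    if average_replicates:
        for sid, mass in pool.assignments.items():
            vals = [v for v in per_id_cpms[sid] if v > 0]
            if not vals:
                points.append(CalibrationPoint(sid, mass, 0.0))
            else:
                geo = 10 ** float(np.mean(np.log10(vals)))
                points.append(CalibrationPoint(sid, mass, geo))
    else:
        for sid, mass in pool.assignments.items():
            for v in per_id_cpms[sid]:
                points.append(CalibrationPoint(sid, mass, v))

    usable = sum(1 for p in points if p.cpm > 0)
    if usable < min_points:
        missing = sorted(sid for sid, vs in per_id_cpms.items()
                         if not any(v > 0 for v in vs))
        raise CalibrationError(
            f"no usable synDNA signal for {len(missing)} pool ids: {missing}"
        )
    sample_id = replicates[0].sample_id if len(replicates) == 1 else \
        "+".join(sc.sample_id for sc in replicates)
    return fit_calibration(points, min_points,
                           log_scale=log_scale, sample_id=sample_id)
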