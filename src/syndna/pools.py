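"""Spike-in pools and serial dilutions.

A pool mixes the panel's plasmids at concentrations taken from a serial
dilution series (e.g. 1 to 1e-4 ng/µL in 10-fold steps) and is added to a
biological sample at a small mass proportion (5% by default).  The
assigned concentrations are the known quantities that the calibration
regression later treats as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "DilutionSeries",
    "PoolSpec",
    "build_dilution_series",
    "assign_pool",
    "expected_mass_fraction",
    "spike",
    "pool_to_yaml",
    "pool_from_yaml",
]


@dataclass(frozen=True)
class DilutionSeries:
    """Descending geometric series of concentrations (ng/µL)."""

    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        lv = self.levels
        if len(lv) < 2:
            raise ValueError("a dilution series needs at least 2 levels")
        if any(x <= 0 for x in lv):
            raise ValueError("all concentrations must be positive")
        if any(b >= a for a, b in zip(lv, lv[1:])):
            raise ValueError("levels must be strictly decreasing")
        ratios = [a / b for a, b in zip(lv, lv[1:])]
        if any(not math.isclose(r, ratios[0], rel_tol=1e-9) for r in ratios):
            raise ValueError("consecutive levels must share a constant ratio")

    @property
    def factor(self) -> float:
        return self.levels[0] / self.levels[1]

    def __len__(self) -> int:
        return len(self.levels)


def build_dilution_series(top: float, factor: float, n_levels: int) -> DilutionSeries:
    """Serial dilution starting at ``top`` ng/µL: levels[i] = top / factor**i."""
    if top <= 0:
        raise ValueError("top concentration must be positive")
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    return DilutionSeries(tuple(top / factor**i for i in range(n_levels)))


@dataclass(frozen=True)
class PoolSpec:
    """One spike-in pool: synDNA ids mapped to assigned concentrations.

    ``plasmid_length`` is the full vector + insert length; ``insert_length``
    the synDNA insert alone.  Reads align to the insert only, so mass
    bookkeeping distinguishes plasmid mass from insert mass.
    ``spike_fraction`` is the pool's share of the total (sample + spike)
    DNA mass, 5% by default.
    """

    pool_id: str
    assignments: Mapping[str, float]
    plasmid_length: int = 4710
    insert_length: int = 2000
    spike_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("pool has no synDNA assignments")
        if any(c <= 0 for c in self.assignments.values()):
            raise ValueError("assigned concentrations must be positive")
        if not 0 < self.spike_fraction < 1:
            raise ValueError("spike_fraction must be in (0, 1)")
        if not 0 < self.insert_length <= self.plasmid_length:
            raise ValueError("insert_length must be in (0, plasmid_length]")
        object.__setattr__(self, "assignments", dict(self.assignments))

    @property
    def insert_mass_ratio(self) -> float:
        """Fraction of plasmid mass contributed by the insert."""
        return self.insert_length / self.plasmid_length


def assign_pool(
    ids: Sequence[str],
    series: DilutionSeries,
    explicit: Mapping[str, float] | None = None,
    *,
    pool_id: str = "pool1",
    **pool_kwargs,
) -> PoolSpec:
    """Assign each panel id a concentration from the dilution series.

    With ``explicit`` given, the map is validated and passed through.
    Otherwise the default rule spreads GC levels across dilution levels:
    ids are taken as consecutive groups (one group per GC level, panel
    order), and replicate ``r`` of group ``g`` is placed at dilution level
    ``(g + r * offset) mod n_levels`` with ``offset = n_levels // 2`` —
    every dilution level is used equally often and the members of a GC
    pair land at distant dilutions, so each dilution level mixes GC
    contents.
    """
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate id in panel id list")
    if explicit is not None:
        missing = set(ids) - set(explicit)
        extra = set(explicit) - set(ids)
        if missing:
            raise ValueError(f"ids without an assigned concentration: {sorted(missing)}")
        if extra:
            raise ValueError(f"assignments for unknown ids: {sorted(extra)}")
        return PoolSpec(pool_id, dict(explicit), **pool_kwargs)

    n = len(series)
    if len(ids) % n != 0:
        raise ValueError(
            f"{len(ids)} ids cannot be spread evenly over {n} dilution levels"
        )
    n_groups = n
    per_group = len(ids) // n
    offset = max(1, n // 2)
    assignments: dict[str, float] = {}
    for g in range(n_groups):
        for r in range(per_group):
            level = (g + r * offset) % n
            assignments[ids[g * per_group + r]] = series.levels[level]
    return PoolSpec(pool_id, assignments, **pool_kwargs)


def expected_mass_fraction(pool: PoolSpec) -> dict[str, float]:
    """Mass fraction of each synDNA within the pool (mixed at equal volumes)."""
    total = sum(pool.assignments.values())
    return {i: c / total for i, c in pool.assignments.items()}


def spike(
    pool: PoolSpec,
    sample_mass: float,
    *,
    convention: str = "of_total",
) -> pd.DataFrame:
    """Mass table for spiking a sample with the pool.

    ``of_total`` (default): the spike contributes ``spike_fraction`` of
    the combined sample + spike mass, i.e. spike mass =
    f/(1-f) × sample_mass.  ``of_sample``: spike mass = f × sample_mass.
    Returns one row per source (the sample, then each synDNA) with
    plasmid and insert-only masses in ng.
    """
    if sample_mass <= 0:
        raise ValueError("sample_mass must be positive")
    f = pool.spike_fraction
    if convention == "of_total":
        spike_total = f / (1.0 - f) * sample_mass
    elif convention == "of_sample":
        spike_total = f * sample_mass
    else:
        raise ValueError(f"unknown convention {convention!r}")

    fractions = expected_mass_fraction(pool)
    rows = [{"source": "sample", "kind": "sample",
             "plasmid_mass_ng": sample_mass, "insert_mass_ng": float("nan")}]
    for sid, frac in fractions.items():
        pm = spike_total * frac
        rows.append({
            "source": sid,
            "kind": "syndna",
            "plasmid_mass_ng": pm,
            "insert_mass_ng": pm * pool.insert_mass_ratio,
        })
    return pd.DataFrame(rows)


def pool_to_yaml(pool: PoolSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(pool), fh, sort_keys=False)


def pool_from_yaml(path) -> PoolSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PoolSpec(**data)
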