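"""Absolute abundance: from taxon read counts to cell numbers.

Given a sample's calibration model, a taxon's CPM is converted to a DNA
mass ("read weight") and then to a number of genome copies:

    cells_i = read_weight_i (g) × N_A / (Y_i × 650 g·mol⁻¹·bp⁻¹)

where Y_i is the taxon's genome length in bp, N_A Avogadro's number, and
650 the average molar mass of a base pair.  One genome copy per cell is
assumed unless a ploidy factor is supplied.  Downstream operations apply
the genome-coverage inclusion filter, aggregate species to genus, and
compare predicted with expected compositions (percent error, log ratios,
Pearson correlation) — alongside the read-based relative abundance
baseline the method is meant to improve on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .calibration import CalibrationModel, predict_mass
from .seqio import SampleCounts

__all__ = [
    "PhysicalConstants",
    "DEFAULT_CONSTANTS",
    "TaxonProfile",
    "ComparisonRow",
    "cells_from_mass",
    "quantify",
    "coverage_filter",
    "aggregate_genus",
    "relative_abundance",
    "compare",
]


@dataclass(frozen=True)
class PhysicalConstants:
    avogadro: float = 6.022e23       # molecules per mol
    bp_mass: float = 650.0           # g per mol per base pair


DEFAULT_CONSTANTS = PhysicalConstants()

NG_PER_G = 1e9


@dataclass
class TaxonProfile:
    """One taxon's path from read count to cell number."""

    taxon_id: str
    genome_length: float | None
    read_count: float
    normalized_reads: float          # X_i = count / total sequenced reads
    coverage_breadth: float | None = None
    read_weight: float | None = None  # ng, from the calibration model
    cells: float = 0.0
    percent: float = 0.0


@dataclass
class ComparisonRow:
    taxon_id: str
    expected_pct: float
    predicted_pct: float
    pct_error: float | None
    log_ratio: float | None
    flagged: bool = False


def cells_from_mass(
    read_weight: float,
    genome_length: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Genome copies in ``read_weight`` ng of a genome of given bp length.

    The ng→g conversion is explicit: cells = mass[g] × N_A / (Y × 650).
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if read_weight < 0:
        raise ValueError("read_weight cannot be negative")
    grams = read_weight / NG_PER_G
    return grams * constants.avogadro / (genome_length * constants.bp_mass)


def _recompute_percent(profiles: Sequence[TaxonProfile]) -> None:
    total = sum(p.cells for p in profiles)
    for p in profiles:
        p.percent = 100.0 * p.cells / total if total > 0 else 0.0


def quantify(
    counts: SampleCounts,
    model: CalibrationModel,
    genome_lengths: Mapping[str, float],
    *,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    coverage: Mapping[str, float] | None = None,
    ploidy: Mapping[str, float] | None = None,
    spike_ids: Iterable[str] | None = None,
) -> list[TaxonProfile]:
    """Estimate cell numbers for every taxon with a known genome length.

    X_i is the taxon's aligned reads over total sequenced reads; the
    calibration model maps the corresponding CPM (X_i × 1e6) to a DNA
    mass, which Avogadro arithmetic turns into genome copies.  Taxa with
    zero counts get zero cells; taxa present in ``counts`` but without a
    genome length are excluded with a warning.  Percentages are computed
    over the returned set (re-derived by any later filter).
    """
    if counts.total_reads <= 0:
        raise ValueError("total_reads must be positive")
    known_spikes = set(spike_ids) if spike_ids else set()
    lengthless = [t for t in counts.counts
                  if t not in genome_lengths and t not in known_spikes
                  and counts.counts[t] > 0]
    if lengthless:
        warnings.warn(
            f"excluding {len(lengthless)} taxa without genome length: "
            f"{sorted(lengthless)[:5]}..."
        )
    profiles: list[TaxonProfile] = []
    for taxon, length in genome_lengths.items():
        count = counts.counts.get(taxon, 0)
        x_i = count / counts.total_reads
        profile = TaxonProfile(
            taxon_id=taxon,
            genome_length=length,
            read_count=count,
            normalized_reads=x_i,
            coverage_breadth=None if coverage is None else coverage.get(taxon),
        )
        weight = predict_mass(model, x_i * 1e6 if model.x_scale == "cpm" else x_i)
        if weight is not None:
            factor = ploidy.get(taxon, 1.0) if ploidy else 1.0
            profile.read_weight = weight
            profile.cells = cells_from_mass(weight, length, constants) / factor
        profiles.append(profile)
    _recompute_percent(profiles)
    return profiles


def coverage_filter(
    profiles: Sequence[TaxonProfile], min_breadth: float = 0.01
) -> list[TaxonProfile]:
    """Keep taxa whose genome coverage breadth strictly exceeds the cutoff.

    Sparse, barely-covered taxa are often artifacts; the default keeps
    taxa with more than 1% of genome positions covered.  Profiles without
    a breadth value are kept with a warning (the filter cannot judge
    them).  Percentages are recomputed over the survivors.
    """
    survivors = []
    n_unknown = 0
    for p in profiles:
        if p.coverage_breadth is None:
            n_unknown += 1
            survivors.append(replace(p))
        elif p.coverage_breadth > min_breadth:
            survivors.append(replace(p))
    if n_unknown:
        warnings.warn(
            f"{n_unknown} profile(s) lack coverage breadth; kept unfiltered"
        )
    _recompute_percent(survivors)
    return survivors


def aggregate_genus(
    profiles: Sequence[TaxonProfile],
    taxonomy: Mapping[str, str],
) -> list[TaxonProfile]:
    """Sum species-level cell numbers into genus-level profiles.

    Every species must be mapped to a genus.  Total cells are conserved;
    percentages are recomputed at the genus level.
    """
    unmapped = [p.taxon_id for p in profiles if p.taxon_id not in taxonomy]
    if unmapped:
        raise KeyError(f"species without a genus mapping: {sorted(unmapped)}")
    by_genus: dict[str, TaxonProfile] = {}
    for p in profiles:
        genus = taxonomy[p.taxon_id]
        agg = by_genus.get(genus)
        if agg is None:
            by_genus[genus] = TaxonProfile(
                taxon_id=genus, genome_length=None,
                read_count=p.read_count, normalized_reads=p.normalized_reads,
                read_weight=p.read_weight, cells=p.cells,
            )
        else:
            agg.read_count += p.read_count
            agg.normalized_reads += p.normalized_reads
            if p.read_weight is not None:
                agg.read_weight = (agg.read_weight or 0.0) + p.read_weight
            agg.cells += p.cells
    result = list(by_genus.values())
    _recompute_percent(result)
    return result


def relative_abundance(
    counts: SampleCounts,
    taxa: Sequence[str],
    *,
    denominator: str = "taxa",
) -> dict[str, float]:
    """Read-based relative abundance in percent — the baseline method.

    ``denominator="taxa"`` (default) normalizes by the summed counts of
    the requested taxa, so the percentages sum to 100 over that set;
    ``"total"`` normalizes by total sequenced reads instead.
    """
    if denominator == "taxa":
        total = sum(counts.counts.get(t, 0) for t in taxa)
    elif denominator == "total":
        total = counts.total_reads
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if total <= 0:
        raise ValueError("no reads to normalize by")
    return {t: 100.0 * counts.counts.get(t, 0) / total for t in taxa}


def compare(
    predicted_pct: Mapping[str, float],
    expected_pct: Mapping[str, float],
    *,
    error_denominator: str = "expected",
) -> tuple[list[ComparisonRow], dict]:
    """Compare a predicted composition with the expected one.

    Per taxon: percent error 100 × |pred − exp| / exp (denominator
    switchable to the prediction) and log10(pred/exp).  Summary: Pearson
    correlation across taxa (two-sided p), min/max percent error.  Taxa
    with expected 0 are flagged and excluded from the correlation; a
    constant vector makes the correlation undefined, reported as None.
    """
    if set(predicted_pct) != set(expected_pct):
        raise ValueError("predicted and expected taxon sets differ")
    if error_denominator not in ("expected", "predicted"):
        raise ValueError(f"unknown error_denominator {error_denominator!r}")

    rows: list[ComparisonRow] = []
    for taxon in expected_pct:
        exp, pred = expected_pct[taxon], predicted_pct[taxon]
        flagged = exp <= 0 or pred <= 0
        if exp <= 0:
            err = None
        else:
            denom = exp if error_denominator == "expected" else pred
            err = 100.0 * abs(pred - exp) / denom if denom > 0 else None
        log_ratio = math.log10(pred / exp) if not flagged else None
        rows.append(ComparisonRow(taxon, exp, pred, err, log_ratio, flagged))

    ok = [r for r in rows if not r.flagged]
    exp_v = np.array([r.expected_pct for r in ok])
    pred_v = np.array([r.predicted_pct for r in ok])
    r_val = p_val = None
    if len(ok) >= 3 and np.ptp(exp_v) > 0 and np.ptp(pred_v) > 0:
        res = stats.pearsonr(exp_v, pred_v)
        r_val, p_val = float(res.statistic), float(res.pvalue)
    errors = [r.pct_error for r in rows if r.pct_error is not None]
    summary = {
        "pearson_r": r_val,
        "p_value": p_val,
        "n": len(ok),
        "min_error_pct": min(errors) if errors else None,
        "max_error_pct": max(errors) if errors else None,
    }
    return rows, summary
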