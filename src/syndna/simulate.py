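"""Synthetic sequencing evidence with known ground truth.

Emulates shotgun sequencing of a spiked sample at the count level: read
counts are drawn (multinomially by default) with probabilities
proportional to each source's DNA mass, optionally distorted by a smooth
GC-dependent amplification weight.  A quadratic GC-dependent base-call
error model supports an optional FASTQ read mode.  Every simulation
returns a truth sidecar so calibration and quantification can be checked
end to end without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .abundance import DEFAULT_CONSTANTS, PhysicalConstants, compare, quantify, relative_abundance
from .calibration import fit_all
from .pools import PoolSpec
from .seqio import SampleCounts

__all__ = [
    "TaxonSpec",
    "CommunitySpec",
    "mock_community_8",
    "ErrorModel",
    "SimulationConfig",
    "gc_weight",
    "simulate_pool_counts",
    "simulate_community",
    "mutate_reads",
    "end_to_end_check",
    "write_truth",
]


@dataclass(frozen=True)
class TaxonSpec:
    genome_length: int      # bp
    cells: float            # genome copies in the sample
    gc: float               # genomic GC fraction

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.cells < 0:
            raise ValueError("cells cannot be negative")
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must be in [0, 1]")


@dataclass(frozen=True)
class CommunitySpec:
    """A defined community: taxon → (genome length, cells, GC)."""

    taxa: Mapping[str, TaxonSpec]

    def mass_ng(self, constants: PhysicalConstants = DEFAULT_CONSTANTS) -> dict[str, float]:
        """DNA mass per taxon in ng: cells × Y × 650 / N_A, ng-scaled."""
        return {
            t: spec.cells * spec.genome_length * constants.bp_mass
               / constants.avogadro * 1e9
            for t, spec in self.taxa.items()
        }


# ZymoBIOMICS-style 8-species mock community: genome length (bp), expected
# percent of total cells, genomic GC fraction.
_MOCK8 = {
    "Bacillus_subtilis":        (4_045_000, 10.3, 0.439),
    "Enterococcus_faecalis":    (2_845_000, 14.6, 0.375),
    "Escherichia_coli":         (4_875_000,  8.5, 0.467),
    "Lactobacillus_fermentum":  (1_905_000, 21.6, 0.524),
    "Listeria_monocytogenes":   (2_992_000, 13.9, 0.380),
    "Pseudomonas_aeruginosa":   (6_792_000,  6.1, 0.662),
    "Salmonella_enterica":      (4_760_000,  8.7, 0.522),
    "Staphylococcus_aureus":    (2_730_000, 15.2, 0.329),
}


def mock_community_8(total_cells: float = 1e8) -> CommunitySpec:
    """Standard 8-species mock community with a known cell composition.

    Mirrors the commercial ZymoBIOMICS DNA mock: cells are split in the
    manufacturer-reported proportions over eight bacteria spanning 33–66%
    genomic GC, the usual ground truth for validating absolute
    quantification.
    """
    total_pct = sum(v[1] for v in _MOCK8.values())
    return CommunitySpec({
        name: TaxonSpec(length, total_cells * pct / total_pct, gc)
        for name, (length, pct, gc) in _MOCK8.items()
    })


@dataclass(frozen=True)
class ErrorModel:
    """Quadratic map from GC percent to per-base error percent.

    rate(g) = clip(a·g² + b·g + c, floor, 100).  The default coefficients
    are synthetic, shaped so error is highest for GC-poor sequence and
    lowest near 55% GC — the qualitative pattern of short-read
    platforms.
    """

    a: float = 0.002
    b: float = -0.22
    c: float = 6.8
    floor: float = 0.0

    def rate(self, gc_percent: float) -> float:
        raw = self.a * gc_percent**2 + self.b * gc_percent + self.c
        return float(np.clip(raw, self.floor, 100.0))


@dataclass(frozen=True)
class SimulationConfig:
    depth: int = 500_000
    read_length: int = 150
    gc_bias_strength: float = 0.0
    seed: int | None = None
    noise: str = "multinomial"       # none | multinomial | lognormal
    overdispersion_sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth cannot be negative")
        if self.noise not in ("none", "multinomial", "lognormal"):
            raise ValueError(f"unknown noise mode {self.noise!r}")


def gc_weight(gc: float, strength: float) -> float:
    """Smooth unimodal amplification weight, peaking at 50% GC.

    w(gc) = 1 + s·(1 − 2·(2(gc − 0.5))²) spans [1 − s, 1 + s]; s = 0.2
    reproduces a ±20% amplification bias across the GC range.
    """
    return 1.0 + strength * (1.0 - 2.0 * (2.0 * (gc - 0.5)) ** 2)


def _draw_counts(
    ids: list[str], probs: np.ndarray, config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    if config.noise == "none":
        values = config.depth * probs
    elif config.noise == "multinomial":
        values = rng.multinomial(config.depth, probs).astype(float)
    else:  # lognormal-overdispersed mass noise, then multinomial sampling
        noisy = probs * rng.lognormal(0.0, config.overdispersion_sigma, len(probs))
        noisy /= noisy.sum()
        values = rng.multinomial(config.depth, noisy).astype(float)
    return dict(zip(ids, values))


def simulate_pool_counts(
    pool: PoolSpec,
    config: SimulationConfig,
    gc_content: Mapping[str, float] | None = None,
    *,
    mass_basis: str = "insert",
    sample_id: str = "sim_pool",
) -> tuple[SampleCounts, dict[str, float]]:
    """Simulate sequencing of a spike-in pool alone.

    Sampling probabilities are proportional to each synDNA's mass
    (insert-only by default — reads align to the insert, not the vector)
    times its GC amplification weight.  Returns the counts and a truth
    sidecar mapping id → assigned mass (the calibration ground truth).
    """
    if mass_basis not in ("insert", "plasmid"):
        raise ValueError(f"unknown mass_basis {mass_basis!r}")
    ids = list(pool.assignments)
    scale = pool.insert_mass_ratio if mass_basis == "insert" else 1.0
    masses = np.array([pool.assignments[i] * scale for i in ids])
    weights = np.array([
        gc_weight(gc_content.get(i, 0.5) if gc_content else 0.5,
                  config.gc_bias_strength)
        for i in ids
    ])
    probs = masses * weights
    total = probs.sum()
    if total <= 0:
        raise ValueError("zero total sampling probability")
    probs = probs / total
    rng = np.random.default_rng(config.seed)
    counts = _draw_counts(ids, probs, config, rng)
    sc = SampleCounts(sample_id=sample_id, counts=counts,
                      total_reads=config.depth)
    truth = {i: pool.assignments[i] for i in ids}
    return sc, truth


def simulate_community(
    community: CommunitySpec,
    pool: PoolSpec,
    config: SimulationConfig,
    gc_content: Mapping[str, float] | None = None,
    *,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    sample_id: str = "sim_sample",
) -> tuple[SampleCounts, pd.DataFrame]:
    """Simulate sequencing of a community spiked with a synDNA pool.

    Taxon masses follow cells × genome length; the pool's total plasmid
    mass is scaled to the configured spike fraction of the combined DNA
    mass, distributed over synDNAs in proportion to their assigned
    concentrations.  Reads are drawn over taxa and synDNA inserts with
    probabilities proportional to mass × GC weight.  The truth sidecar
    lists each source's kind, actual mass (ng), cells, and the ng per
    assigned-concentration-unit scale factor linking pool assignments to
    physical mass.
    """
    taxa_mass = community.mass_ng(constants)
    sample_mass = sum(taxa_mass.values())
    if sample_mass <= 0:
        raise ValueError("community has zero DNA mass")
    f = pool.spike_fraction
    spike_plasmid_total = f / (1.0 - f) * sample_mass
    conc_total = sum(pool.assignments.values())
    mass_scale = spike_plasmid_total / conc_total   # ng per concentration unit

    ids, masses, gcs = [], [], []
    for taxon, spec in community.taxa.items():
        ids.append(taxon)
        masses.append(taxa_mass[taxon])
        gcs.append(spec.gc)
    for sid, conc in pool.assignments.items():
        ids.append(sid)
        masses.append(conc * mass_scale * pool.insert_mass_ratio)
        gcs.append(gc_content.get(sid, 0.5) if gc_content else 0.5)

    masses_arr = np.array(masses)
    weights = np.array([gc_weight(g, config.gc_bias_strength) for g in gcs])
    probs = masses_arr * weights
    probs = probs / probs.sum()
    rng = np.random.default_rng(config.seed)
    counts = _draw_counts(ids, probs, config, rng)
    sc = SampleCounts(sample_id=sample_id, counts=counts,
                      total_reads=config.depth)

    truth = pd.DataFrame({
        "id": ids,
        "kind": ["taxon"] * len(community.taxa) + ["syndna"] * len(pool.assignments),
        "mass_ng": masses,
        "cells": [community.taxa[t].cells for t in community.taxa]
                 + [float("nan")] * len(pool.assignments),
    })
    truth.attrs["mass_scale_ng_per_unit"] = mass_scale
    return sc, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def mutate_reads(
    windows: list[tuple[str, str]],
    error_model: ErrorModel,
    seed: int | None = None,
) -> list[SeqRecord]:
    """Apply GC-dependent substitution errors to sequence windows.

    Each (id, sequence) window becomes one FASTQ-ready record: every base
    is substituted (uniformly to one of the other three) with probability
    rate(GC%)/100, where GC% is the window's own GC content; Phred
    qualities are set from the same rate.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    records = []
    for rid, seq in windows:
        seq = seq.upper()
        n = len(seq)
        gc_pct = 100.0 * sum(b in "GC" for b in seq) / n if n else 0.0
        p = error_model.rate(gc_pct) / 100.0
        arr = np.array(list(seq))
        hit = rng.random(n) < p
        if hit.any():
            for i in np.flatnonzero(hit):
                choices = alphabet[alphabet != arr[i]]
                arr[i] = rng.choice(choices)
        qual = int(round(-10 * np.log10(max(p, 1e-4)))) if p > 0 else 40
        rec = SeqRecord(Seq("".join(arr)), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [min(qual, 40)] * n
        records.append(rec)
    return records


def end_to_end_check(
    community: CommunitySpec,
    pool: PoolSpec,
    config: SimulationConfig,
    gc_content: Mapping[str, float] | None = None,
    *,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> dict:
    """Simulate, calibrate, quantify, and compare against the truth.

    Runs the full pipeline on one simulated spiked sample and returns the
    fitted calibration model, per-taxon comparison rows (predicted vs
    true percent composition), the comparison summary, and the
    relative-abundance baseline.
    """
    sc, truth = simulate_community(community, pool, config, gc_content,
                                   constants=constants)
    model = fit_all(sc, pool)
    genome_lengths = {t: s.genome_length for t, s in community.taxa.items()}
    profiles = quantify(sc, model, genome_lengths, constants=constants,
                        spike_ids=pool.assignments)
    predicted = {p.taxon_id: p.percent for p in profiles}

    total_cells = sum(s.cells for s in community.taxa.values())
    truth_pct = {t: 100.0 * s.cells / total_cells
                 for t, s in community.taxa.items()}
    rows, summary = compare(predicted, truth_pct)
    baseline = relative_abundance(sc, list(community.taxa))
    return {
        "counts": sc,
        "model": model,
        "profiles": profiles,
        "predicted_pct": predicted,
        "truth_pct": truth_pct,
        "rows": rows,
        "summary": summary,
        "relative_abundance_pct": baseline,
    }
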