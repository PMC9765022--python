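"""I/O for the formats the pipeline touches, and per-feature statistics.

Covers reading SAM alignments into per-reference counts (with NM-tag
mismatch tallies for base-call error rates), feature-by-sample count
tables (TSV, as produced by taxonomic classifiers), panel FASTA files,
and the derived per-feature quantities: counts per million (CPM) and
percent base-call error.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import SynDNARecord

__all__ = [
    "SampleCounts",
    "parse_sam_counts",
    "coverage_breadth",
    "error_rate",
    "cpm",
    "read_count_table",
    "write_count_table",
    "combine_orientations",
    "write_panel_fasta",
    "read_panel_fasta",
    "write_design_sidecar",
]

logger = logging.getLogger(__name__)


@dataclass
class SampleCounts:
    """Aligned read counts and mismatch tallies for one library.

    ``total_reads`` is the number of sequenced reads (aligned or not),
    the denominator of both CPM and the normalized read fraction X_i.
    ``orientation`` records whether the library holds forward reads,
    reverse reads, or their combination.
    """

    sample_id: str
    counts: dict[str, float] = field(default_factory=dict)
    total_reads: float = 0
    aligned_bases: dict[str, int] = field(default_factory=dict)
    mismatches: dict[str, int] = field(default_factory=dict)
    orientation: str = "combined"
    missing_nm: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative read count")
        if self.counts and self.total_reads < max(self.counts.values()):
            raise ValueError("total_reads below a per-feature count")
        for fid, mm in self.mismatches.items():
            if mm > self.aligned_bases.get(fid, 0):
                raise ValueError(f"mismatches exceed aligned bases for {fid}")

    @property
    def features(self) -> set[str]:
        return set(self.counts)


def parse_sam_counts(
    path,
    references: Iterable[str] | None = None,
    *,
    sample_id: str | None = None,
    orientation: str = "combined",
) -> SampleCounts:
    """Tally per-reference primary-alignment counts from a SAM file.

    Each primary record contributes one count to its reference; unmapped
    records count toward ``total_reads`` only; secondary and supplementary
    records are ignored.  Per-reference NM-tag mismatch totals and aligned
    base totals are accumulated for base-call error estimation; mapped
    records lacking an NM tag keep their count but are excluded from the
    mismatch tallies (``missing_nm`` reports how many).
    """
    refs = set(references) if references is not None else None
    counts: dict[str, float] = {}
    bases: dict[str, int] = {}
    mm: dict[str, int] = {}
    total = 0
    missing_nm = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_secondary or read.is_supplementary:
                continue
            total += 1
            if read.is_unmapped:
                continue
            ref = read.reference_name
            if refs is not None and ref not in refs:
                continue
            counts[ref] = counts.get(ref, 0) + 1
            try:
                nm = read.get_tag("NM")
            except KeyError:
                missing_nm += 1
                continue
            alen = read.query_alignment_length
            bases[ref] = bases.get(ref, 0) + alen
            mm[ref] = mm.get(ref, 0) + int(nm)
    if missing_nm:
        logger.warning("%d mapped records lacked an NM tag", missing_nm)
    return SampleCounts(
        sample_id=sample_id or str(path),
        counts=counts, total_reads=total,
        aligned_bases=bases, mismatches=mm,
        orientation=orientation, missing_nm=missing_nm,
    )


def coverage_breadth(path, references: Iterable[str] | None = None) -> dict[str, float]:
    """Fraction of each reference's positions covered by >= 1 primary read.

    Uses the aligned blocks of each primary record (0-based half-open);
    reference lengths come from the SAM header.
    """
    refs = set(references) if references is not None else None
    covered: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), "r") as sam:
        for name, length in zip(sam.references, sam.lengths):
            if refs is None or name in refs:
                lengths[name] = length
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            ref = read.reference_name
            if ref not in lengths:
                continue
            mask = covered.setdefault(ref, np.zeros(lengths[ref], dtype=bool))
            for start, end in read.get_blocks():
                mask[start:end] = True
    return {
        ref: float(covered[ref].mean()) if ref in covered else 0.0
        for ref in lengths
    }


def error_rate(counts: SampleCounts, feature_id: str) -> float | None:
    """Percent base-call error for a feature: 100 × mismatches / aligned bases.

    Returns None (missing, not zero) when no aligned bases were tallied.
    """
    aligned = counts.aligned_bases.get(feature_id, 0)
    if aligned <= 0:
        return None
    return 100.0 * counts.mismatches.get(feature_id, 0) / aligned


def cpm(counts: SampleCounts, feature_id: str) -> float:
    """Counts per million sequenced reads for one feature."""
    if counts.total_reads <= 0:
        raise ValueError("total_reads must be positive to compute CPM")
    return 1e6 * counts.counts.get(feature_id, 0) / counts.total_reads


def read_count_table(
    path,
    totals: Mapping[str, float] | str | None = None,
) -> list[SampleCounts]:
    """Read a feature × sample TSV count table into per-sample counts.

    The first column holds feature ids; remaining columns are samples with
    integer counts; ``#`` lines are comments.  ``totals`` supplies
    per-sample sequenced-read totals, either as a mapping or as the path
    of a two-column TSV (sample_id, total_reads); without it, totals fall
    back to column sums (aligned reads only) with a warning.
    """
    # '#' marks comments except on the header line ("#FeatureID ..." style)
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    kept = [ln for i, ln in enumerate(lines) if i == 0 or not ln.startswith("#")]
    df = pd.read_csv(io.StringIO("\n".join(kept)), sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated feature ids: {dupes}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="raise")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError(f"non-integer count in sample column {col!r}")
    df = df.astype(np.int64)

    if isinstance(totals, (str, bytes)) or hasattr(totals, "__fspath__"):
        tot_df = pd.read_csv(totals, sep="\t", comment="#")
        totals = dict(zip(tot_df.iloc[:, 0].astype(str), tot_df.iloc[:, 1]))
    if totals is None:
        warnings.warn("no total-read metadata: totals default to column sums")

    samples = []
    for col in df.columns:
        total = int(totals[col]) if totals is not None else int(df[col].sum())
        samples.append(SampleCounts(
            sample_id=str(col),
            counts={str(f): int(c) for f, c in df[col].items()},
            total_reads=total,
        ))
    return samples


def write_count_table(samples: list[SampleCounts], path, totals_path=None) -> None:
    """Write per-sample counts as a feature × sample TSV (and totals sidecar)."""
    features = sorted(set().union(*(s.features for s in samples)))
    df = pd.DataFrame(
        {s.sample_id: [int(s.counts.get(f, 0)) for f in features] for s in samples},
        index=pd.Index(features, name="#FeatureID"),
    )
    df.to_csv(path, sep="\t")
    if totals_path is not None:
        pd.DataFrame({
            "sample_id": [s.sample_id for s in samples],
            "total_reads": [int(s.total_reads) for s in samples],
        }).to_csv(totals_path, sep="\t", index=False)


def combine_orientations(forward: SampleCounts, reverse: SampleCounts) -> SampleCounts:
    """Element-wise sum of forward- and reverse-read counts for one sample.

    Used when no orientation-specific bias is observed, so a single
    calibration model can be fitted per sample.
    """
    if forward.features != reverse.features:
        raise ValueError("orientations cover different feature sets")
    keys = forward.features
    return SampleCounts(
        sample_id=forward.sample_id,
        counts={k: forward.counts[k] + reverse.counts[k] for k in keys},
        total_reads=forward.total_reads + reverse.total_reads,
        aligned_bases={
            k: forward.aligned_bases.get(k, 0) + reverse.aligned_bases.get(k, 0)
            for k in keys},
        mismatches={
            k: forward.mismatches.get(k, 0) + reverse.mismatches.get(k, 0)
            for k in keys},
        orientation="combined",
        missing_nm=forward.missing_nm + reverse.missing_nm,
    )


def write_panel_fasta(records: list[SynDNARecord], path) -> None:
    """Write a designed panel as multi-FASTA; metadata in the description."""
    seq_records = []
    for rec in records:
        desc = (f"target_gc={rec.target_gc:g} realized_gc={rec.realized_gc:.6g} "
                f"flank5={rec.flank5 or '-'} flank3={rec.flank3 or '-'}")
        seq_records.append(SeqRecord(Seq(rec.sequence), id=rec.id, description=desc))
    SeqIO.write(seq_records, str(path), "fasta")


def read_panel_fasta(path) -> list[SynDNARecord]:
    """Read a panel multi-FASTA written by :func:`write_panel_fasta`."""
    records = []
    for sr in SeqIO.parse(str(path), "fasta"):
        meta = dict(
            item.split("=", 1) for item in sr.description.split()[1:]
            if "=" in item
        )
        flank5 = meta.get("flank5", "-")
        flank3 = meta.get("flank3", "-")
        records.append(SynDNARecord(
            id=sr.id,
            sequence=str(sr.seq),
            target_gc=float(meta.get("target_gc", "nan")),
            realized_gc=float(meta.get("realized_gc", "nan")),
            flank5="" if flank5 == "-" else flank5,
            flank3="" if flank3 == "-" else flank3,
        ))
    return records


def write_design_sidecar(params: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True)
        fh.write("\n")
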