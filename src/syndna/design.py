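"""Design of synthetic spike-in DNA (synDNA) sequences.

A synDNA is a random DNA sequence with a user-controlled length and GC
content, no meaningful similarity to natural genomes, and no long
self-complementary (hairpin-prone) regions.  Panels of such sequences,
spanning a range of GC contents, serve as internal standards for shotgun
metagenomic sequencing: because their input amounts are known, the observed
read counts calibrate the relation between DNA mass and sequencing signal.

The default panel covers GC contents of 26/36/46/56/66% with two sequences
per level (ids ``p126``, ``p226``, ``p136``, ... — replicate digit followed
by the GC percentage), each 2,000 bp long.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "SynDNARecord",
    "ComplementarityHit",
    "NoveltyReport",
    "KmerIndex",
    "DesignError",
    "reverse_complement",
    "generate_sequence",
    "screen_self_complementarity",
    "add_flanks",
    "novelty_screen",
    "design_panel",
    "DEFAULT_GC_LEVELS",
]

DEFAULT_GC_LEVELS = (0.26, 0.36, 0.46, 0.56, 0.66)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


class DesignError(RuntimeError):
    """A sequence satisfying all screens could not be produced."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _check_dna(sequence: str, *, what: str = "sequence") -> None:
    bad = set(sequence) - _VALID
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")


@dataclass(frozen=True)
class SynDNARecord:
    """One designed spike-in sequence.

    ``sequence`` is the full oligo (flanks included); ``length``,
    ``target_gc`` and ``realized_gc`` refer to the random core only, the
    part that is aligned against during analysis.
    """

    id: str
    sequence: str
    target_gc: float
    realized_gc: float
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        _check_dna(self.sequence)

    @property
    def core(self) -> str:
        end = len(self.sequence) - len(self.flank3)
        return self.sequence[len(self.flank5):end]

    @property
    def length(self) -> int:
        """Core length in bp (flanks excluded)."""
        return len(self.core)


def generate_sequence(
    length: int,
    target_gc: float,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    mode: str = "exact",
    gc_tolerance: float = 0.005,
    max_tries: int = 100,
    record_id: str = "synDNA",
) -> SynDNARecord:
    """Generate one random unflanked synDNA core.

    In ``exact`` mode (default) the number of G+C bases is fixed at
    ``round(length * target_gc)`` and base identities within the GC and AT
    classes are drawn uniformly, so the realized GC content is
    deterministic.  In ``stochastic`` mode every base is drawn
    independently (G/C with probability ``target_gc``) and the draw is
    repeated until the realized GC lies within ``gc_tolerance`` of the
    target.

    Parameters
    ----------
    length : int
        Core length in bp; must be positive.
    target_gc : float
        Desired GC fraction in [0, 1].
    seed : int, optional
        Seed for a fresh generator; ignored if ``rng`` is given.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    if not 0.0 <= target_gc <= 1.0:
        raise ValueError(f"target_gc must be in [0, 1], got {target_gc}")
    if mode not in ("exact", "stochastic"):
        raise ValueError(f"unknown composition mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(seed)

    if mode == "exact":
        n_gc = int(round(length * target_gc))
        bases = np.concatenate([
            rng.choice(np.array(["G", "C"]), size=n_gc),
            rng.choice(np.array(["A", "T"]), size=length - n_gc),
        ])
        rng.shuffle(bases)
        seq = "".join(bases)
        realized = n_gc / length
    else:
        for _ in range(max_tries):
            is_gc = rng.random(length) < target_gc
            gc_pick = rng.choice(np.array(["G", "C"]), size=length)
            at_pick = rng.choice(np.array(["A", "T"]), size=length)
            bases = np.where(is_gc, gc_pick, at_pick)
            realized = float(np.mean(is_gc))
            if abs(realized - target_gc) <= gc_tolerance:
                seq = "".join(bases)
                break
        else:
            raise DesignError(
                f"stochastic draw did not reach |GC - {target_gc}| <= "
                f"{gc_tolerance} within {max_tries} tries"
            )

    return SynDNARecord(id=record_id, sequence=seq,
                        target_gc=target_gc, realized_gc=realized)


@dataclass(frozen=True, order=True)
class ComplementarityHit:
    """A maximal intramolecular reverse-complement match.

    ``sequence[start_a:start_a+length]`` equals the reverse complement of
    ``sequence[start_b:start_b+length]`` and cannot be extended on either
    side.  ``start_a <= start_b``.
    """

    start_a: int
    start_b: int
    length: int

    def seed_pairs(self, window: int) -> set[tuple[int, int]]:
        """All contained matching substring pairs of width ``window``."""
        pairs = set()
        for a in range(self.length - window + 1):
            i = self.start_a + a
            j = self.start_b + self.length - window - a
            pairs.add((min(i, j), max(i, j)))
        return pairs


def screen_self_complementarity(
    sequence: str, max_len: int = 15
) -> list[ComplementarityHit]:
    """Find self-complementary regions longer than ``max_len`` bp.

    Two substrings of the same sequence that are reverse complements of
    each other can fold back into a hairpin; designed spike-ins exclude
    any such match exceeding ``max_len`` (default 15 bp).  Returns every
    maximal offending pair; an empty list means the sequence passes.
    """
    _check_dna(sequence)
    n = len(sequence)
    w = max_len + 1
    if n < w:
        return []

    index: dict[str, list[int]] = {}
    for i in range(n - w + 1):
        index.setdefault(sequence[i:i + w], []).append(i)

    comp = dict(zip("ACGT", "TGCA"))
    hits: set[ComplementarityHit] = set()
    for i in range(n - w + 1):
        rc = reverse_complement(sequence[i:i + w])
        for j in index.get(rc, ()):
            # extend the seed pair (i, j, w) to its maximal match
            a, b, length = i, j, w
            while a > 0 and b + length < n and \
                    sequence[a - 1] == comp[sequence[b + length]]:
                a -= 1
                length += 1
            while a + length < n and b > 0 and \
                    sequence[a + length] == comp[sequence[b - 1]]:
                b -= 1
                length += 1
            hits.add(ComplementarityHit(min(a, b), max(a, b), length))
    return sorted(hits)


def add_flanks(record: SynDNARecord, site5: str, site3: str) -> SynDNARecord:
    """Attach restriction-site flanks to a designed core.

    The sites must not occur inside the core (a second cut site would
    break cloning); offending cores raise :class:`DesignError` so the
    caller can regenerate.
    """
    _check_dna(site5, what="site5")
    _check_dna(site3, what="site3")
    core = record.core
    for site in (site5, site3):
        if site and site in core:
            raise DesignError(
                f"restriction site {site} occurs inside the core of {record.id}"
            )
    return replace(record, sequence=site5 + core + site3,
                   flank5=site5, flank3=site3)


class KmerIndex:
    """Exact k-mer set over reference sequences, for novelty screening."""

    def __init__(self, k: int = 31):
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self._kmers: set[str] = set()

    def __len__(self) -> int:
        return len(self._kmers)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self._kmers

    def add_sequence(self, sequence: str) -> None:
        seq = sequence.upper()
        k = self.k
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if set(kmer) <= _VALID:
                self._kmers.add(kmer)
                self._kmers.add(reverse_complement(kmer))

    @classmethod
    def from_sequences(cls, sequences: Iterable[str], k: int = 31) -> "KmerIndex":
        idx = cls(k)
        for s in sequences:
            idx.add_sequence(s)
        return idx

    @classmethod
    def from_fasta(cls, paths: Iterable[str], k: int = 31) -> "KmerIndex":
        idx = cls(k)
        for path in paths:
            for rec in SeqIO.parse(str(path), "fasta"):
                idx.add_sequence(str(rec.seq))
        return idx


@dataclass(frozen=True)
class NoveltyReport:
    shared_kmers: int
    longest_match_bp: int
    passed: bool
    skipped: bool = False


def novelty_screen(
    record: SynDNARecord,
    reference_index: KmerIndex | None,
    *,
    max_match_bp: int | None = None,
) -> NoveltyReport:
    """Screen a designed sequence for exact matches to reference k-mers.

    A local surrogate for a database homology search: counts k-mers of the
    core shared with the reference index and the longest run of
    consecutive shared k-mers (an exact match of ``run + k - 1`` bp).  By
    default any shared k-mer fails the screen (``max_match_bp = k - 1``);
    for unrelated random sequence the chance of a shared 31-mer is
    negligible (~4^-31 per pair).
    """
    if reference_index is None or len(reference_index) == 0:
        warnings.warn("empty reference index: novelty screen skipped")
        return NoveltyReport(0, 0, passed=True, skipped=True)

    k = reference_index.k
    if max_match_bp is None:
        max_match_bp = k - 1
    core = record.core
    shared = 0
    longest_run = run = 0
    for i in range(len(core) - k + 1):
        if core[i:i + k] in reference_index:
            shared += 1
            run += 1
            longest_run = max(longest_run, run)
        else:
            run = 0
    longest_bp = longest_run + k - 1 if longest_run else 0
    return NoveltyReport(shared, longest_bp, passed=longest_bp <= max_match_bp)


def _panel_id(replicate: int, gc: float) -> str:
    return f"p{replicate}{int(round(gc * 100))}"


def design_panel(
    gc_levels: Sequence[float] = DEFAULT_GC_LEVELS,
    n_per_level: int = 2,
    length: int = 2000,
    *,
    seed: int | None = None,
    gc_tolerance: float = 0.005,
    max_self_comp: int = 15,
    flank5: str = "",
    flank3: str = "",
    reference_index: KmerIndex | None = None,
    retry_budget: int = 100,
    mode: str = "exact",
) -> list[SynDNARecord]:
    """Design a full spike-in panel: ``n_per_level`` sequences per GC level.

    Every emitted record passes the self-complementarity screen, carries
    no internal copy of the flank sites, and (when a reference index is
    supplied) passes the novelty screen.  Identical parameters and seed
    give a byte-identical panel; each sequence draws from its own spawned
    RNG stream, so the panel is reproducible regardless of retry counts
    elsewhere.
    """
    streams = np.random.SeedSequence(seed).spawn(len(gc_levels) * n_per_level)
    panel: list[SynDNARecord] = []
    idx = 0
    for gc in gc_levels:
        for rep in range(1, n_per_level + 1):
            rng = np.random.default_rng(streams[idx])
            idx += 1
            rec_id = _panel_id(rep, gc)
            last_failure = "no attempt made"
            for _ in range(retry_budget):
                rec = generate_sequence(
                    length, gc, rng=rng, mode=mode,
                    gc_tolerance=gc_tolerance, record_id=rec_id,
                )
                if screen_self_complementarity(rec.core, max_self_comp):
                    last_failure = f"self-complementary run > {max_self_comp} bp"
                    continue
                if (flank5 and flank5 in rec.core) or \
                        (flank3 and flank3 in rec.core):
                    last_failure = "flank site occurs inside the core"
                    continue
                if reference_index is not None:
                    report = novelty_screen(rec, reference_index)
                    if not report.passed:
                        last_failure = (
                            f"shared {report.longest_match_bp} bp with reference"
                        )
                        continue
                panel.append(add_flanks(rec, flank5, flank3))
                break
            else:
                raise DesignError(
                    f"retry budget ({retry_budget}) exhausted for {rec_id}: "
                    f"{last_failure}"
                )
    return panel
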