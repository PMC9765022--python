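# Methods

## Overview

The package models the synDNA spike-in workflow for absolute metagenomic
quantification: a panel of synthetic DNA sequences spanning a range of GC
contents is mixed at known, serially diluted amounts into a DNA sample
before library preparation; after sequencing, the spike-ins' read counts
anchor a per-sample standard curve that converts any feature's read count
into a DNA mass and thence into genome copies.

## Sequence design

Sequences are random DNA with a controlled GC content. Two composition
modes exist:

- **exact** (default): the number of G+C bases is fixed at
  `round(L · gc)`; base identities within the GC and AT classes are drawn
  uniformly and positions shuffled. Realized GC is deterministic —
  `round(L·gc)/L` exactly — which makes the designer reproducible and
  testable byte for byte.
- **stochastic**: every base drawn independently (G/C with probability
  `gc`), redrawn until the realized GC is within `gc_tolerance`
  (default 0.005) of the target. This mirrors the obvious
  one-base-at-a-time generator a practitioner would write first.

Screens applied to every candidate core:

- **Self-complementarity**: no intramolecular reverse-complement match
  longer than 15 bp (hairpin potential, the standard oligo-design meaning
  of "self-complementary"; direct repeats are not screened). Detection
  seeds on exact (max_len+1)-mer reverse-complement pairs via a hash
  index and extends each seed to its maximal match; the test suite checks
  equivalence with a brute-force all-substring-pairs oracle.
- **Flank sites**: optional restriction sites are appended to the 5′/3′
  ends; a site occurring *inside* the core triggers regeneration (a
  second cut site would break cloning). Sites default to empty and are
  user-configurable strings, since no particular enzyme is mandated.
- **Novelty**: an exact k-mer screen (k = 31, both strands) against
  user-supplied reference FASTA files, reporting the shared-k-mer count
  and the longest exact match. This is a local surrogate for a full
  database homology search, not an equivalent: it catches exact identity,
  not diverged similarity. With an empty index the screen is skipped and
  flagged.

Each panel position draws from its own spawned RNG stream
(`numpy.random.SeedSequence.spawn`), so a fixed seed yields a
byte-identical panel regardless of per-sequence retry counts.

## Pools and dilutions

A dilution series is a descending geometric sequence of concentrations;
the default spans 1 to 10⁻⁴ ng/µL in 10-fold steps (five levels). The
default assignment rule places replicate `r` of GC-level group `g` at
dilution level `(g + r·⌊n/2⌋) mod n`: every dilution level is used
equally often and the two members of a GC pair sit at distant dilutions,
so no dilution level is confounded with GC content. Explicit maps
override the rule.

Spike proportion: "5%" is interpreted as 5% of the *combined*
(sample + spike) DNA mass, i.e. spike mass = f/(1−f) × sample mass; the
alternative reading (5% of sample mass) is selectable. The calibration
ground truth is the assigned concentration itself (ng/µL): absolute
volumes are not modelled, exactly as a standard curve regressed on
dilution level. Reads align to the synDNA insert, not the plasmid
vector, so count-generating mass defaults to insert-only
(insert_length/plasmid_length of the plasmid mass; default 2,000/4,710).

## Counting and normalization

SAM parsing counts one alignment per primary record keyed by reference;
secondary and supplementary records are ignored, unmapped records count
toward the sequenced-read total only. Multi-mappers therefore count once,
at their primary position. NM-tag edit distances and aligned-base totals
accumulate per reference; the base-call error rate is
100 × mismatches / aligned bases, undefined (not zero) without aligned
bases. A mapped record lacking an NM tag keeps its count but is excluded
from the error-rate tallies, with a warning counter.

CPM is 10⁶ × count / total sequenced reads. The total is the
pre-alignment library size, matching the definition of the normalized
read count X_i; normalizing by aligned reads only is available behind a
flag. Count tables are feature × sample TSVs with a leading
`#FeatureID`-style header and a (sample_id, total_reads) sidecar; without
the sidecar, totals fall back to column sums with a warning.

Forward and reverse orientations are combined by element-wise summation
when no orientation bias is observed, giving one calibration model per
sample.

## Calibration

The standard curve is ordinary least squares of log10(assigned mass) on
log10(CPM) (`scipy.stats.linregress`), reported with slope, intercept,
R², and the two-sided t-test p-value for slope ≠ 0. The regression is
deliberately oriented to predict mass from signal, because that is the
direction in which it is applied. Although the mass–signal relation can
be written linearly, the fit is performed and inverted on the log–log
scale, where serial dilutions are linear across four decades; a raw-scale
mode exists behind a flag for comparison.

Zero-CPM calibration points are dropped with a warning (log undefined);
a pseudo-count mode (+0.5 reads before CPM) is selectable. At least 3
usable points are required; all-identical masses or CPMs raise a
degenerate-design error. Replicate libraries are averaged on the log-CPM
scale (geometric mean) before fitting by default, or fitted jointly.

## Absolute abundance

For taxon `i` with genome length `Y_i`: X_i = aligned reads / total
sequenced reads; the model maps X_i (as CPM) to a read weight in ng; and

    cells_i = read_weight_i × 10⁻⁹ × 6.022×10²³ / (Y_i × 650)

The 10⁻⁹ ng→g factor is applied explicitly so the formula is
dimensionally exact; it cancels in percent compositions. One genome copy
per cell is assumed (prokaryotic haploidy); a per-taxon ploidy divisor is
accepted. Zero-count taxa get zero cells and stay in the profile.

Filters and comparisons:

- **Coverage filter**: keep taxa whose genome coverage breadth (fraction
  of positions with depth ≥ 1, 0-based half-open blocks) strictly exceeds
  1% by default; profiles without breadth are kept with a warning.
  Percentages are recomputed over survivors.
- **Genus aggregation**: species cells sum within genus; totals conserved.
- **Relative abundance baseline**: 100 × count / Σ counts over the taxon
  set (sums to 100); normalization by total sequenced reads is available.
- **compare**: percent error 100 × |pred − exp| / exp (denominator
  switchable to the prediction), log10(pred/exp), and Pearson correlation
  across taxa with two-sided p. Zero-expected taxa are flagged and
  excluded from the correlation; constant vectors yield a missing (None)
  correlation rather than a spurious value.

## Simulator

Count-level simulation is the default: read counts are drawn over all
sources (taxa and synDNA inserts) with probabilities proportional to DNA
mass × GC weight.

- Taxon mass is physical: cells × Y × 650 / N_A, in ng. synDNA masses are
  proportional to their assigned concentrations, scaled so the pool's
  plasmid mass is the configured spike fraction of total DNA; the ng per
  concentration-unit scale factor is recorded in the truth sidecar.
  Because calibration regresses on assigned concentrations, predicted
  masses carry that known scale factor — exactly as in the real assay —
  so percent compositions are recovered exactly and absolute cells up to
  the recorded scale.
- **GC bias**: w(gc) = 1 + s·(1 − 2·(2(gc − 0.5))²), a smooth unimodal
  weight peaking at 50% GC and spanning [1−s, 1+s]; s = 0.2 emulates a
  ±20% amplification bias. The functional form is a modelling choice; any
  smooth unimodal weight of the same amplitude behaves equivalently at
  the granularity tested.
- **Noise**: `none` (exact expectations, for identity tests),
  `multinomial` (default), or `lognormal` (multiplicative log-normal mass
  noise, σ default 0.3, then multinomial) as a generic overdispersion
  knob for replicate variability.
- **Error model**: per-base substitution probability is quadratic in GC
  percent, clipped to [0, 100]. The default coefficients
  (a, b, c) = (0.002, −0.22, 6.8) are synthetic, shaped to the known
  qualitative pattern — highest error for GC-poor reads, minimum near
  55% GC (≈2.4% at 26% GC, ≈0.75% at 55%); no quantitative result depends
  on them. The optional FASTQ mode applies this model per window with
  matching Phred qualities; it supports integration tests, not realistic
  read simulation (no indels, insert-size or quality-profile modelling).

Default study conditions: 10 synDNAs in pairs over 1 → 10⁻⁴ ng/µL, 5%
spike fraction, 2,000-bp inserts on a 4,710-bp plasmid, 8-taxon mock
community with the commercial mock's cell proportions (equal DNA mass per
species), read depth 5×10⁵ for pool-only runs and 10⁶ for community
runs. At these depths the most dilute synDNAs receive few reads in
community runs, as in real libraries; zero-count points are dropped from
the fit, which still leaves ≥ 8 usable points in practice.

What the simulator does *not* emulate: alignment ambiguity and
multi-mapping, database incompleteness, host contamination (beyond
unaligned mass), DNA-extraction efficiency differences, and pipetting
error in pool construction. Passing tests therefore demonstrate the
statistical correctness of the pipeline given faithful counts, not
robustness to upstream artifacts.

## Numerical choices and edge cases

- OLS via `scipy.stats.linregress`; tests verify equality with the
  closed-form formulas to 12 digits.
- Percent renormalization after every filter/aggregation (tolerance
  1e−9 in tests); zero-total profiles get 0% throughout.
- Coverage threshold is strictly greater-than, so exactly-1% breadth is
  excluded.
- Geometric-mean replicate averaging ignores zero-CPM replicates for a
  given synDNA; a synDNA with no signal anywhere becomes a zero-CPM point
  and is dropped by the fit's zero policy.
- Per-replicate seeds in the acceptance script derive from the base seed
  as (seed × 100003 + i) mod (2³¹ − 1).

## Known limitations

- The novelty screen detects exact k-mer identity only; genuinely novel
  panels should still be checked against a comprehensive database before
  synthesis.
- Calibration assumes a single log-linear regime; saturation at very high
  spike input or dropout below ~10 reads are not modelled beyond zero
  handling.
- Absolute (not just proportional) cell numbers require the spike volume
  bookkeeping the assigned-concentration proxy elides; the simulator's
  truth sidecar records the needed scale factor, but real experiments
  must track it in the pool metadata.
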