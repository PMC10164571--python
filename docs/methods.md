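# Methods

## Inverted-pair discovery

### Coordinates and candidate enumeration

All internal coordinates are 0-based half-open; conversion from the
RepeatMasker dialect (1-based inclusive, `C` for the minus strand) happens
only in `genomic_io`. A candidate inverted pair is any two annotated
elements in one region that share a repeat family, sit on opposite strands,
do not overlap, and are separated by less than the distance cap. Separation
is the inner gap (downstream start − upstream end), i.e. the length of the
intervening "spacer" sequence — not center-to-center distance — because the
biology of fold-back formation depends on the single-stranded loop between
the annealing arms. Convergent (`+` then `−`) and divergent (`−` then `+`)
arrangements are both enumerated and labelled. Elements whose annotations
overlap each other (nested or fragmented annotation artifacts) are skipped
rather than treated as zero-separation pairs.

An element belongs to a region when it overlaps it by at least 1 bp
(`attribution="overlap"`, the weakest assumption); full containment is
available as `attribution="containment"`. A pair can therefore be reported
in more than one region if regions overlap; counts are per region.

### Alignment and retention

Each candidate is scored with a local Smith–Waterman alignment (affine
gaps) of the upstream element sequence against the reverse complement of
the downstream one, both taken from the genome's plus strand. Scoring
defaults emulate nucleotide BLAST: match +2, mismatch −3, gap existence 5,
gap extension 2 (a gap of length k costs 5 + 2k). The backend is
Biopython's `PairwiseAligner`; identity and matched length are recomputed
from the alignment coordinates by an explicit column walk so that the
conventions below are guaranteed:

- `matched_length` counts all alignment columns, gap columns included;
- `identity_fraction` = identities / matched_length by default
  (`identity_denominator="alignment"`, the common "pident over alignment
  length" convention); identities / length of the shorter element is
  available behind `identity_denominator="shorter_element"`;
- `N` never counts as an identity and scores as a mismatch against every
  base, including `N` (real genome windows contain N runs);
- among equal-scoring optimal alignments, the one with the smallest start
  in A, then in B, is kept (a bounded prefix of the optimal-alignment
  enumeration is inspected, since the number of co-optimal tracebacks can
  be combinatorial);
- only the single best local alignment per pair is retained — one
  identity/length/distance triple per pair.

A pair passes when identity_fraction > 0.75, matched_length > 100 bp and
separation < 30 kb. The thresholds are strict inequalities by default, as
the retention rules are stated; `inequality_mode="inclusive"` relaxes all
three to ≥/≤ for boundary exploration. Lowering `min_identity` or raising
`max_separation` never removes a passing pair (threshold monotonicity).

### Reporting

`scan_regions` reports, deterministically (region input order, then pair
coordinates): per-region passing-pair counts by family; for each family the
number of regions with ≥1, >1 and >10 passing pairs; and histograms of
passing pairs by separation ([0,10), [10,20), [20,30) kb) and identity
([75,80), [80,85), [85,90), [90,95), [95,100]%, left-closed with the last
bin closed). Bin totals must equal the passing-pair count; a pair outside
all bins raises, which is impossible for passing pairs under the default
thresholds and therefore serves as an internal consistency check.

## Fluctuation-test rate estimation

Drake's median method defines the rate per cell per generation as the root
μ of μ·ln(N·μ) = f, with f the mutant frequency and N the final population
size. `drake_rate` locates the root by bracketed Brent iteration on
(1/N, max(f, e/N)], doubling the upper bound if needed; g(1/N) = −f < 0 and
g(max(f, e/N)) ≥ 0 whenever N·f > 1, so the bracket always holds. (The
naive bracket (1/N, f] fails for 1 < N·f < e, where the root exceeds f.)
The returned root satisfies the fixed point to ~1e−14 relative error,
comfortably inside the 1e−10 contract.

`estimate_rate` computes per-culture rates μᵢ from each culture's own
frequency and population size (no pooling), takes their median, and
attaches a 95% percentile bootstrap CI (default 10 000 resamples, seeded;
rates are sorted before resampling so culture order cannot change the
result). Conventions:

- a culture with zero mutants contributes rate 0 (the formula is undefined
  at f = 0);
- a culture with exactly one mutant has N·f = 1, the boundary the public
  `drake_rate` excludes; the fixed-point root still exists (μ ≈ 1.763/N)
  and is used, so single-mutant cultures are not discarded;
- `method="median_frequency"` applies Drake's formula once to the median
  frequency and median population size, the other common reading of the
  median method; with monotone per-culture rates the two usually agree;
- `ci_method="rank"` gives the order-statistic (binomial-rank) CI of the
  median as an assumption-light alternative to the bootstrap. Whether a
  reported CI should span the cultures of one experiment or repeated
  experiments is a design question for the caller; both entry points exist
  (one experiment per call; call repeatedly for experiment-level spread).

`rate_ratio` is the plain arithmetic quotient of two point estimates.

### Strand coordination

For clustered mutations recorded as reference top-strand bases, a mutation
is "designated-strand pyrimidine" when its pyrimidine lies on the
designated strand: reference C/T for the top strand, reference A/G for the
bottom (whose complement is the pyrimidine). A clone is coordinated when
all of its ≥2 mutations agree; single-mutation clones have a defined
fraction but are never flagged coordinated. Pooled counts across clones
use the same rule.

## Synthetic data

The generator emulates the study conditions rather than any particular
genome:

- **Background**: i.i.d. nucleotides at GC 0.41 (the human genome-wide
  average), seeded. No repeats other than the planted ones, so the
  annotation is complete by construction.
- **Planted pairs**: arm A is a seeded random 320-mer (a real Alu consensus
  can be supplied; scanner behavior depends only on identity, length and
  spacer). Arm B is the reverse complement of a copy of arm A carrying
  round(L·divergence) substitutions at distinct seeded positions, so the
  realized gap-free identity is exactly 1 − k/L (within 1 percentage point
  of the target, by rounding). The design grids are identities
  100/94/86/75/65% and spacers 12 bp – 30 kb. Arms of different plants are
  independent, so cross-plant pairs are non-homologous and precision
  against truth is measurable.
- **Truth records** carry the planted intervals, realized identity, spacer
  and an `expected_pass` flag computed from realized values under the
  default thresholds. The local aligner may trim a mismatch-dense end and
  report slightly higher identity than the planted divergence; plants at
  exactly 75% identity sit on the threshold boundary and are deliberately
  absent from the recovery benchmark (65% and 80% bracket it instead).
- **`substitute_spaced`** places substitutions ≥3 bp apart and ≥2 bp from
  the ends so that, under +2/−3 scoring, every prefix/suffix of the
  full-length gapless alignment scores positive and the optimal local
  alignment is exactly full-length — the construction used by the
  alignment-identity oracle.
- **Cultures**: growth is discrete doublings from one cell to ≥ the target
  population; at each doubling new mutants arise binomially at rate μ per
  division and mutant lineages double thereafter. This discretization
  exhibits the Luria–Delbrück jackpot skew (mean mutant count > median)
  that the estimator assumes. It omits death, phenotypic lag, plating
  efficiency and post-plating growth.

What passing tests on synthetic data do **not** show: behavior on real
annotation (fragmented/nested RepeatMasker elements beyond the skip rule,
shared Alu consensus homology that makes *every* cross pair alignable,
N-runs at scale), or calibration of the thresholds themselves — those are
inputs, not outputs, of this package.

## Problem sizes and numerical choices

The recovery benchmark scans 30 regions over a ≥2 Mb genome with 65 planted
pairs (50 recoverable; 10 at 65% identity and 5 at 30 kb spacer that must
be excluded), one region carrying 12 pairs to exercise the ">10 per region"
tally. Rate recovery runs 100 experiments of 24 cultures at μ = 5×10⁻⁷,
N ≈ 2.7×10⁸ (2²⁸ cells); the whole acceptance script completes in seconds.
Root-finding tolerance is brentq rtol 1e−14; bootstrap default 10 000
resamples (2000 in the repeated-experiment loops, where only the point
estimate is consumed). All randomness flows from explicit seeds through
`numpy.random.default_rng`.

## Known limitations

- Only the best local alignment per pair is considered; a pair with two
  separate homologous blocks is summarized by one block.
- The scanner is quadratic in elements per region (all candidate pairs are
  aligned); regions with thousands of same-family elements would need
  banding or seeding, which real cluster-scale inputs do not require.
- No cruciform/hairpin thermodynamics, no short-palindrome (<100 bp)
  detection, no APOBEC-cluster calling from VCFs, and no mechanistic
  simulation of fold-back/dicentric formation — the scanner classifies
  structural potential only.
- The Luria–Delbrück estimator is the Drake median method only; no
  Ma–Sandri–Sarkar maximum likelihood, plating-efficiency or
  phenotypic-lag corrections.
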