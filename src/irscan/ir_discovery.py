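"""Discovery of inverted repeat (IR) pairs of transposable elements.

Within each scan region, every pair of same-family, opposite-strand,
non-overlapping elements separated by less than the distance cap is a
candidate inverted pair. Each candidate is scored with a local
Smith-Waterman alignment (affine gaps) of the upstream element against the
reverse complement of the downstream one; pairs whose best alignment exceeds
the identity and matched-length thresholds are retained. The retention
defaults — identity > 75%, matched length > 100 bp, separation < 30 kb —
are the structural parameters under which inverted pairs annealing in
single-stranded DNA remain efficient triggers of chromosomal rearrangement.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from intervaltree import IntervalTree

from .genomic_io import GenomicInterval, Region, RepeatElement

__all__ = [
    "ScanConfig",
    "PairCandidate",
    "AlignmentResult",
    "IRPairResult",
    "ScanReport",
    "reverse_complement",
    "collect_elements_in_region",
    "enumerate_inverted_pairs",
    "align_inverted_pair",
    "evaluate_pair",
    "scan_regions",
    "bin_pairs",
    "DISTANCE_BIN_LABELS",
    "IDENTITY_BIN_LABELS",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ScanConfig:
    """Retention thresholds and alignment scoring for the IR scan.

    Defaults follow the nucleotide-BLAST scoring scheme (match +2,
    mismatch -3, gap existence 5, gap extension 2) and the strict
    retention thresholds: identity > 0.75, matched length > 100 bp,
    separation < 30000 bp.
    """

    min_identity: float = 0.75
    min_matched_length: int = 100
    max_separation: int = 30_000
    match_score: int = 2
    mismatch_penalty: int = 3
    gap_open: int = 5
    gap_extend: int = 2
    #: "strict" applies the thresholds as strict inequalities (>, >, <);
    #: "inclusive" relaxes them to >=, >=, <=.
    inequality_mode: str = "strict"
    #: identity denominator: "alignment" (all alignment columns including
    #: gap columns) or "shorter_element" (length of the shorter element).
    identity_denominator: str = "alignment"
    #: pair-to-region attribution: "overlap" keeps elements overlapping the
    #: region by >=1 bp, "containment" requires full containment.
    attribution: str = "overlap"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")
        if self.min_matched_length < 0 or self.max_separation < 0:
            raise ValueError("length/separation thresholds must be non-negative")
        if self.match_score < 1 or self.mismatch_penalty < 0:
            raise ValueError("match_score >= 1 and mismatch_penalty >= 0 required")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.inequality_mode not in ("strict", "inclusive"):
            raise ValueError("inequality_mode must be 'strict' or 'inclusive'")
        if self.identity_denominator not in ("alignment", "shorter_element"):
            raise ValueError(
                "identity_denominator must be 'alignment' or 'shorter_element'"
            )
        if self.attribution not in ("overlap", "containment"):
            raise ValueError("attribution must be 'overlap' or 'containment'")


@dataclass(frozen=True)
class PairCandidate:
    """A same-family inverted-orientation element pair before alignment.

    ``elementA`` precedes ``elementB`` on the chromosome; ``separation_bp``
    is the inner gap ``B.start - A.end`` (the "spacer"). A pair is convergent
    when the upstream element is on "+" and the downstream on "-" (elements
    pointing toward each other), divergent for the opposite arrangement.
    """

    region_id: str
    elementA: RepeatElement
    elementB: RepeatElement
    separation_bp: int
    orientation_class: str

    def __post_init__(self) -> None:
        a, b = self.elementA, self.elementB
        if a.chrom != b.chrom:
            raise ValueError("pair elements must share a chromosome")
        if a.end > b.start:
            raise ValueError("elementA must precede elementB without overlap")
        if a.strand == b.strand:
            raise ValueError("pair elements must be on opposite strands")
        if a.family != b.family:
            raise ValueError("pair elements must share a family")
        expected = "convergent" if a.strand == "+" else "divergent"
        if self.orientation_class != expected:
            raise ValueError(
                f"orientation_class {self.orientation_class!r} inconsistent with strands"
            )
        if self.separation_bp != b.start - a.end:
            raise ValueError("separation_bp must equal B.start - A.end")


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment of one element against the other's reverse complement.

    ``matched_length`` counts alignment columns including gap columns;
    ``identity_fraction`` is ``identities`` over the configured denominator.
    ``spanA``/``spanB`` are the aligned sub-intervals within each element
    (0-based half-open, element-local, on the element's genomic "+" strand).
    """

    score: float
    matched_length: int
    identities: int
    identity_fraction: float
    spanA: tuple[int, int] = (0, 0)
    spanB: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise ValueError("identity_fraction must be in [0, 1]")
        if self.identities > self.matched_length:
            raise ValueError("identities cannot exceed matched_length")
        if self.matched_length == 0 and self.score != 0:
            raise ValueError("empty alignment must have score 0")


EMPTY_ALIGNMENT = AlignmentResult(
    score=0.0, matched_length=0, identities=0, identity_fraction=0.0
)


@dataclass(frozen=True)
class IRPairResult:
    candidate: PairCandidate
    alignment: AlignmentResult
    pass_filter: bool


@dataclass
class ScanReport:
    """Per-region and per-family summary of a scan."""

    n_regions: int = 0
    n_passing_pairs: int = 0
    #: region_id -> {"total": n, "families": {family: n}}
    per_region: dict = field(default_factory=dict)
    #: family -> number of regions with >=1 passing pair of that family
    per_family_region_counts: dict = field(default_factory=dict)
    #: family -> number of regions with >1 passing pair of that family
    regions_with_gt1: dict = field(default_factory=dict)
    #: family -> number of regions with >10 passing pairs of that family
    regions_with_gt10: dict = field(default_factory=dict)
    distance_histogram: dict = field(default_factory=dict)
    identity_histogram: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_regions": self.n_regions,
            "n_passing_pairs": self.n_passing_pairs,
            "per_region": self.per_region,
            "per_family_region_counts": self.per_family_region_counts,
            "regions_with_gt1": self.regions_with_gt1,
            "regions_with_gt10": self.regions_with_gt10,
            "distance_histogram": self.distance_histogram,
            "identity_histogram": self.identity_histogram,
        }


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A, C, G, T, N} alphabet (N -> N)."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def collect_elements_in_region(
    elements: Iterable[RepeatElement], region: Region
) -> list[RepeatElement]:
    """Elements overlapping the region by >=1 bp, in chromosomal order."""
    hits = [e for e in elements if e.interval.overlaps(region.interval)]
    hits.sort(key=lambda e: (e.start, e.end))
    return hits


def enumerate_inverted_pairs(
    elements: Sequence[RepeatElement], config: ScanConfig | None = None
) -> list[PairCandidate]:
    """All same-family opposite-strand non-overlapping pairs within the distance cap.

    ``elements`` must come from one region on one chromosome. Overlapping
    inverted elements (nested or intersecting annotations) are skipped with a
    debug note rather than treated as separation 0.
    """
    config = config or ScanConfig()
    ordered = sorted(elements, key=lambda e: (e.start, e.end))
    chroms = {e.chrom for e in ordered}
    if len(chroms) > 1:
        raise ValueError(f"elements span multiple chromosomes: {sorted(chroms)}")
    out: list[PairCandidate] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if a.family != b.family or a.strand == b.strand:
                continue
            if a.end > b.start:
                logger.debug(
                    "skipping overlapping inverted elements %s:%d-%d / %d-%d",
                    a.chrom, a.start, a.end, b.start, b.end,
                )
                continue
            sep = b.start - a.end
            if config.inequality_mode == "strict":
                if sep >= config.max_separation:
                    continue
            elif sep > config.max_separation:
                continue
            out.append(
                PairCandidate(
                    region_id="",
                    elementA=a,
                    elementB=b,
                    separation_bp=sep,
                    orientation_class="convergent" if a.strand == "+" else "divergent",
                )
            )
    return out


def _make_aligner(config: ScanConfig) -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            if x == y and x != "N":
                matrix[x, y] = config.match_score
            else:
                # N scores as a mismatch against everything, including N.
                matrix[x, y] = -config.mismatch_penalty
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # BLAST convention: a gap of length k costs open + k*extend.
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def _alignment_stats(alignment, lenB: int) -> tuple[int, int, tuple, tuple]:
    """Column walk over one local alignment: (matched_length, identities, spanA, spanB)."""
    coords = alignment.coordinates
    target = alignment.target
    query = alignment.query
    matched = 0
    idents = 0
    for i in range(coords.shape[1] - 1):
        t0, t1 = int(coords[0, i]), int(coords[0, i + 1])
        q0, q1 = int(coords[1, i]), int(coords[1, i + 1])
        if t1 > t0 and q1 > q0:
            matched += t1 - t0
            idents += sum(
                1
                for x, y in zip(target[t0:t1], query[q0:q1])
                if x == y and x != "N"
            )
        else:
            matched += max(t1 - t0, q1 - q0)
    spanA = (int(coords[0, 0]), int(coords[0, -1]))
    q_span = (int(coords[1, 0]), int(coords[1, -1]))
    # The query is the reverse complement of element B: map back.
    spanB = (lenB - q_span[1], lenB - q_span[0])
    return matched, idents, spanA, spanB


def align_inverted_pair(
    seqA: str, seqB: str, config: ScanConfig | None = None
) -> AlignmentResult:
    """Best local alignment of ``seqA`` against ``reverse_complement(seqB)``.

    Both sequences are genome substrings on the "+" orientation. Among
    equal-scoring optimal alignments the one with the smallest start in A,
    then in B, is retained. A best score of 0 (no positive-scoring local
    alignment) yields the empty result.
    """
    config = config or ScanConfig()
    if not seqA or not seqB:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(config)
    rcB = reverse_complement(seqB)
    alignments = aligner.align(seqA, rcB)
    try:
        best_score = alignments.score
    except (AttributeError, IndexError):
        return EMPTY_ALIGNMENT
    if best_score <= 0:
        return EMPTY_ALIGNMENT
    # All returned alignments are optimal; inspect a bounded prefix for the
    # deterministic tie-break (the optimum count can be combinatorial).
    best = None
    best_key = None
    for alignment in itertools.islice(alignments, 64):
        matched, idents, spanA, spanB = _alignment_stats(alignment, len(seqB))
        key = (spanA[0], spanB[0])
        if best_key is None or key < best_key:
            best_key = key
            best = (matched, idents, spanA, spanB)
    matched, idents, spanA, spanB = best
    if config.identity_denominator == "alignment":
        denom = matched
    else:
        denom = min(len(seqA), len(seqB))
    fraction = idents / denom if denom else 0.0
    return AlignmentResult(
        score=float(best_score),
        matched_length=matched,
        identities=idents,
        identity_fraction=fraction,
        spanA=spanA,
        spanB=spanB,
    )


def _passes(alignment: AlignmentResult, separation_bp: int, config: ScanConfig) -> bool:
    if config.inequality_mode == "strict":
        return (
            alignment.identity_fraction > config.min_identity
            and alignment.matched_length > config.min_matched_length
            and separation_bp < config.max_separation
        )
    return (
        alignment.identity_fraction >= config.min_identity
        and alignment.matched_length >= config.min_matched_length
        and separation_bp <= config.max_separation
    )


def evaluate_pair(
    candidate: PairCandidate,
    genome: Mapping[str, str],
    config: ScanConfig | None = None,
) -> IRPairResult:
    """Extract both element sequences, align, and apply the retention thresholds."""
    config = config or ScanConfig()
    chrom = candidate.elementA.chrom
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome")
    chrom_seq = genome[chrom]
    for element in (candidate.elementA, candidate.elementB):
        if element.end > len(chrom_seq):
            raise ValueError(
                f"element {element.chrom}:{element.start}-{element.end} outside "
                f"chromosome bounds (length {len(chrom_seq)})"
            )
    seqA = chrom_seq[candidate.elementA.start : candidate.elementA.end]
    seqB = chrom_seq[candidate.elementB.start : candidate.elementB.end]
    alignment = align_inverted_pair(seqA, seqB, config)
    return IRPairResult(
        candidate=candidate,
        alignment=alignment,
        pass_filter=_passes(alignment, candidate.separation_bp, config),
    )


DISTANCE_BIN_LABELS = ["0-10kb", "10-20kb", "20-30kb"]
IDENTITY_BIN_LABELS = ["75-80", "80-85", "85-90", "90-95", "95-100"]

_DISTANCE_EDGES = [(0, 10_000), (10_000, 20_000), (20_000, 30_000)]
# Left-closed identity bins in percent; the last bin is closed on the right
# so that 100% identity is counted.
_IDENTITY_EDGES = [(75, 80), (80, 85), (85, 90), (90, 95), (95, 100)]


def bin_pairs(pairs: Iterable[IRPairResult]) -> tuple[dict, dict]:
    """Histogram passing pairs by separation distance and percent identity.

    Distance bins: [0, 10 kb), [10, 20 kb), [20, 30 kb). Identity bins
    (percent, left-closed): [75, 80), ..., [90, 95), [95, 100]. A pair
    falling outside all bins raises — impossible for pairs passing the
    default thresholds, so this doubles as an internal consistency check.
    """
    dist = {label: 0 for label in DISTANCE_BIN_LABELS}
    ident = {label: 0 for label in IDENTITY_BIN_LABELS}
    for pair in pairs:
        sep = pair.candidate.separation_bp
        pct = pair.alignment.identity_fraction * 100.0
        for label, (lo, hi) in zip(DISTANCE_BIN_LABELS, _DISTANCE_EDGES):
            if lo <= sep < hi:
                dist[label] += 1
                break
        else:
            raise ValueError(f"pair separation {sep} bp outside all distance bins")
        last = IDENTITY_BIN_LABELS[-1]
        for label, (lo, hi) in zip(IDENTITY_BIN_LABELS, _IDENTITY_EDGES):
            if lo <= pct < hi or (label == last and pct == hi):
                ident[label] += 1
                break
        else:
            raise ValueError(f"pair identity {pct:.2f}% outside all identity bins")
    return dist, ident


def scan_regions(
    genome: Mapping[str, str],
    elements: Sequence[RepeatElement],
    regions: Sequence[Region],
    config: ScanConfig | None = None,
) -> tuple[ScanReport, list[IRPairResult]]:
    """Run the full scan: collect, enumerate and evaluate for every region.

    Output ordering is deterministic: regions in input order, pairs by
    coordinates within each region. Returns the report together with every
    evaluated candidate (passing and failing).
    """
    config = config or ScanConfig()
    missing = sorted(
        {r.region_id for r in regions if r.chrom not in genome}
    )
    if missing:
        raise KeyError(
            f"regions on chromosomes absent from the genome: {missing}"
        )

    trees: dict[str, IntervalTree] = {}
    for idx, element in enumerate(elements):
        trees.setdefault(element.chrom, IntervalTree()).addi(
            element.start, element.end, idx
        )

    report = ScanReport(n_regions=len(regions))
    results: list[IRPairResult] = []
    passing: list[IRPairResult] = []
    region_family_counts: dict[str, dict[str, int]] = {}

    for region in regions:
        tree = trees.get(region.chrom)
        hit_idx = sorted(iv.data for iv in tree.overlap(region.start, region.end)) if tree else []
        in_region = [elements[i] for i in hit_idx]
        if config.attribution == "containment":
            in_region = [
                e
                for e in in_region
                if e.start >= region.start and e.end <= region.end
            ]
        in_region.sort(key=lambda e: (e.start, e.end))
        family_counts: dict[str, int] = {}
        for cand in enumerate_inverted_pairs(in_region, config):
            cand = replace(cand, region_id=region.region_id)
            result = evaluate_pair(cand, genome, config)
            results.append(result)
            if result.pass_filter:
                passing.append(result)
                family = cand.elementA.family
                family_counts[family] = family_counts.get(family, 0) + 1
        region_family_counts[region.region_id] = family_counts
        report.per_region[region.region_id] = {
            "total": sum(family_counts.values()),
            "families": dict(sorted(family_counts.items())),
        }

    families = sorted({f for fc in region_family_counts.values() for f in fc})
    for family in families:
        counts = [fc.get(family, 0) for fc in region_family_counts.values()]
        report.per_family_region_counts[family] = sum(1 for c in counts if c >= 1)
        report.regions_with_gt1[family] = sum(1 for c in counts if c > 1)
        report.regions_with_gt10[family] = sum(1 for c in counts if c > 10)

    report.n_passing_pairs = len(passing)
    report.distance_histogram, report.identity_histogram = bin_pairs(passing)
    return report, results
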