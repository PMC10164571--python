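"""Synthetic inputs for every pipeline stage.

The generator emulates the study conditions end to end: genomes carrying
planted ~320 bp Alu-like elements in inverted orientation at controlled arm
identity (the 100/94/86/75/65% design points) and spacer (12 bp up to
30 kb), region lists that cover or miss them, and Luria-Delbruck culture
outcomes grown at a known mutation rate. Every planted pair comes with a
ground-truth record so recall and precision of the scanner are measurable
without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fluctuation import CultureResult
from .genomic_io import GenomicInterval, Region, RepeatElement
from .ir_discovery import IRPairResult, ScanConfig, reverse_complement

__all__ = [
    "PlantSpec",
    "TruthRecord",
    "DatasetResult",
    "DEFAULT_GC",
    "random_background",
    "mutate_to_identity",
    "substitute_spaced",
    "plant_inverted_pair",
    "build_dataset",
    "generate_dataset",
    "recovery_benchmark_plan",
    "simulate_fluctuation_cultures",
    "recovery_metrics",
    "write_fasta",
    "write_repeatmasker_out",
    "write_regions_bed",
    "write_truth_tsv",
    "read_truth_tsv",
]

#: Background GC fraction; matches the genome-wide human average.
DEFAULT_GC = 0.41

#: The identity design points exercised by the construct grid.
IDENTITY_GRID = (100, 94, 86, 75, 65)
#: The spacer design points (bp), 12 bp up to 30 kb.
SPACER_GRID = (12, 200, 1500, 3200, 5000, 7000, 10_000, 20_000, 30_000)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantSpec:
    """One planted inverted pair: where, how long, how diverged, how spaced."""

    chrom: str
    insert_position: int
    element_length: int = 320
    spacer_bp: int = 12
    identity_percent: float = 100.0
    orientation_class: str = "convergent"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.element_length <= 0:
            raise ValueError("element_length must be positive")
        if self.spacer_bp < 0:
            raise ValueError("spacer_bp must be non-negative")
        if not 0 < self.identity_percent <= 100:
            raise ValueError("identity_percent must be in (0, 100]")
        if self.orientation_class not in ("convergent", "divergent"):
            raise ValueError("orientation_class must be convergent or divergent")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted pair, used for recall/precision scoring."""

    region_id: str
    elementA: RepeatElement
    elementB: RepeatElement
    realized_identity: float
    spacer_bp: int
    expected_pass: bool


@dataclass
class DatasetResult:
    """In-memory view of one generated dataset."""

    genome: dict[str, str]
    elements: list[RepeatElement]
    regions: list[Region]
    truths: list[TruthRecord]


def random_background(
    length: int, gc_fraction: float = DEFAULT_GC, seed: int | None = 0
) -> str:
    """A seeded random background sequence with the given GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    draw = rng.choice(4, size=length, p=p)
    return _BASES[draw].tobytes().decode("ascii")


def mutate_to_identity(
    seq: str, target_identity_percent: float, seed: int | None = 0
) -> tuple[str, int]:
    """Introduce substitutions so gap-free identity to ``seq`` is exactly 1 - k/L.

    ``k = round(L * (1 - target/100))`` substitutions are placed at distinct
    seeded positions, each changing the base to a different one, so the
    realized identity is exact by construction.
    """
    if not 0 < target_identity_percent <= 100:
        raise ValueError("target identity must be in (0, 100]")
    L = len(seq)
    k = round(L * (1 - target_identity_percent / 100))
    if k > L:
        raise ValueError(f"requested {k} substitutions over length {L}")
    if k == 0:
        return seq, 0
    rng = np.random.default_rng(seed)
    positions = rng.choice(L, size=k, replace=False)
    out = list(seq)
    for pos in sorted(int(p) for p in positions):
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(out), k


def substitute_spaced(seq: str, k: int, seed: int | None = 0) -> tuple[str, int]:
    """Place exactly ``k`` substitutions spaced >=3 bp apart, away from the ends.

    Designed for gap-free alignment oracles: with substitutions at least
    3 bp apart and at least 2 bp from either end, every prefix and suffix of
    the full-length gapless alignment keeps a positive score under the
    default +2/-3 scheme, so the optimal local alignment is exactly the
    full-length one and its identity is 1 - k/L with no end trimming.
    """
    L = len(seq)
    slots = list(range(2, L - 2, 3))
    if k > len(slots):
        raise ValueError(f"cannot place {k} spaced substitutions in length {L}")
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(slots), size=k, replace=False)
    out = list(seq)
    for idx in sorted(int(p) for p in positions):
        pos = slots[idx]
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(out), k


def _expected_pass(
    realized_identity: float, element_length: int, spacer_bp: int, config: ScanConfig
) -> bool:
    if config.inequality_mode == "strict":
        return (
            realized_identity > config.min_identity
            and element_length > config.min_matched_length
            and spacer_bp < config.max_separation
        )
    return (
        realized_identity >= config.min_identity
        and element_length >= config.min_matched_length
        and spacer_bp <= config.max_separation
    )


def _build_insert(
    spec: PlantSpec,
    gc_fraction: float,
    arm_seq: str | None,
) -> tuple[str, int]:
    """Return (inserted sequence, substitution count) for a plant."""
    rng = np.random.default_rng(spec.seed)
    arm_seed, mut_seed, spacer_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 3))
    armA = arm_seq if arm_seq is not None else random_background(
        spec.element_length, gc_fraction, arm_seed
    )
    if len(armA) != spec.element_length:
        raise ValueError("arm sequence length must equal element_length")
    mutated, k = mutate_to_identity(armA, spec.identity_percent, mut_seed)
    spacer = (
        random_background(spec.spacer_bp, gc_fraction, spacer_seed)
        if spec.spacer_bp > 0
        else ""
    )
    return armA + spacer + reverse_complement(mutated), k


def plant_inverted_pair(
    genome: dict[str, str],
    spec: PlantSpec,
    gc_fraction: float = DEFAULT_GC,
    arm_seq: str | None = None,
    family: str = "SINE/Alu",
    config: ScanConfig | None = None,
) -> tuple[dict[str, str], TruthRecord, list[RepeatElement]]:
    """Insert an inverted element pair into a genome at a chosen position.

    The insert is arm A, a background spacer, and arm B — the reverse
    complement of a mutated copy of arm A at the target identity. The genome
    grows by exactly ``2 * element_length + spacer_bp``. Returns the modified
    genome, the :class:`TruthRecord` and the two annotation rows.
    """
    config = config or ScanConfig()
    if spec.chrom not in genome:
        raise KeyError(f"chromosome {spec.chrom!r} absent from genome")
    chrom_seq = genome[spec.chrom]
    if not 0 <= spec.insert_position <= len(chrom_seq):
        raise ValueError(
            f"insertion window does not fit: position {spec.insert_position} "
            f"outside chromosome of length {len(chrom_seq)}"
        )
    insert, k = _build_insert(spec, gc_fraction, arm_seq)
    L, p = spec.element_length, spec.insert_position
    new_genome = dict(genome)
    new_genome[spec.chrom] = chrom_seq[:p] + insert + chrom_seq[p:]

    strand_a, strand_b = (
        ("+", "-") if spec.orientation_class == "convergent" else ("-", "+")
    )
    elem_a = RepeatElement(
        GenomicInterval(spec.chrom, p, p + L, strand_a), family=family, name="Alu_synthA"
    )
    elem_b = RepeatElement(
        GenomicInterval(spec.chrom, p + L + spec.spacer_bp, p + 2 * L + spec.spacer_bp, strand_b),
        family=family,
        name="Alu_synthB",
    )
    realized = 1.0 - k / L
    truth = TruthRecord(
        region_id="",
        elementA=elem_a,
        elementB=elem_b,
        realized_identity=realized,
        spacer_bp=spec.spacer_bp,
        expected_pass=_expected_pass(realized, L, spec.spacer_bp, config),
    )
    return new_genome, truth, [elem_a, elem_b]


def build_dataset(
    plan: Sequence[Sequence[tuple]],
    seed: int = 0,
    element_length: int = 320,
    gc_fraction: float = DEFAULT_GC,
    chrom: str = "chr1",
    region_pad: int = 500,
    intra_region_gap: int = 200,
    inter_region_gap: int = 3000,
    min_genome_length: int = 0,
    family: str = "SINE/Alu",
    config: ScanConfig | None = None,
) -> DatasetResult:
    """Build one chromosome with planted pairs laid out per the plan.

    ``plan`` is a list over regions; each entry lists that region's plants as
    ``(identity_percent, spacer_bp)`` or ``(identity_percent, spacer_bp,
    orientation_class)`` tuples (empty list = negative region). Regions are
    tiled left to right along one chromosome, padded with background, and the
    chromosome is extended to ``min_genome_length`` if needed. Arms of
    distinct plants are independent random sequences, so cross-plant element
    pairs are non-homologous by construction.
    """
    config = config or ScanConfig()
    rng = np.random.default_rng(seed)
    chunks: list[str] = []
    pos = 0

    def _append(seq: str) -> None:
        nonlocal pos
        chunks.append(seq)
        pos += len(seq)

    def _background(n: int) -> str:
        return random_background(n, gc_fraction, int(rng.integers(0, 2**31 - 1)))

    elements: list[RepeatElement] = []
    regions: list[Region] = []
    truths: list[TruthRecord] = []

    for r_idx, plants in enumerate(plan):
        _append(_background(inter_region_gap))
        region_id = f"region_{r_idx:04d}"
        region_start = pos
        _append(_background(region_pad))
        for p_idx, plant in enumerate(plants):
            if len(plant) == 2:
                identity, spacer = plant
                orientation = "convergent" if (r_idx + p_idx) % 2 == 0 else "divergent"
            else:
                identity, spacer, orientation = plant
            spec = PlantSpec(
                chrom=chrom,
                insert_position=0,
                element_length=element_length,
                spacer_bp=int(spacer),
                identity_percent=float(identity),
                orientation_class=orientation,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            insert, k = _build_insert(spec, gc_fraction, None)
            strand_a, strand_b = (
                ("+", "-") if orientation == "convergent" else ("-", "+")
            )
            elem_a = RepeatElement(
                GenomicInterval(chrom, pos, pos + element_length, strand_a),
                family=family,
                name=f"Alu_synth_{r_idx}_{p_idx}A",
            )
            b_start = pos + element_length + spec.spacer_bp
            elem_b = RepeatElement(
                GenomicInterval(chrom, b_start, b_start + element_length, strand_b),
                family=family,
                name=f"Alu_synth_{r_idx}_{p_idx}B",
            )
            _append(insert)
            realized = 1.0 - k / element_length
            truths.append(
                TruthRecord(
                    region_id=region_id,
                    elementA=elem_a,
                    elementB=elem_b,
                    realized_identity=realized,
                    spacer_bp=spec.spacer_bp,
                    expected_pass=_expected_pass(
                        realized, element_length, spec.spacer_bp, config
                    ),
                )
            )
            elements.extend([elem_a, elem_b])
            _append(_background(intra_region_gap))
        _append(_background(region_pad))
        regions.append(
            Region(
                interval=GenomicInterval(chrom, region_start, pos),
                region_id=region_id,
                category="synthetic",
            )
        )

    if pos < min_genome_length:
        _append(_background(min_genome_length - pos))
    return DatasetResult(
        genome={chrom: "".join(chunks)},
        elements=elements,
        regions=regions,
        truths=truths,
    )


def generate_dataset(
    outdir: str | Path,
    n_regions: int = 20,
    plant_fraction: float = 0.6,
    pairs_per_region_distribution: dict[int, float] | None = None,
    seed: int = 0,
    identity_choices: Sequence[float] = (100, 94, 86),
    spacer_choices: Sequence[int] = (12, 200, 1500, 5000),
    element_length: int = 320,
    gc_fraction: float = DEFAULT_GC,
    min_genome_length: int = 0,
) -> DatasetResult:
    """Generate a full dataset and write FASTA, annotation, regions and truth files.

    Exactly ``round(n_regions * plant_fraction)`` regions carry at least one
    planted pair; their pair counts are drawn from
    ``pairs_per_region_distribution`` (a mapping count -> probability,
    default all-ones). Plant identities and spacers are drawn uniformly from
    the given choice grids. Fully reproducible: the same seed yields
    byte-identical files.

    Writes ``genome.fa``, ``repeats.out`` (RepeatMasker layout),
    ``regions.bed`` and ``truth.tsv`` under ``outdir``.
    """
    if not 0.0 <= plant_fraction <= 1.0:
        raise ValueError("plant_fraction must be in [0, 1]")
    dist = pairs_per_region_distribution or {1: 1.0}
    counts = sorted(dist)
    probs = np.array([dist[c] for c in counts], dtype=float)
    if (probs < 0).any() or not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("pairs_per_region_distribution must be a probability distribution")
    if any(c < 1 for c in counts):
        raise ValueError("pair counts in the distribution must be >= 1")

    rng = np.random.default_rng(seed)
    n_planted = round(n_regions * plant_fraction)
    planted_idx = set(rng.permutation(n_regions)[:n_planted].tolist())
    plan: list[list[tuple]] = []
    for r in range(n_regions):
        if r not in planted_idx:
            plan.append([])
            continue
        n_pairs = int(np.asarray(counts)[rng.choice(len(counts), p=probs)])
        plan.append(
            [
                (
                    float(rng.choice(np.asarray(identity_choices, dtype=float))),
                    int(rng.choice(np.asarray(spacer_choices, dtype=int))),
                )
                for _ in range(n_pairs)
            ]
        )
    dataset = build_dataset(
        plan,
        seed=int(rng.integers(0, 2**31 - 1)),
        element_length=element_length,
        gc_fraction=gc_fraction,
        min_genome_length=min_genome_length,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.genome, outdir / "genome.fa")
    write_repeatmasker_out(dataset.elements, outdir / "repeats.out")
    write_regions_bed(dataset.regions, outdir / "regions.bed")
    write_truth_tsv(dataset.truths, outdir / "truth.tsv")
    return dataset


def recovery_benchmark_plan() -> list[list[tuple]]:
    """The standard planted-pair recovery scenario, as a build_dataset plan.

    30 regions carrying 50 recoverable pairs that sweep identities
    {100, 94, 86, 80}% and spacers {12 bp, 1.5, 5, 10, 20, 29 kb}, plus 10
    pairs at 65% identity and 5 at a 30 kb spacer (both excluded by the
    default strict thresholds), plus one negative region. One region holds
    12 pairs to exercise the ">10 pairs per region" tally.
    """
    identities = (100, 94, 86, 80)
    spacers = (12, 1500, 5000, 10_000, 20_000, 29_000)
    good = [(identities[i % 4], spacers[i % 6]) for i in range(50)]
    plan: list[list[tuple]] = [[] for _ in range(30)]
    plan[0] = good[:12]
    for i, plant in enumerate(good[12:]):
        plan[1 + i % 24].append(plant)
    for i in range(10):
        plan[25 + i % 4].append((65, 1500))
    for i in range(5):
        plan[5 + i].append((100, 30_000))
    return plan


def simulate_fluctuation_cultures(
    mu: float, n_final: float, n_cultures: int, seed: int | None = 0
) -> list[CultureResult]:
    """Simulate parallel cultures under a Luria-Delbruck growth model.

    Each culture grows from a single non-mutant cell by discrete doublings
    until the population reaches at least ``n_final``. At each doubling, new
    mutants arise binomially at rate ``mu`` per division and existing mutant
    lineages double alongside, producing the characteristic jackpot skew.
    """
    if not 0.0 <= mu < 1e-3:
        raise ValueError("mu must be in [0, 1e-3)")
    if n_final < 1e3:
        raise ValueError("n_final must be at least 1e3")
    if n_cultures < 1:
        raise ValueError("n_cultures must be positive")
    rng = np.random.default_rng(seed)
    generations = math.ceil(math.log2(n_final))
    cultures: list[CultureResult] = []
    for _ in range(n_cultures):
        nonmutant = 1
        mutants = 0
        for _gen in range(generations):
            new_mutants = int(rng.binomial(nonmutant, mu)) if mu > 0 else 0
            mutants = 2 * mutants + new_mutants
            nonmutant = 2 * nonmutant - new_mutants
        cultures.append(
            CultureResult(mutant_count=mutants, total_cells=float(nonmutant + mutants))
        )
    return cultures


def recovery_metrics(
    results: Iterable[IRPairResult], truths: Sequence[TruthRecord]
) -> dict:
    """Recall/precision of passing scanned pairs against planted ground truth.

    Recall is over truth records with ``expected_pass``; precision is the
    fraction of passing pairs that correspond to a planted pair (whether or
    not that plant was expected to pass).
    """
    def _truth_key(t: TruthRecord):
        return (t.region_id, t.elementA.start, t.elementA.end, t.elementB.start, t.elementB.end)

    def _pair_key(p: IRPairResult):
        c = p.candidate
        return (c.region_id, c.elementA.start, c.elementA.end, c.elementB.start, c.elementB.end)

    truth_keys = {_truth_key(t) for t in truths}
    expected_keys = {_truth_key(t) for t in truths if t.expected_pass}
    passing = [p for p in results if p.pass_filter]
    passing_keys = {_pair_key(p) for p in passing}

    recovered = expected_keys & passing_keys
    true_positives = passing_keys & truth_keys
    recall = len(recovered) / len(expected_keys) if expected_keys else 1.0
    precision = len(true_positives) / len(passing_keys) if passing_keys else 1.0
    return {
        "recall": recall,
        "precision": precision,
        "n_expected": len(expected_keys),
        "n_passing": len(passing_keys),
        "false_negatives": sorted(expected_keys - passing_keys),
        "false_positives": sorted(passing_keys - truth_keys),
    }


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_repeatmasker_out(elements: Iterable[RepeatElement], path: str | Path) -> None:
    """Write annotations in the RepeatMasker ``.out`` column layout."""
    header = (
        "   SW   perc perc perc  query      position in query           matching"
        "       repeat              position in repeat\n"
        "score   div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, e in enumerate(elements, start=1):
            strand = "+" if e.strand == "+" else "C"
            fh.write(
                f"  225    0.0  0.0  0.0  {e.chrom} {e.start + 1} {e.end} "
                f"(0) {strand} {e.name or 'synthetic'} {e.family} 1 {e.length} (0) {i}\n"
            )


def write_regions_bed(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{r.category}\n")


def write_truth_tsv(truths: Iterable[TruthRecord], path: str | Path) -> None:
    rows = []
    for t in truths:
        rows.append(
            {
                "region_id": t.region_id,
                "chrom": t.elementA.chrom,
                "start_a": t.elementA.start,
                "end_a": t.elementA.end,
                "strand_a": t.elementA.strand,
                "start_b": t.elementB.start,
                "end_b": t.elementB.end,
                "strand_b": t.elementB.strand,
                "realized_identity": t.realized_identity,
                "spacer_bp": t.spacer_bp,
                "expected_pass": t.expected_pass,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    truths = []
    for row in df.itertuples(index=False):
        truths.append(
            TruthRecord(
                region_id=str(row.region_id),
                elementA=RepeatElement(
                    GenomicInterval(row.chrom, int(row.start_a), int(row.end_a), row.strand_a),
                    family="SINE/Alu",
                    name="Alu_synthA",
                ),
                elementB=RepeatElement(
                    GenomicInterval(row.chrom, int(row.start_b), int(row.end_b), row.strand_b),
                    family="SINE/Alu",
                    name="Alu_synthB",
                ),
                realized_identity=float(row.realized_identity),
                spacer_bp=int(row.spacer_bp),
                expected_pass=bool(row.expected_pass),
            )
        )
    return truths
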