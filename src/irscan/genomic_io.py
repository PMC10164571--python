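"""Readers and writers for the standard formats the pipeline touches.

All coordinates are 0-based half-open internally; conversion to and from the
1-based inclusive RepeatMasker dialect happens only inside the readers and
writers defined here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "RepeatElement",
    "Region",
    "FormatError",
    "read_fasta",
    "read_repeatmasker_out",
    "read_bed",
    "write_pairs_tsv",
    "read_pairs_tsv",
    "write_summary",
    "PAIR_TABLE_COLUMNS",
]

# IUPAC ambiguity codes collapse to N; anything else is rejected.
_AMBIGUITY = set("RYSWKMBDHVU")
_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Overlap by at least 1 bp (half-open semantics; strand ignored)."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class RepeatElement:
    """One annotated repeat occurrence: interval + strand + family + name."""

    interval: GenomicInterval
    family: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("repeat family must be non-empty")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class Region:
    """A scan region (e.g. one ssDNA/mutation-cluster interval); strand ignored."""

    interval: GenomicInterval
    region_id: str
    category: str = ""

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a mapping of name -> uppercase sequence.

    Record names are taken from the header up to the first whitespace.
    Sequences are uppercased; IUPAC ambiguity codes become ``N``. Characters
    outside the nucleotide alphabet, duplicate record names, a body before
    the first header, or an empty file raise :class:`FormatError` naming the
    offending line.
    """
    path = Path(path)
    # Light pre-scan for the errors SeqIO silently tolerates, with line numbers.
    seen: dict[str, int] = {}
    first_content_line = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if first_content_line is None:
                first_content_line = lineno
                if not stripped.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno}: expected FASTA header, got sequence data"
                    )
            if stripped.startswith(">"):
                name = stripped[1:].split()[0] if len(stripped) > 1 else ""
                if not name:
                    raise FormatError(f"{path}: line {lineno}: empty FASTA header")
                if name in seen:
                    raise FormatError(
                        f"{path}: line {lineno}: duplicate record name {name!r} "
                        f"(first seen on line {seen[name]})"
                    )
                seen[name] = lineno
    if first_content_line is None:
        raise FormatError(f"{path}: line 1: empty FASTA file")

    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        cleaned = []
        for ch in seq:
            if ch in _ALPHABET:
                cleaned.append(ch)
            elif ch in _AMBIGUITY:
                cleaned.append("N")
            else:
                raise FormatError(
                    f"{path}: record {record.id!r}: invalid sequence character {ch!r}"
                )
        genome[record.id] = "".join(cleaned)
    return genome


def read_repeatmasker_out(
    path: str | Path, families: Iterable[str] | None = None
) -> list[RepeatElement]:
    """Parse a RepeatMasker ``.out`` annotation file.

    The standard layout has three header lines followed by whitespace-delimited
    rows. Query coordinates are 1-based inclusive and are converted to 0-based
    half-open; the ``C`` strand symbol maps to ``-``. The repeat class/family
    column becomes :attr:`RepeatElement.family`.

    Parameters
    ----------
    families:
        Optional include-list of family labels; rows with other families are
        dropped. By default every family is kept, including simple repeats and
        low-complexity classes.
    """
    path = Path(path)
    keep = set(families) if families is not None else None
    elements: list[RepeatElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            # Header lines start with the column banner ("SW", "score") or
            # "bit" depending on RepeatMasker version.
            if fields[0] in ("SW", "score", "bit"):
                continue
            if len(fields) < 11:
                raise FormatError(
                    f"{path}: row {lineno}: expected >=11 columns, got {len(fields)}"
                )
            try:
                begin_1based = int(fields[5])
                end_1based = int(fields[6])
            except ValueError as exc:
                raise FormatError(f"{path}: row {lineno}: unparseable coordinates") from exc
            if begin_1based < 1 or end_1based < begin_1based:
                raise FormatError(
                    f"{path}: row {lineno}: negative or inverted coordinates "
                    f"({begin_1based}, {end_1based})"
                )
            strand_sym = fields[8]
            if strand_sym == "+":
                strand = "+"
            elif strand_sym in ("C", "-"):
                strand = "-"
            else:
                raise FormatError(f"{path}: row {lineno}: bad strand symbol {strand_sym!r}")
            family = fields[10]
            if keep is not None and family not in keep:
                continue
            elements.append(
                RepeatElement(
                    interval=GenomicInterval(
                        chrom=fields[4],
                        start=begin_1based - 1,
                        end=end_1based,
                        strand=strand,
                    ),
                    family=family,
                    name=fields[9],
                )
            )
    return elements


def read_bed(path: str | Path, as_elements: bool = False):
    """Read a BED3+ file of 0-based half-open intervals.

    Returns a list of :class:`Region` by default. With ``as_elements=True``
    a BED6 file is read as repeat annotations instead: the name column holds
    the family label, optionally as ``name|family``.

    ``region_id`` comes from column 4 when present, otherwise it is
    synthesized as ``chrom:start-end``.
    """
    path = Path(path)
    out: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split()
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: unparseable coordinates") from exc
            if start < 0 or end <= start:
                raise FormatError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) >= 4 else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) >= 6 else "+"
            if as_elements:
                if len(fields) < 6:
                    raise FormatError(
                        f"{path}: line {lineno}: BED6 required for element annotations"
                    )
                if "|" in name:
                    elem_name, family = name.split("|", 1)
                else:
                    elem_name, family = name, name
                out.append(
                    RepeatElement(
                        interval=GenomicInterval(chrom, start, end, strand),
                        family=family,
                        name=elem_name,
                    )
                )
            else:
                out.append(
                    Region(
                        interval=GenomicInterval(chrom, start, end),
                        region_id=name,
                        category=fields[4] if len(fields) >= 5 else "",
                    )
                )
    return out


PAIR_TABLE_COLUMNS = [
    "region_id",
    "family",
    "chrom_a",
    "start_a",
    "end_a",
    "strand_a",
    "length_a",
    "chrom_b",
    "start_b",
    "end_b",
    "strand_b",
    "length_b",
    "separation_bp",
    "orientation_class",
    "identity_fraction",
    "matched_length",
    "pass_filter",
]


def write_pairs_tsv(pairs, path: str | Path) -> None:
    """Write evaluated pairs (``IRPairResult`` objects) as a TSV table."""
    rows = []
    for p in pairs:
        c = p.candidate
        rows.append(
            {
                "region_id": c.region_id,
                "family": c.elementA.family,
                "chrom_a": c.elementA.chrom,
                "start_a": c.elementA.start,
                "end_a": c.elementA.end,
                "strand_a": c.elementA.strand,
                "length_a": c.elementA.length,
                "chrom_b": c.elementB.chrom,
                "start_b": c.elementB.start,
                "end_b": c.elementB.end,
                "strand_b": c.elementB.strand,
                "length_b": c.elementB.length,
                "separation_bp": c.separation_bp,
                "orientation_class": c.orientation_class,
                "identity_fraction": p.alignment.identity_fraction,
                "matched_length": p.alignment.matched_length,
                "pass_filter": bool(p.pass_filter),
            }
        )
    df = pd.DataFrame(rows, columns=PAIR_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: str | Path) -> pd.DataFrame:
    """Read back a pair table written by :func:`write_pairs_tsv`."""
    return pd.read_csv(path, sep="\t", dtype={"region_id": str})


def write_summary(report, path: str | Path) -> None:
    """Write a ``ScanReport`` as JSON."""
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=False)
        fh.write("\n")
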