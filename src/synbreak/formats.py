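"""Readers/writers for external file formats and the coordinate conventions.

All coordinates are 0-based half-open throughout the package.  BED input is
consumed natively; any 1-based dialect must be converted before it reaches
these readers.  Negative-orientation alignment anchors keep ``start < end``
on both genomes and carry the orientation as a separate flag, so interval
arithmetic is uniform everywhere.

Output tables are tab-separated with a commented header line naming the
columns and the tool version (self-describing, diff-friendly).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

# ASCII and typographic minus both denote reverse orientation in inputs.
_MINUS_TOKENS = {"-", "−"}
_PLUS_TOKENS = {"+"}

ANCHOR_COLUMNS = ("ref_seq", "ref_start", "ref_end", "tgt_seq", "tgt_start", "tgt_end", "orientation")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:[{self.start},{self.end}): need 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.seq_id, max(self.start, other.start), min(self.end, other.end)
        )

    def distance(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals on the same sequence (0 if they overlap)."""
        if self.seq_id != other.seq_id:
            raise ValueError("distance undefined across sequences")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.seq_id}:{self.start}-{self.end}"


@dataclass(frozen=True)
class AlignmentAnchor:
    """One local alignment match between reference and target intervals."""

    ref: GenomicInterval
    tgt: GenomicInterval
    orientation: str
    species: str

    def __post_init__(self) -> None:
        if self.orientation not in {"+", "-"}:
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")
        if not self.species:
            raise ValueError("species label must be non-empty")


@dataclass(frozen=True)
class Feature:
    """A BED feature: an interval plus an optional family/name label."""

    interval: GenomicInterval
    name: str = ""


@dataclass
class AssemblyIndex:
    species: str
    seq_lengths: dict[str, int]
    assembly_level: str = "scaffold"

    def __post_init__(self) -> None:
        if self.assembly_level not in {"chromosome", "scaffold"}:
            raise ValueError(f"unknown assembly_level {self.assembly_level!r}")
        for name, length in self.seq_lengths.items():
            if length <= 0:
                raise ValueError(f"sequence {name!r} has non-positive length {length}")


def _parse_orientation(token: str, lineno: int) -> str:
    if token in _PLUS_TOKENS:
        return "+"
    if token in _MINUS_TOKENS:
        return "-"
    raise ValueError(f"line {lineno}: unknown orientation token {token!r}")


def _data_lines(handle: TextIO) -> Iterable[tuple[int, list[str]]]:
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        yield lineno, line.split("\t")


def read_anchors(path: str | Path, species: str) -> list[AlignmentAnchor]:
    """Read 7-column tab-delimited alignment anchors (0-based half-open).

    Columns: ref_seq, ref_start, ref_end, tgt_seq, tgt_start, tgt_end,
    orientation.  Canonical layout for converted whole-genome-aligner output.
    """
    anchors: list[AlignmentAnchor] = []
    with open(path) as handle:
        for lineno, fields in _data_lines(handle):
            if len(fields) < 7:
                raise ValueError(f"line {lineno}: expected 7 columns, got {len(fields)}")
            try:
                rs, re_, ts, te = (int(fields[i]) for i in (1, 2, 4, 5))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate") from exc
            if re_ <= rs:
                raise ValueError(f"line {lineno}: ref_end <= ref_start ({rs}, {re_})")
            if te <= ts:
                raise ValueError(f"line {lineno}: tgt_end <= tgt_start ({ts}, {te})")
            orientation = _parse_orientation(fields[6], lineno)
            anchors.append(
                AlignmentAnchor(
                    ref=GenomicInterval(fields[0], rs, re_),
                    tgt=GenomicInterval(fields[3], ts, te),
                    orientation=orientation,
                    species=species,
                )
            )
    return anchors


def write_anchors(path: str | Path, anchors: Sequence[AlignmentAnchor]) -> None:
    with open(path, "w") as handle:
        write_header_comment(handle, ANCHOR_COLUMNS)
        for a in anchors:
            handle.write(
                f"{a.ref.seq_id}\t{a.ref.start}\t{a.ref.end}\t"
                f"{a.tgt.seq_id}\t{a.tgt.start}\t{a.tgt.end}\t{a.orientation}\n"
            )


def read_bed(path: str | Path) -> list[Feature]:
    """Read BED3/BED4 features (0-based half-open), preserving file order."""
    features: list[Feature] = []
    with open(path) as handle:
        for lineno, fields in _data_lines(handle):
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"line {lineno}: start >= end ({start}, {end})")
            name = fields[3] if len(fields) > 3 else ""
            features.append(Feature(GenomicInterval(fields[0], start, end), name))
    return features


def write_bed(path: str | Path, features: Sequence[Feature]) -> None:
    with open(path, "w") as handle:
        for f in features:
            iv = f.interval
            if f.name:
                handle.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{f.name}\n")
            else:
                handle.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a 2-column (name, length) TSV of sequence sizes."""
    sizes: dict[str, int] = {}
    with open(path) as handle:
        for lineno, fields in _data_lines(handle):
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected 2 columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer length") from exc
            if length <= 0:
                raise ValueError(f"line {lineno}: non-positive length {length}")
            if name in sizes:
                raise ValueError(f"line {lineno}: duplicate sequence name {name!r}")
            sizes[name] = length
    return sizes


def write_chrom_sizes(path: str | Path, sizes: dict[str, int]) -> None:
    with open(path, "w") as handle:
        for name, length in sizes.items():
            handle.write(f"{name}\t{length}\n")


def read_tree(path: str | Path):
    """Read a rooted Newick species tree; returns a :class:`synbreak.phylo.Phylogeny`."""
    from .phylo import Phylogeny

    return Phylogeny.from_newick_file(path)


def write_header_comment(handle: TextIO, columns: Sequence[str]) -> None:
    from . import __version__

    handle.write(f"# synbreak {__version__}\n")
    handle.write("# " + "\t".join(columns) + "\n")


def write_table(path: str | Path, columns: Sequence[str], rows: Iterable[Sequence]) -> None:
    """Write a commented-header TSV table."""
    with open(path, "w") as handle:
        write_header_comment(handle, columns)
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")
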