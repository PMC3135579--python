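"""Readers and writers for the genomic file formats the pipeline consumes.

All coordinates are normalised on ingest to a single internal convention:
0-based, half-open ``[start, end)`` intervals. BED and bedGraph already use
this convention and are adopted verbatim; fixed-step wiggle starts are
1-based and are shifted by one on ingest. Positions a coverage track does
not cover score 0, matching read-pileup semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .errors import DataError, ValidationError

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


class CoverageTrack:
    """Per-base, per-chromosome scores; uncovered positions score 0."""

    def __init__(self, arrays: dict[str, np.ndarray] | None = None):
        self._arrays: dict[str, np.ndarray] = {}
        if arrays:
            for chrom, values in arrays.items():
                self.set_chromosome(chrom, values)

    def set_chromosome(self, chrom: str, values: np.ndarray) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1:
            raise ValidationError("coverage values must be one-dimensional")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValidationError(
                f"coverage for {chrom} must be finite and non-negative"
            )
        self._arrays[chrom] = arr

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._arrays)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._arrays

    def get(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores over [start, end); positions outside coverage are 0.

        The query window may extend past either end of the stored array
        (or name an unknown chromosome): missing positions are zero-filled
        so windows near chromosome edges stay well-defined.
        """
        if end <= start:
            raise ValidationError(f"empty query window [{start}, {end})")
        out = np.zeros(end - start, dtype=float)
        arr = self._arrays.get(chrom)
        if arr is None:
            return out
        lo = max(start, 0)
        hi = min(end, arr.size)
        if lo < hi:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def interval_sum(self, interval: GenomicInterval) -> float:
        return float(self.get(interval.chrom, interval.start, interval.end).sum())


@dataclass
class GeneModel:
    """A gene as an ordered exon chain; introns are the inter-exon gaps."""

    name: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    introns: list[GenomicInterval] = field(init=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"gene {self.name} has no exons")
        exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValidationError(f"gene {self.name} has overlapping exons")
        self.exons = exons
        self.introns = [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(exons, exons[1:])
        ]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass(frozen=True)
class ExpressionRecord:
    """Mature-miRNA identifier with its deep-sequencing read count."""

    mirna_id: str
    level: float

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValidationError(
                f"negative expression level for {self.mirna_id}: {self.level}"
            )


class GenomeSequence:
    """Uppercased chromosome sequences with bounds-checked slicing."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs: dict[str, str] = {}
        for chrom, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise DataError(
                    f"sequence {chrom} contains invalid characters: {sorted(bad)}"
                )
            self._seqs[chrom] = seq

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or end <= start:
            raise ValidationError(
                f"interval [{start}, {end}) out of bounds for {chrom} "
                f"(length {len(seq)})"
            )
        return seq[start:end]

    def fetch_padded(self, chrom: str, start: int, end: int) -> str:
        """Like fetch but pads positions outside the chromosome with N."""
        if chrom not in self._seqs:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        lo, hi = max(start, 0), min(end, len(seq))
        core = seq[lo:hi] if lo < hi else ""
        return "N" * (lo - start) + core + "N" * (end - hi)


def read_bed(path) -> list[tuple[str, GenomicInterval]]:
    """Read BED3+ records as (name, interval) pairs.

    Column 4 provides the name (empty string if absent) and column 6 the
    strand (``.`` if absent). Coordinates are adopted verbatim.
    """
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}: line {lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise DataError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start or start < 0:
                raise ValidationError(
                    f"{path}: line {lineno}: invalid coordinates {start}-{end}"
                )
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            records.append((name, GenomicInterval(chrom, start, end, strand)))
    return records


def write_bed(path, records: list[tuple[str, GenomicInterval]]) -> None:
    """Write (name, interval) pairs as BED6 (score column fixed at 0)."""
    with open(path, "w") as handle:
        for name, iv in records:
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


def read_gene_models(path) -> list[GeneModel]:
    """Read a refGene-flavor tab-delimited table into gene models.

    Requires a header line naming at least ``name``, ``chrom``, ``strand``,
    ``exonCount``, ``exonStarts`` and ``exonEnds``; any other columns are
    ignored. Exon starts/ends are comma-separated lists, as exported by the
    UCSC table browser.
    """
    genes = []
    with open(path) as handle:
        header_line = handle.readline()
        if not header_line:
            return genes
        header = header_line.lstrip("#").rstrip("\n").split("\t")
        required = ["name", "chrom", "strand", "exonCount", "exonStarts", "exonEnds"]
        missing = [c for c in required if c not in header]
        if missing:
            raise DataError(f"{path}: missing required columns {missing}")
        idx = {c: header.index(c) for c in required}
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            starts = [int(s) for s in fields[idx["exonStarts"]].split(",") if s]
            ends = [int(s) for s in fields[idx["exonEnds"]].split(",") if s]
            if len(starts) != len(ends):
                raise ValidationError(
                    f"{path}: line {lineno}: exonStarts/exonEnds length mismatch"
                )
            n_declared = int(fields[idx["exonCount"]])
            if n_declared != len(starts):
                raise ValidationError(
                    f"{path}: line {lineno}: exonCount {n_declared} != "
                    f"{len(starts)} exons listed"
                )
            chrom = fields[idx["chrom"]]
            strand = fields[idx["strand"]]
            exons = [
                GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends)
            ]
            genes.append(GeneModel(fields[idx["name"]], chrom, strand, exons))
    return genes


def _finalize_track(chunks: dict[str, list[tuple[int, int, float]]]) -> CoverageTrack:
    track = CoverageTrack()
    for chrom, spans in chunks.items():
        size = max(end for _, end, _ in spans)
        arr = np.zeros(size, dtype=float)
        covered = np.zeros(size, dtype=bool)
        warned = False
        for start, end, value in spans:
            if not warned and covered[start:end].any():
                logger.warning(
                    "overlapping coverage records on %s: last writer wins", chrom
                )
                warned = True
            arr[start:end] = value
            covered[start:end] = True
        track.set_chromosome(chrom, arr)
    return track


def read_coverage(path, format: str = "bedgraph") -> CoverageTrack:
    """Read a bedGraph or fixed-step wiggle file into a per-base track.

    Interval/step scores are expanded to one value per base. Overlapping
    bedGraph records resolve last-writer-wins with a logged warning.
    """
    fmt = format.lower()
    if fmt not in ("bedgraph", "wig", "wiggle", "fixedstep"):
        raise ValidationError(f"unknown coverage format {format!r}")
    chunks: dict[str, list[tuple[int, int, float]]] = {}

    def add(chrom: str, start: int, end: int, value: float, lineno: int) -> None:
        if end <= start or start < 0:
            raise ValidationError(
                f"{path}: line {lineno}: invalid span [{start}, {end})"
            )
        if not np.isfinite(value) or value < 0:
            raise ValidationError(
                f"{path}: line {lineno}: score must be finite and non-negative"
            )
        chunks.setdefault(chrom, []).append((start, end, value))

    with open(path) as handle:
        if fmt == "bedgraph":
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise DataError(
                        f"{path}: line {lineno}: expected 4 bedGraph columns"
                    )
                add(fields[0], int(fields[1]), int(fields[2]), float(fields[3]), lineno)
        else:
            chrom, pos, step, span = None, 0, 1, 1
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                if line.startswith("fixedStep"):
                    params = dict(
                        kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
                    )
                    try:
                        chrom = params["chrom"]
                        pos = int(params["start"]) - 1  # wiggle is 1-based
                    except KeyError as exc:
                        raise DataError(
                            f"{path}: line {lineno}: fixedStep needs chrom and start"
                        ) from exc
                    step = int(params.get("step", 1))
                    span = int(params.get("span", 1))
                    continue
                if chrom is None:
                    raise DataError(
                        f"{path}: line {lineno}: data before fixedStep header"
                    )
                add(chrom, pos, pos + span, float(line), lineno)
                pos += step
    return _finalize_track(chunks)


def write_bedgraph(path, track: CoverageTrack) -> None:
    """Write a track as bedGraph, run-length-merging equal adjacent scores."""
    with open(path, "w") as handle:
        for chrom in track.chromosomes:
            arr = track.get(chrom, 0, len(track._arrays[chrom]))
            if arr.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [arr.size]))
            for s, e in zip(starts, ends):
                if arr[s] != 0:
                    handle.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.6g}\n")


def read_fasta(path) -> GenomeSequence:
    """Load a FASTA file into an in-memory, validated sequence store."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise DataError(f"{path}: no FASTA records found")
    return GenomeSequence(seqs)


def write_fasta(path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as handle:
        for chrom in sorted(sequences):
            handle.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_expression_table(path) -> list[ExpressionRecord]:
    """Read a two-column TSV of miRNA id and read count (header optional)."""
    records: list[ExpressionRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataError(f"{path}: line {lineno}: expected 2 columns")
            try:
                level = float(fields[1])
            except ValueError:
                if lineno == 1:  # tolerated header row
                    continue
                raise DataError(
                    f"{path}: line {lineno}: non-numeric expression level"
                ) from None
            if fields[0] in seen:
                raise DataError(f"{path}: duplicate miRNA id {fields[0]!r}")
            seen.add(fields[0])
            records.append(ExpressionRecord(fields[0], level))
    return records
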