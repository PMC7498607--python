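"""Readers and writers for the formats every other module consumes.

All in-memory coordinates are 0-based half-open; 1-based inclusive
coordinates (FASTA/GFF3 convention) exist only at file boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

#: GFF3 feature types retained by :func:`read_gff3`.
FEATURE_TYPES = frozenset(
    {"gene", "mRNA", "CDS", "five_prime_UTR", "three_prime_UTR", "exon", "intron"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """One uppercased DNA sequence from a genome assembly."""

    seq_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureRecord:
    """One genome annotation feature, stored 0-based half-open."""

    seq_id: str
    type: str
    start: int
    end: int
    strand: str

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end


@dataclass
class GenotypeTable:
    """Diploid fragment-size genotypes for individuals x loci.

    ``calls[(individual, locus)]`` is a sorted pair of allele sizes in bp,
    or ``None`` for missing data (always explicit, never dropped).
    """

    individuals: list[str]
    loci: list[str]
    calls: dict[tuple[str, str], tuple[int, int] | None] = field(default_factory=dict)

    def get(self, individual: str, locus: str) -> tuple[int, int] | None:
        return self.calls[(individual, locus)]

    def allele_counts(self, locus: str) -> dict[int, int]:
        """Allele counts over non-missing diploid calls at one locus."""
        counts: dict[int, int] = {}
        for ind in self.individuals:
            call = self.calls[(ind, locus)]
            if call is None:
                continue
            for allele in call:
                counts[allele] = counts.get(allele, 0) + 1
        return counts

    def subset_loci(self, loci: list[str]) -> "GenotypeTable":
        """Table restricted to (a resampling of) ``loci``.

        Duplicate locus names are allowed (bootstrap resampling); duplicates
        are disambiguated with a suffix so column names stay unique.
        """
        new_loci = []
        calls: dict[tuple[str, str], tuple[int, int] | None] = {}
        seen: dict[str, int] = {}
        for loc in loci:
            n = seen.get(loc, 0)
            seen[loc] = n + 1
            name = loc if n == 0 else f"{loc}.{n}"
            new_loci.append(name)
            for ind in self.individuals:
                calls[(ind, name)] = self.calls[(ind, loc)]
        return GenotypeTable(list(self.individuals), new_loci, calls)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file.

    Sequences are uppercased; multi-line sequences are concatenated; record
    order is preserved. Duplicate ids, an empty file, or characters outside
    {A,C,G,T,N} are hard errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = next((i for i, c in enumerate(seq) if c not in VALID_BASES), None)
        if bad is not None:
            raise ValueError(
                f"invalid character {seq[bad]!r} at position {bad + 1} "
                f"of sequence {rec.id!r}"
            )
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def genome_index(records: list[SequenceRecord]) -> dict[str, SequenceRecord]:
    return {r.seq_id: r for r in records}


def read_gff3(path: str | Path) -> list[FeatureRecord]:
    """Read GFF3, keeping only the feature types in :data:`FEATURE_TYPES`.

    Coordinates are converted from 1-based inclusive to the internal
    0-based half-open convention. Unknown feature types are skipped (count
    logged); start > end is a hard error.
    """
    features: list[FeatureRecord] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seq_id, _, ftype, start, end, _, strand, _, _ = cols
            if ftype not in FEATURE_TYPES:
                skipped += 1
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ValueError(f"{path}:{lineno}: start {start_i} > end {end_i}")
            features.append(FeatureRecord(seq_id, ftype, start_i - 1, end_i, strand))
    if skipped:
        logger.info("read_gff3: skipped %d lines with unhandled feature types", skipped)
    return features


def write_gff3(features: list[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features):
            fh.write(
                f"{f.seq_id}\t.\t{f.type}\t{f.start_1based}\t{f.end_1based}"
                f"\t.\t{f.strand}\t.\tID=f{i}\n"
            )


def _parse_call(cell: str, missing: str, row: int, col: int) -> tuple[int, int] | None:
    if cell == missing:
        return None
    parts = cell.split("/")
    if len(parts) == 1:
        parts = [parts[0], parts[0]]
    if len(parts) != 2:
        raise ValueError(f"malformed genotype cell {cell!r} at row {row}, column {col}")
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError:
        raise ValueError(
            f"non-integer allele size in cell {cell!r} at row {row}, column {col}"
        ) from None
    if a <= 0 or b <= 0:
        raise ValueError(f"non-positive allele size at row {row}, column {col}")
    return (a, b) if a <= b else (b, a)


def read_genotypes(path: str | Path, missing: str = "-") -> GenotypeTable:
    """Read a tab-separated genotype table.

    Layout: header row ``sample<TAB>locus1<TAB>...``; one row per
    individual; cells ``a/b`` (allele sizes in bp), ``a`` for a homozygote,
    or the missing code (default ``-``).
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty genotype table {path}")
    header = lines[0].split("\t")
    loci = header[1:]
    individuals: list[str] = []
    calls: dict[tuple[str, str], tuple[int, int] | None] = {}
    for row, line in enumerate(lines[1:], 2):
        cols = line.split("\t")
        if len(cols) != len(header):
            raise ValueError(
                f"{path}: row {row} has {len(cols)} columns, expected {len(header)}"
            )
        ind = cols[0]
        individuals.append(ind)
        for col, (locus, cell) in enumerate(zip(loci, cols[1:]), 2):
            calls[(ind, locus)] = _parse_call(cell, missing, row, col)
    return GenotypeTable(individuals, loci, calls)


def write_genotypes(gt: GenotypeTable, path: str | Path, missing: str = "-") -> None:
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(gt.loci) + "\n")
        for ind in gt.individuals:
            cells = []
            for locus in gt.loci:
                call = gt.calls[(ind, locus)]
                cells.append(missing if call is None else f"{call[0]}/{call[1]}")
            fh.write(ind + "\t" + "\t".join(cells) + "\n")
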