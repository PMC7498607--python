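"""End-to-end microsatellite-marker construction.

Stages: scan a source genome for SSRs, design up to three ranked primer
pairs per locus, drop redundant markers (duplicate primer pairs and
non-specific multi-hit markers), collapse identical primer pairs across
genomes into a non-redundant marker set, call cross-taxa transferability
and length polymorphism from an e-PCR matrix (>= 6 bp size variation =>
polymorphic), map transferable markers onto a chromosome-level assembly,
and export the marker table to TSV and SQLite.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genomic_context import GenomicContext, classify_with_fallback
from .insilico_pcr import Amplicon, EPCRConfig, amplify, epcr_matrix
from .io_core import FeatureRecord, SequenceRecord
from .primer_design import DesignConfig, FlankedLocus, PrimerPair, design_for_locus, extract_flanks
from .repeat_scan import RepeatLocus, ScanConfig, join_compound, scan_genome

#: minimum amplicon size difference (bp) for a polymorphism call
POLYMORPHISM_MIN_DIFF = 6


@dataclass
class MarkerRecord:
    """One microsatellite marker and everything known about it."""

    marker_id: str
    source_genome: str
    locus: RepeatLocus
    primer_pairs: tuple[PrimerPair, ...]
    flanks: FlankedLocus
    context: GenomicContext | None = None
    source_genomes: tuple[str, ...] = ()
    amplicons: dict[str, list[Amplicon]] = field(default_factory=dict)
    transferable_to: frozenset[str] = frozenset()
    polymorphic: bool | None = None

    @property
    def expected_size(self) -> int:
        return self.primer_pairs[0].product_size

    @property
    def primer_key(self) -> tuple[str, str]:
        return (self.primer_pairs[0].forward, self.primer_pairs[0].reverse)


@dataclass(frozen=True)
class TransferPolymorphismCall:
    marker_id: str
    taxa_present: frozenset[str]
    polymorphic: bool
    size_range: tuple[int, int]


@dataclass
class DesignReport:
    markers: list[MarkerRecord]
    n_loci: int
    n_success: int

    @property
    def success_rate_pct(self) -> float:
        return 100.0 * self.n_success / self.n_loci if self.n_loci else 0.0


def build_markers(
    genome_name: str,
    records: list[SequenceRecord],
    scan_cfg: ScanConfig | None = None,
    design_cfg: DesignConfig | None = None,
    flank_size: int = 200,
    features: list[FeatureRecord] | None = None,
    join_compounds: bool = True,
) -> DesignReport:
    """Scan one genome and design markers for every SSR locus.

    Marker ids are ``EMM-<genome>-<serial>`` with serials assigned in
    (seq_id, start) order, so the numbering is reproducible.
    """
    scan_cfg = scan_cfg or ScanConfig()
    design_cfg = design_cfg or DesignConfig()
    loci = scan_genome(records, scan_cfg)
    if join_compounds:
        loci = join_compound(loci, scan_cfg)
    loci.sort(key=lambda l: (l.seq_id, l.start))
    markers: list[MarkerRecord] = []
    serial = 0
    for locus in loci:
        fl = extract_flanks(locus, records, flank_size)
        pairs = design_for_locus(fl, design_cfg)
        if not pairs:
            continue
        serial += 1
        ctx = classify_with_fallback(fl, features)
        markers.append(
            MarkerRecord(
                marker_id=f"EMM-{genome_name}-{serial:05d}",
                source_genome=genome_name,
                locus=locus,
                primer_pairs=tuple(pairs),
                flanks=fl,
                context=ctx,
                source_genomes=(genome_name,),
            )
        )
    return DesignReport(markers=markers, n_loci=len(loci), n_success=len(markers))


def filter_redundant(
    markers: list[MarkerRecord],
    genome: list[SequenceRecord],
    cfg: EPCRConfig | None = None,
    drop_duplicates: bool = True,
    drop_multihit: bool = True,
) -> tuple[list[MarkerRecord], float]:
    """Remove redundant markers from a single genome's set.

    (i) exact duplicate (forward, reverse) primer pairs: the first by locus
    coordinate is kept; (ii) non-specific markers whose rank-1 pair yields
    more than one amplicon in their own source genome are removed.
    Returns (kept, removed percentage of the input).
    """
    cfg = cfg or EPCRConfig()
    n_input = len(markers)
    kept = sorted(markers, key=lambda m: (m.locus.seq_id, m.locus.start))
    if drop_duplicates:
        seen: set[tuple[str, str]] = set()
        uniq = []
        for m in kept:
            if m.primer_key in seen:
                continue
            seen.add(m.primer_key)
            uniq.append(m)
        kept = uniq
    if drop_multihit:
        kept = [m for m in kept if len(amplify(m.primer_pairs[0], genome, cfg)) == 1]
    kept.sort(key=lambda m: m.marker_id)
    removed_pct = 100.0 * (n_input - len(kept)) / n_input if n_input else 0.0
    return kept, removed_pct


def cluster_across_genomes(
    per_genome_markers: dict[str, list[MarkerRecord]],
) -> tuple[list[MarkerRecord], dict[frozenset[str], int]]:
    """Collapse identical (forward, reverse) primer pairs across genomes.

    The surviving record comes from the alphabetically first source genome
    and lists every source in ``source_genomes``. Also returns Venn-style
    membership counts keyed by the genome subset."""
    by_key: dict[tuple[str, str], list[MarkerRecord]] = {}
    for genome in sorted(per_genome_markers):
        for m in per_genome_markers[genome]:
            by_key.setdefault(m.primer_key, []).append(m)
    merged: list[MarkerRecord] = []
    venn: dict[frozenset[str], int] = {}
    for key in by_key:
        group = by_key[key]
        sources = tuple(sorted({m.source_genome for m in group}))
        rep = replace(group[0], source_genomes=sources)
        merged.append(rep)
        cell = frozenset(sources)
        venn[cell] = venn.get(cell, 0) + 1
    merged.sort(key=lambda m: m.marker_id)
    return merged, venn


def call_transfer_polymorphism(
    matrix: dict[tuple[str, str], list[Amplicon]],
    expected_sizes: dict[str, int],
) -> list[TransferPolymorphismCall]:
    """Per-marker presence and length-polymorphism calls.

    A marker is polymorphic when some pair of observed amplicon lengths -
    the source genome's expected size included - differs by at least
    6 bp."""
    marker_ids = sorted({mk for mk, _ in matrix})
    calls = []
    for marker_id in marker_ids:
        taxa = sorted({tx for (mk, tx) in matrix if mk == marker_id})
        present = frozenset(
            tx for tx in taxa if matrix[(marker_id, tx)]
        )
        sizes = [a.length for tx in taxa for a in matrix[(marker_id, tx)]]
        if marker_id in expected_sizes:
            sizes.append(expected_sizes[marker_id])
        lo, hi = (min(sizes), max(sizes)) if sizes else (0, 0)
        calls.append(
            TransferPolymorphismCall(
                marker_id=marker_id,
                taxa_present=present,
                polymorphic=bool(sizes) and (hi - lo) >= POLYMORPHISM_MIN_DIFF,
                size_range=(lo, hi),
            )
        )
    return calls


def transferable_to_clade(
    call: TransferPolymorphismCall, clade: set[str] | frozenset[str]
) -> bool:
    """Present in every member of the clade."""
    return bool(clade) and set(clade) <= set(call.taxa_present)


@dataclass
class ComparativeMap:
    counts: dict[str, int]
    unplaced: int
    mean: float
    std: float


def comparative_map(
    matrix: dict[tuple[str, str], list[Amplicon]], taxon: str
) -> ComparativeMap:
    """Assign each marker with a unique amplicon in ``taxon`` to its
    chromosome; markers with several hits are flagged unplaced. The mean
    and (population) standard deviation are across chromosomes."""
    counts: dict[str, int] = {}
    unplaced = 0
    for (marker_id, tx), amps in matrix.items():
        if tx != taxon or not amps:
            continue
        if len(amps) == 1:
            chrom = amps[0].seq_id
            counts[chrom] = counts.get(chrom, 0) + 1
        else:
            unplaced += 1
    values = list(counts.values())
    mean = float(np.mean(values)) if values else 0.0
    std = float(np.std(values)) if values else 0.0
    return ComparativeMap(counts=dict(sorted(counts.items())), unplaced=unplaced, mean=mean, std=std)


EMM_COLUMNS = (
    ["marker_id", "source_genome", "seq_id", "start_1based", "end_1based",
     "ssr_type", "motif", "canonical_motif", "class", "composition", "context"]
    + [f"forward_{i}" for i in (1, 2, 3)]
    + [f"reverse_{i}" for i in (1, 2, 3)]
    + [f"tm_{i}" for i in (1, 2, 3)]
    + [f"product_size_{i}" for i in (1, 2, 3)]
    + ["transferable_taxa", "polymorphic", "left_flank", "right_flank"]
)


def _marker_row(m: MarkerRecord) -> list[str]:
    pads = list(m.primer_pairs) + [None] * (3 - len(m.primer_pairs))
    fw = [p.forward if p else "" for p in pads]
    rv = [p.reverse if p else "" for p in pads]
    # annealing temperature of a pair: the limiting (lower) primer Tm
    tm = [f"{min(p.tm_f, p.tm_r):.2f}" if p else "" for p in pads]
    ps = [str(p.product_size) if p else "" for p in pads]
    return (
        [
            m.marker_id,
            m.source_genome,
            m.locus.seq_id,
            str(m.locus.start + 1),
            str(m.locus.end),
            m.locus.ssr_type,
            m.locus.motif,
            m.locus.canonical_motif,
            m.locus.length_class,
            m.locus.composition_class,
            m.context.region if m.context else "",
        ]
        + fw
        + rv
        + tm
        + ps
        + [
            ";".join(sorted(m.transferable_to)),
            "" if m.polymorphic is None else str(int(m.polymorphic)),
            m.flanks.left_flank,
            m.flanks.right_flank,
        ]
    )


def export_emm(
    markers: list[MarkerRecord],
    tsv_path: str | Path,
    sqlite_path: str | Path | None = None,
) -> None:
    """Write the marker table (TSV, fixed column order) and optionally a
    SQLite database with one ``markers`` table of the same columns."""
    rows = [_marker_row(m) for m in sorted(markers, key=lambda m: m.marker_id)]
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(EMM_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    if sqlite_path is not None:
        con = sqlite3.connect(str(sqlite_path))
        try:
            cols_sql = ", ".join(f'"{c}" TEXT' for c in EMM_COLUMNS)
            con.execute("DROP TABLE IF EXISTS markers")
            con.execute(f"CREATE TABLE markers ({cols_sql})")
            placeholders = ", ".join("?" for _ in EMM_COLUMNS)
            con.executemany(f"INSERT INTO markers VALUES ({placeholders})", rows)
            con.commit()
        finally:
            con.close()


def query_markers(
    sqlite_path: str | Path,
    ssr_type: str | None = None,
    length_class: str | None = None,
    transferable_to: str | None = None,
    polymorphic: bool | None = None,
    marker_id: str | None = None,
) -> list[dict[str, str]]:
    """Filter the exported SQLite marker table on the searchable fields."""
    clauses, params = [], []
    if ssr_type is not None:
        clauses.append('"ssr_type" = ?')
        params.append(ssr_type)
    if length_class is not None:
        clauses.append('"class" = ?')
        params.append(length_class)
    if polymorphic is not None:
        clauses.append('"polymorphic" = ?')
        params.append(str(int(polymorphic)))
    if marker_id is not None:
        clauses.append('"marker_id" = ?')
        params.append(marker_id)
    if transferable_to is not None:
        clauses.append(
            '(";" || "transferable_taxa" || ";") LIKE ?'
        )
        params.append(f"%;{transferable_to};%")
    sql = "SELECT * FROM markers"
    if clauses:
        sql += " WHERE " + " AND ".join(clauses)
    sql += ' ORDER BY "marker_id"'
    con = sqlite3.connect(str(sqlite_path))
    try:
        con.row_factory = sqlite3.Row
        return [dict(r) for r in con.execute(sql, params)]
    finally:
        con.close()


@dataclass
class PipelineResult:
    per_genome_reports: dict[str, DesignReport]
    redundancy_pct: dict[str, float]
    markers: list[MarkerRecord]
    venn: dict[frozenset[str], int]
    matrix: dict[tuple[str, str], list[Amplicon]]
    calls: list[TransferPolymorphismCall]


def run_pipeline(
    source_genomes: dict[str, list[SequenceRecord]],
    extra_taxa: dict[str, list[SequenceRecord]] | None = None,
    features: dict[str, list[FeatureRecord]] | None = None,
    scan_cfg: ScanConfig | None = None,
    design_cfg: DesignConfig | None = None,
    epcr_cfg: EPCRConfig | None = None,
    flank_size: int = 200,
) -> PipelineResult:
    """Run scan -> design -> dedupe -> cluster -> e-PCR -> call end to end.

    ``source_genomes`` get markers designed; ``extra_taxa`` only serve as
    e-PCR targets. Deterministic on identical inputs."""
    scan_cfg = scan_cfg or ScanConfig()
    design_cfg = design_cfg or DesignConfig()
    epcr_cfg = epcr_cfg or EPCRConfig()
    reports: dict[str, DesignReport] = {}
    per_genome: dict[str, list[MarkerRecord]] = {}
    redundancy: dict[str, float] = {}
    for genome in sorted(source_genomes):
        report = build_markers(
            genome,
            source_genomes[genome],
            scan_cfg,
            design_cfg,
            flank_size,
            features.get(genome) if features else None,
        )
        reports[genome] = report
        kept, pct = filter_redundant(report.markers, source_genomes[genome], epcr_cfg)
        per_genome[genome] = kept
        redundancy[genome] = pct
    markers, venn = cluster_across_genomes(per_genome)
    all_taxa = dict(source_genomes)
    if extra_taxa:
        all_taxa.update(extra_taxa)
    matrix = epcr_matrix(markers, all_taxa, epcr_cfg)
    expected = {m.marker_id: m.expected_size for m in markers}
    calls = call_transfer_polymorphism(matrix, expected)
    by_id = {c.marker_id: c for c in calls}
    annotated = []
    for m in markers:
        c = by_id[m.marker_id]
        annotated.append(
            replace(m, transferable_to=c.taxa_present, polymorphic=c.polymorphic)
        )
    return PipelineResult(
        per_genome_reports=reports,
        redundancy_pct=redundancy,
        markers=annotated,
        venn=venn,
        matrix=matrix,
        calls=calls,
    )
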