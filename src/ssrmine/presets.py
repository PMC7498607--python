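"""Ready-made synthetic study panels.

``four_landraces`` emulates the study layout: four clonally related
landrace assemblies of the focal species (one of which is annotated), a
diverged chromosome-level outgroup genome in the same family, and a
two-group diploid marker assay. Every planted SSR, edit and generating
allele frequency is recorded in the manifest, so scanner output, the
e-PCR matrix, polymorphism calls and diversity estimates are all exactly
predictable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .io_core import (
    FeatureRecord,
    SequenceRecord,
    write_fasta,
    write_genotypes,
    write_gff3,
)
from .marker_pipeline import MarkerRecord, build_markers
from .primer_design import DesignConfig
from .repeat_scan import ScanConfig
from .simulate import (
    PlantManifest,
    PrimerSiteEdit,
    SSRPlant,
    TractEdit,
    duplicate_cassette,
    make_genome,
    make_genotypes,
    make_landraces,
)

BASE_GENOME = "landrace_a"
LANDRACES = ("landrace_a", "landrace_b", "landrace_c", "landrace_d")
OUTGROUP = "musa_like"


@dataclass
class FixtureSet:
    genomes: dict[str, list[SequenceRecord]]
    features: dict[str, list[FeatureRecord]]
    genotypes: object
    groups: dict[str, list[str]]
    manifest: PlantManifest
    base_markers: list[MarkerRecord] = field(default_factory=list)

    @property
    def landrace_genomes(self) -> dict[str, list[SequenceRecord]]:
        return {k: v for k, v in self.genomes.items() if k != OUTGROUP}

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, records in self.genomes.items():
            write_fasta(records, out / f"{name}.fa")
        for name, feats in self.features.items():
            write_gff3(feats, out / f"{name}.gff3")
        write_genotypes(self.genotypes, out / "genotypes.tsv")
        with open(out / "groups.tsv", "w") as fh:
            for group, members in sorted(self.groups.items()):
                for m in members:
                    fh.write(f"{m}\t{group}\n")
        self.manifest.to_json(out / "manifest.json")


def _plants(small: bool) -> list[SSRPlant]:
    spec = [
        # contig 1 (annotated): positions coordinate with the GFF3 below
        ("P01", 0, 600, "A", 14),
        ("P02", 0, 1400, "AG", 12),
        ("P03", 0, 2200, "AT", 9),   # duplicated elsewhere -> multi-hit
        ("P04", 0, 3000, "AC", 11),
        ("P05", 0, 3800, "AAT", 8),
        ("P06", 0, 4600, "ATC", 6),
        ("P07", 0, 5400, "AAG", 7),
        ("P08", 0, 6200, "CCG", 5),
        ("P09", 0, 7000, "AAAT", 6),
        # contig 2
        ("P10", 1, 600, "ACAT", 5),
        ("P11", 1, 1400, "AATAT", 4),
        ("P12", 1, 2200, "AATGGC", 4),
        ("P13", 1, 3000, "AG", 8),
        ("P14", 1, 3800, "AAT", 5),
    ]
    if small:
        spec = [s for s in spec if s[0] in ("P01", "P02", "P04", "P05", "P07", "P09")]
        spec = [(pid, 0, pos, m, c) for (pid, _, pos, m, c) in spec]
    return [SSRPlant(pid, ci, pos, motif, count) for pid, ci, pos, motif, count in spec]


def _annotation() -> list[FeatureRecord]:
    # one + strand gene on contig1 covering P01 (5'UTR), P02/P04/P05 (CDS),
    # P03 (intron) and P06 (3'UTR); everything else is intergenic
    return [
        FeatureRecord("contig1", "gene", 550, 4750, "+"),
        FeatureRecord("contig1", "mRNA", 550, 4750, "+"),
        FeatureRecord("contig1", "exon", 550, 1600, "+"),
        FeatureRecord("contig1", "five_prime_UTR", 550, 700, "+"),
        FeatureRecord("contig1", "CDS", 700, 1600, "+"),
        FeatureRecord("contig1", "exon", 2900, 4750, "+"),
        FeatureRecord("contig1", "CDS", 2900, 4300, "+"),
        FeatureRecord("contig1", "three_prime_UTR", 4300, 4750, "+"),
    ]


def _footprint(marker: MarkerRecord, which: str) -> tuple[int, int, int]:
    """(contig_index, start, end) of a primer binding site on the source
    genome; contig index derived from the 'contigN' naming."""
    pair = marker.primer_pairs[0]
    t0 = marker.flanks.template_start
    if which == "forward":
        a, b = t0 + pair.forward_start, t0 + pair.forward_start + len(pair.forward)
    else:
        a, b = t0 + pair.reverse_end - len(pair.reverse), t0 + pair.reverse_end
    ci = int(marker.locus.seq_id.removeprefix("contig")) - 1
    return ci, a, b


def four_landraces(seed: int = 42, small: bool = False) -> FixtureSet:
    """Build the four-landraces-plus-outgroup panel.

    ``small=True`` shrinks the panel (one contig, six plants, two derived
    landraces, no duplicated cassette) for fast smoke/property runs; the
    default is the full panel.
    """
    scan_cfg = ScanConfig()
    design_cfg = DesignConfig()
    n_contigs = 1 if small else 2
    contig_len = 9000 if small else 15000
    plants = _plants(small)
    base, manifest = make_genome(n_contigs, contig_len, plants, seed, scan_cfg)
    if not small:
        base = duplicate_cassette(base, manifest, "P03", 1, 9000)

    report = build_markers(BASE_GENOME, base, scan_cfg, design_cfg)
    by_plant: dict[str, MarkerRecord] = {}
    for m in report.markers:
        for p in plants:
            if m.locus.seq_id == f"contig{p.contig + 1}" and m.locus.start == p.position:
                by_plant[p.plant_id] = m

    def site_edit(pid: str, which: str, n: int) -> PrimerSiteEdit:
        # substitutions concentrated over the primer's 3' end (the exact
        # e-PCR seed), where a semi-global gapped alignment cannot absorb
        # them; the 5' half is rescuable by design
        ci, a, b = _footprint(by_plant[pid], which)
        if which == "forward":
            a = b - 12  # 3' end at the right edge of the footprint
        else:
            b = a + 12  # reverse primer: 3' end at the left edge
        return PrimerSiteEdit(pid, ci, a, b, n)

    edits: dict[str, list] = {
        "landrace_b": [
            TractEdit("P02", +3),   # +6 bp: polymorphic
            TractEdit("P05", -2),   # -6 bp: polymorphic
            TractEdit("P04", +2),   # +4 bp: below the 6 bp rule
        ],
        "landrace_c": [
            TractEdit("P02", +5),
            TractEdit("P09", +2),   # +8 bp
        ],
        "landrace_d": [
            TractEdit("P05", +1),   # +3 bp: below the 6 bp rule
        ],
    }
    if "P07" in by_plant:
        edits["landrace_b"].append(site_edit("P07", "forward", 5))
    if not small:
        if "P08" in by_plant:
            edits["landrace_c"].append(site_edit("P08", "forward", 5))
        edits["landrace_d"].append(TractEdit("P06", +3))
        if "P12" in by_plant:
            edits["landrace_d"].append(site_edit("P12", "reverse", 5))
    # outgroup: most primer sites destroyed, surviving tracts shifted
    out_edits: list = []
    transferable_to_outgroup = {"P02", "P05", "P09"} & set(by_plant)
    for pid, marker in sorted(by_plant.items()):
        if pid in transferable_to_outgroup:
            out_edits.append(TractEdit(pid, +3 if pid != "P05" else -3))
        elif pid == "P03":
            continue  # duplicated cassette: leave as is
        else:
            out_edits.append(site_edit(pid, "forward", 5))
            out_edits.append(site_edit(pid, "reverse", 5))
    edits[OUTGROUP] = out_edits

    derived = make_landraces(base, manifest, edits, seed + 1)
    genomes: dict[str, list[SequenceRecord]] = {BASE_GENOME: base}
    for name in LANDRACES[1:]:
        if name in derived:
            genomes[name] = derived[name]
    genomes[OUTGROUP] = [
        SequenceRecord(f"chr{i + 1}", rec.sequence)
        for i, rec in enumerate(derived[OUTGROUP])
    ]

    # two-group diploid assay: clearly diverged generating frequencies
    loci = [f"L{i:02d}" for i in range(1, 11)]
    cultivated: dict[str, dict[int, float]] = {}
    wild: dict[str, dict[int, float]] = {}
    for i, locus in enumerate(loci):
        base_size = 180 + 10 * i
        cultivated[locus] = {base_size: 0.55, base_size + 6: 0.30, base_size + 12: 0.15}
        wild[locus] = {base_size + 12: 0.10, base_size + 18: 0.55, base_size + 24: 0.35}
    freqs = {"cultivated": cultivated, "wild": wild}
    n_per_group = {"cultivated": 20, "wild": 8}
    genotypes, groups = make_genotypes(freqs, n_per_group, seed + 2)
    manifest.genotype_freqs = {
        g: {loc: dict(t) for loc, t in freqs[g].items()} for g in freqs
    }

    features = {BASE_GENOME: _annotation()} if not small else {}
    return FixtureSet(
        genomes=genomes,
        features=features,
        genotypes=genotypes,
        groups=groups,
        manifest=manifest,
        base_markers=report.markers,
    )
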