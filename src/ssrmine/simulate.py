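"""Synthetic genomes, landrace variants and genotype tables with exact
ground truth.

``make_genome`` plants SSR tracts at stated positions in an i.i.d. uniform
ACGT background that is rejection-resampled until it contains no
threshold-passing SSR of its own, so the plant manifest predicts the
scanner output exactly. ``make_landraces`` derives variant genomes by
expanding/contracting planted tracts (each unit changes the expected
amplicon by exactly the motif length) and by placing substitutions inside
designed primer footprints (to destroy transferability at a chosen
mismatch budget). ``make_genotypes`` draws diploid genotypes under
Hardy-Weinberg proportions within groups. Everything is seeded and
deterministic.

These fixtures emulate study conditions - a handful of clonally related
landrace assemblies plus a diverged outgroup, and a two-group marker
assay - at desk scale; they do not model transposable-element background,
assembly gaps or chromosome-scale structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_core import GenotypeTable, SequenceRecord
from .repeat_scan import RepeatLocus, ScanConfig, scan_genome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SSRPlant:
    """One planted SSR: tract = motif * repeat_count at [position, ...)."""

    plant_id: str
    contig: int
    position: int
    motif: str
    repeat_count: int

    @property
    def tract(self) -> str:
        return self.motif * self.repeat_count

    @property
    def end(self) -> int:
        return self.position + len(self.tract)


@dataclass
class TractEdit:
    """Expand (delta_units > 0) or contract a planted tract by whole units."""

    plant_id: str
    delta_units: int


@dataclass
class PrimerSiteEdit:
    """Place ``n_substitutions`` inside a primer footprint given as a
    genomic interval [start, end) on the base genome's contig."""

    plant_id: str
    contig: int
    start: int
    end: int
    n_substitutions: int


@dataclass
class PlantManifest:
    plants: list[SSRPlant] = field(default_factory=list)
    #: landrace name -> list of applied edits
    edits: dict[str, list] = field(default_factory=dict)
    #: landrace name -> plant_id -> expected amplicon size change in bp
    size_shifts: dict[str, dict[str, int]] = field(default_factory=dict)
    #: plant_id of cassettes duplicated elsewhere in the base genome
    duplicated: list[str] = field(default_factory=list)
    #: group -> locus -> allele size -> generating frequency
    genotype_freqs: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "plants": [vars(p) for p in self.plants],
            "edits": {
                lr: [
                    {"kind": type(e).__name__, **vars(e)} for e in edits
                ]
                for lr, edits in self.edits.items()
            },
            "size_shifts": self.size_shifts,
            "duplicated": self.duplicated,
            "genotype_freqs": self.genotype_freqs,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def make_genome(
    n_contigs: int,
    contig_len: int,
    ssr_plants: list[SSRPlant],
    seed: int,
    scan_cfg: ScanConfig | None = None,
    contig_prefix: str = "contig",
) -> tuple[list[SequenceRecord], PlantManifest]:
    """Uniform-background genome with the given SSRs planted verbatim.

    Spontaneous threshold-passing SSRs in the background are removed by
    rejection-resampling their spans, so the scanner finds exactly the
    planted loci. Plants must be non-overlapping with >= 250 nt clean
    margin to contig ends and to each other.
    """
    scan_cfg = scan_cfg or ScanConfig()
    rng = np.random.default_rng(seed)
    for p in ssr_plants:
        if not (0 <= p.contig < n_contigs):
            raise ValueError(f"plant {p.plant_id}: contig index out of range")
        if p.position < 250 or p.end > contig_len - 250:
            raise ValueError(f"plant {p.plant_id}: needs a 250 nt margin")
    by_contig: dict[int, list[SSRPlant]] = {i: [] for i in range(n_contigs)}
    for p in ssr_plants:
        by_contig[p.contig].append(p)
    for plants in by_contig.values():
        plants.sort(key=lambda p: p.position)
        for a, b in zip(plants, plants[1:]):
            if b.position - a.end < 250:
                raise ValueError(
                    f"plants {a.plant_id} and {b.plant_id} overlap or are "
                    "closer than the 250 nt margin (infeasible packing)"
                )

    records: list[SequenceRecord] = []
    for ci in range(n_contigs):
        arr = _random_seq(rng, contig_len)
        plant_spans = []
        for p in by_contig[ci]:
            tract = np.frombuffer(p.tract.encode(), dtype=np.uint8)
            arr[p.position : p.end] = tract
            plant_spans.append((p.position, p.end))

        def in_plant(a: int, b: int) -> bool:
            return any(a < pe and ps < b for ps, pe in plant_spans)

        seq_id = f"{contig_prefix}{ci + 1}"
        for _ in range(100):
            seq = arr.tobytes().decode("ascii")
            spurious = [
                l
                for l in scan_genome([SequenceRecord(seq_id, seq)], scan_cfg)
                if not any(
                    ps <= l.start and l.end <= pe for ps, pe in plant_spans
                )
            ]
            if not spurious:
                break
            for l in spurious:
                a, b = max(0, l.start - 3), min(contig_len, l.end + 3)
                for pos in range(a, b):
                    if not in_plant(pos, pos + 1):
                        arr[pos] = _random_seq(rng, 1)[0]
        else:
            raise RuntimeError("background resampling did not converge")
        records.append(SequenceRecord(seq_id, arr.tobytes().decode("ascii")))

    manifest = PlantManifest(plants=sorted(ssr_plants, key=lambda p: (p.contig, p.position)))
    return records, manifest


def duplicate_cassette(
    records: list[SequenceRecord],
    manifest: PlantManifest,
    plant_id: str,
    target_contig: int,
    target_position: int,
    margin: int = 250,
) -> list[SequenceRecord]:
    """Copy a planted SSR cassette (tract + ``margin`` nt each side) to a
    second location, creating a genuine multi-hit / duplicated-primer case."""
    plant = next(p for p in manifest.plants if p.plant_id == plant_id)
    src = records[plant.contig].sequence
    cassette = src[plant.position - margin : plant.end + margin]
    rec = records[target_contig]
    seq = rec.sequence
    a, b = target_position, target_position + len(cassette)
    if b > len(seq):
        raise ValueError("duplicate cassette would run past the contig end")
    new_seq = seq[:a] + cassette + seq[b:]
    out = list(records)
    out[target_contig] = SequenceRecord(rec.seq_id, new_seq)
    manifest.duplicated.append(plant_id)
    return out


def make_landraces(
    base: list[SequenceRecord],
    manifest: PlantManifest,
    edits: dict[str, list],
    seed: int,
) -> dict[str, list[SequenceRecord]]:
    """Derive edited landrace genomes from the base genome.

    Tract edits change the expected amplicon size by exactly
    ``delta_units * len(motif)`` bp; primer-site edits place the stated
    number of substitutions at seeded positions inside the footprint.
    Records the per-landrace expected size shifts in the manifest.
    """
    plants = {p.plant_id: p for p in manifest.plants}
    rng = np.random.default_rng(seed)
    out: dict[str, list[SequenceRecord]] = {}
    for landrace, edit_list in edits.items():
        for e in edit_list:
            if e.plant_id not in plants:
                raise ValueError(f"edit references unknown plant {e.plant_id!r}")
        seqs = [bytearray(r.sequence.encode()) for r in base]
        shifts: dict[str, int] = {}
        # substitutions first (length-preserving), then tract edits
        # right-to-left so earlier coordinates stay valid
        for e in edit_list:
            if isinstance(e, PrimerSiteEdit):
                arr = seqs[e.contig]
                # substitutions spaced >= 2 apart so short gapped alignments
                # cannot absorb adjacent edits
                slots = np.arange(e.start, e.end, 2)
                if len(slots) < e.n_substitutions:
                    slots = np.arange(e.start, e.end)
                pos = rng.choice(slots, size=e.n_substitutions, replace=False)
                for p_i in sorted(int(x) for x in pos):
                    old = arr[p_i]
                    choices = [b for b in b"ACGT" if b != old]
                    arr[p_i] = choices[int(rng.integers(0, 3))]
        tract_edits = sorted(
            (e for e in edit_list if isinstance(e, TractEdit)),
            key=lambda e: (plants[e.plant_id].contig, plants[e.plant_id].position),
            reverse=True,
        )
        for e in tract_edits:
            p = plants[e.plant_id]
            new_count = p.repeat_count + e.delta_units
            if new_count < 1:
                raise ValueError(f"edit would delete tract of {p.plant_id}")
            arr = seqs[p.contig]
            new_tract = (p.motif * new_count).encode()
            seqs[p.contig] = arr[: p.position] + bytearray(new_tract) + arr[p.end :]
            shifts[p.plant_id] = e.delta_units * len(p.motif)
        out[landrace] = [
            SequenceRecord(r.seq_id, bytes(s).decode("ascii"))
            for r, s in zip(base, seqs)
        ]
        manifest.edits[landrace] = list(edit_list)
        manifest.size_shifts[landrace] = shifts
    return out


def make_genotypes(
    freqs: dict[str, dict[str, dict[int, float]]],
    n_per_group: dict[str, int],
    seed: int,
) -> tuple[GenotypeTable, dict[str, list[str]]]:
    """Diploid genotypes drawn under Hardy-Weinberg within groups.

    ``freqs``: group -> locus -> allele size -> frequency (each locus's
    frequencies must sum to 1). Returns the table and the group membership.
    """
    rng = np.random.default_rng(seed)
    groups = sorted(freqs)
    loci = sorted({loc for g in groups for loc in freqs[g]})
    individuals: list[str] = []
    membership: dict[str, list[str]] = {}
    calls: dict[tuple[str, str], tuple[int, int] | None] = {}
    for group in groups:
        members = [f"{group}_{i + 1:03d}" for i in range(n_per_group[group])]
        membership[group] = members
        individuals.extend(members)
        for locus in loci:
            table = freqs[group][locus]
            alleles = sorted(table)
            p = np.array([table[a] for a in alleles], dtype=float)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus!r} in {group!r} do not sum to 1")
            draws = rng.choice(len(alleles), size=(len(members), 2), p=p)
            for ind, (a, b) in zip(members, draws):
                pair = sorted((alleles[int(a)], alleles[int(b)]))
                calls[(ind, locus)] = (pair[0], pair[1])
    return GenotypeTable(individuals, loci, calls), membership
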