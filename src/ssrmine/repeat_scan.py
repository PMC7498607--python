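"""Detection and classification of perfect microsatellites (SSRs).

The scanner finds every maximal perfect tandem repeat of a primitive motif
of length 1-6 nt that meets a per-motif-length minimum repeat count
(defaults: mono 12, di 8, tri 5, tetra 5, penta 4, hexa 4). A tract
divisible at two motif phases is reported once, at its leftmost start,
with ``repeat_count = floor(tract / motif length)`` - trailing partial
motif copies are neither counted nor included in the tract. Loci are
classified by tract length (class I > 20 nt, class II <= 20 nt) and by
base composition of the motif (AT-rich / GC-rich / balanced), and nearby
loci can be joined into compound SSRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_core import SequenceRecord, revcomp

DEFAULT_MIN_REPEATS = {1: 12, 2: 8, 3: 5, 4: 5, 5: 4, 6: 4}

AT_RICH = "AT_RICH"
GC_RICH = "GC_RICH"
BALANCED = "BALANCED"

#: Class I tracts are strictly longer than this many nt.
CLASS_I_THRESHOLD = 20

SSR_TYPE_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class ScanConfig:
    min_repeats: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_REPEATS))
    max_interruption: int = 100

    def __post_init__(self):
        if set(self.min_repeats) != set(range(1, 7)):
            raise ValueError("min_repeats must map motif lengths 1..6")
        if any(v < 2 for v in self.min_repeats.values()):
            raise ValueError("all repeat-count minima must be >= 2")
        if self.max_interruption < 0:
            raise ValueError("max_interruption must be >= 0")


@dataclass(frozen=True)
class RepeatLocus:
    """One detected SSR; coordinates 0-based half-open on ``seq_id``."""

    seq_id: str
    start: int
    end: int
    motif: str
    canonical_motif: str
    repeat_count: int
    compound: bool = False
    members: tuple["RepeatLocus", ...] = ()

    @property
    def tract_length(self) -> int:
        return self.end - self.start

    @property
    def length_class(self) -> str:
        return "I" if self.tract_length > CLASS_I_THRESHOLD else "II"

    @property
    def composition_class(self) -> str:
        if self.compound:
            if self.members:
                at = sum(
                    m.tract_length * sum(c in "AT" for c in m.motif) / len(m.motif)
                    for m in self.members
                )
                total = sum(m.tract_length for m in self.members)
            else:  # deserialized compound locus: fall back to the joined motifs
                joined = self.motif.replace("-", "")
                at = sum(c in "AT" for c in joined)
                total = len(joined)
            frac = at / total
            return AT_RICH if frac > 0.5 else GC_RICH if frac < 0.5 else BALANCED
        return classify_composition(self.motif)

    @property
    def ssr_type(self) -> str:
        return "compound" if self.compound else SSR_TYPE_NAMES[len(self.motif)]


def is_primitive(motif: str) -> bool:
    """True if the motif is not a repetition of a shorter word."""
    k = len(motif)
    return not any(
        k % d == 0 and motif == motif[:d] * (k // d) for d in range(1, k)
    )


def canonical_motif(motif: str) -> str:
    """Group representative of a motif: the lexicographically smallest word
    among all cyclic rotations of the motif and of its reverse complement
    (so A/T collapse to A, AAT/ATT to AAT, ...). Idempotent."""
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 1-6, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = revcomp(motif)
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def classify_composition(motif: str) -> str:
    """AT fraction > 1/2 -> AT_RICH; < 1/2 -> GC_RICH; exactly 1/2 -> BALANCED."""
    if not motif:
        raise ValueError("empty motif")
    frac = sum(c in "AT" for c in motif) / len(motif)
    return AT_RICH if frac > 0.5 else GC_RICH if frac < 0.5 else BALANCED


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs [a, b) of True in a boolean vector."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _scan_window(seq: str, offset: int, seq_id: str, cfg: ScanConfig) -> list[RepeatLocus]:
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    loci: list[RepeatLocus] = []
    for k in range(1, 7):
        min_count = cfg.min_repeats[k]
        if n < k * min_count:
            continue
        # match[i] is True iff seq[i] == seq[i+k]; a run [a, b) of matches
        # means [a, b + k) is perfectly periodic with period k.
        match = arr[:-k] == arr[k:]
        for a, b in _runs_of_true(match):
            start, region_end = a, b + k
            # shift right past a non-primitive leading phase (the region
            # then locally has a shorter period and is reported there)
            while region_end - start >= k * min_count and not is_primitive(
                seq[start : start + k]
            ):
                start += 1
            if region_end - start < k * min_count:
                continue
            motif = seq[start : start + k]
            if not is_primitive(motif):
                continue
            count = (region_end - start) // k
            loci.append(
                RepeatLocus(
                    seq_id=seq_id,
                    start=offset + start,
                    end=offset + start + count * k,
                    motif=motif,
                    canonical_motif=canonical_motif(motif),
                    repeat_count=count,
                )
            )
    loci.sort(key=lambda l: (l.start, len(l.motif)))
    return loci


def scan_sequence(record: SequenceRecord, cfg: ScanConfig | None = None) -> list[RepeatLocus]:
    """All maximal perfect SSRs in one sequence, left to right.

    Runs of N split the sequence into independent windows, so no reported
    tract contains an N and motifs never include N.
    """
    cfg = cfg or ScanConfig()
    seq = record.sequence
    loci: list[RepeatLocus] = []
    pos = 0
    n = len(seq)
    while pos < n:
        nxt = seq.find("N", pos)
        if nxt == -1:
            window_end = n
        else:
            window_end = nxt
        if window_end > pos:
            loci.extend(_scan_window(seq[pos:window_end], pos, record.seq_id, cfg))
        if nxt == -1:
            break
        pos = nxt
        while pos < n and seq[pos] == "N":
            pos += 1
    return loci


def scan_genome(
    records: list[SequenceRecord], cfg: ScanConfig | None = None
) -> list[RepeatLocus]:
    cfg = cfg or ScanConfig()
    out: list[RepeatLocus] = []
    for rec in records:
        out.extend(scan_sequence(rec, cfg))
    return out


def join_compound(loci: list[RepeatLocus], cfg: ScanConfig | None = None) -> list[RepeatLocus]:
    """Merge consecutive simple loci on one sequence separated by at most
    ``max_interruption`` nt into compound loci; others pass through."""
    cfg = cfg or ScanConfig()
    for prev, cur in zip(loci, loci[1:]):
        if (cur.seq_id, cur.start) < (prev.seq_id, prev.start):
            raise ValueError("loci must be sorted by (seq_id, start)")
    out: list[RepeatLocus] = []
    group: list[RepeatLocus] = []

    def flush():
        if not group:
            return
        if len(group) == 1:
            out.append(group[0])
        else:
            out.append(
                RepeatLocus(
                    seq_id=group[0].seq_id,
                    start=group[0].start,
                    end=group[-1].end,
                    motif="-".join(m.motif for m in group),
                    canonical_motif="-".join(m.canonical_motif for m in group),
                    repeat_count=sum(m.repeat_count for m in group),
                    compound=True,
                    members=tuple(group),
                )
            )
        group.clear()

    for locus in loci:
        if group and locus.seq_id == group[-1].seq_id and (
            locus.start - group[-1].end <= cfg.max_interruption
        ):
            group.append(locus)
        else:
            flush()
            group.append(locus)
    flush()
    return out


@dataclass
class LandscapeSummary:
    """Genome-wide SSR landscape counts (per-motif-length, class, composition,
    canonical-motif groups), density per Mbp, and the genome fraction in %."""

    total_count: int
    n_simple: int
    n_compound: int
    by_motif_length: dict[int, int]
    by_length_class: dict[str, int]
    by_composition: dict[str, int]
    by_canonical: dict[str, int]
    density_per_mbp: float
    genome_fraction_pct: float
    total_assembly_length: int


def summarize_landscape(
    loci: list[RepeatLocus],
    genome: list[SequenceRecord],
    count_compound: str = "single",
) -> LandscapeSummary:
    """Summarize an SSR landscape.

    ``count_compound``: ``"single"`` counts each compound locus once in the
    total (its span counted once toward the genome fraction); ``"members"``
    dissolves compounds into their member loci for all counts. Per-motif
    tables always cover simple loci only under ``"single"``.
    """
    if count_compound not in ("single", "members"):
        raise ValueError("count_compound must be 'single' or 'members'")
    known = {r.seq_id for r in genome}
    for locus in loci:
        if locus.seq_id not in known:
            raise ValueError(f"locus references unknown sequence {locus.seq_id!r}")
    assembly_len = sum(r.length for r in genome)

    simple = [l for l in loci if not l.compound]
    compounds = [l for l in loci if l.compound]
    if count_compound == "members":
        simple = simple + [m for c in compounds for m in c.members]
        counted: list[RepeatLocus] = simple
    else:
        counted = simple + compounds

    by_len: dict[int, int] = {k: 0 for k in range(1, 7)}
    by_canon: dict[str, int] = {}
    for l in simple:
        by_len[len(l.motif)] += 1
        by_canon[l.canonical_motif] = by_canon.get(l.canonical_motif, 0) + 1
    by_class: dict[str, int] = {"I": 0, "II": 0}
    by_comp: dict[str, int] = {AT_RICH: 0, GC_RICH: 0, BALANCED: 0}
    for l in counted:
        by_class[l.length_class] += 1
        by_comp[l.composition_class] += 1

    total = len(counted)
    tract_sum = sum(l.tract_length for l in counted)
    return LandscapeSummary(
        total_count=total,
        n_simple=len(simple),
        n_compound=len(compounds),
        by_motif_length=by_len,
        by_length_class=by_class,
        by_composition=by_comp,
        by_canonical=by_canon,
        density_per_mbp=(1e6 * total / assembly_len) if assembly_len else 0.0,
        genome_fraction_pct=(100.0 * tract_sum / assembly_len) if assembly_len else 0.0,
        total_assembly_length=assembly_len,
    )


LOCI_TSV_COLUMNS = [
    "seq_id",
    "start_1based",
    "end_1based",
    "motif",
    "canonical_motif",
    "repeat_count",
    "tract_length",
    "class",
    "composition",
    "compound_flag",
]


def write_loci_tsv(loci: list[RepeatLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(LOCI_TSV_COLUMNS) + "\n")
        for l in loci:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        l.seq_id,
                        l.start + 1,
                        l.end,
                        l.motif,
                        l.canonical_motif,
                        l.repeat_count,
                        l.tract_length,
                        l.length_class,
                        l.composition_class,
                        int(l.compound),
                    )
                )
                + "\n"
            )


def read_loci_tsv(path: str | Path) -> list[RepeatLocus]:
    loci: list[RepeatLocus] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != LOCI_TSV_COLUMNS:
            raise ValueError(f"unexpected loci table header in {path}")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            seq_id, s1, e1, motif, canon, count = cols[:6]
            compound = bool(int(cols[9]))
            members: tuple[RepeatLocus, ...] = ()
            if compound:
                # member detail is not serialized; re-derive simple fields only
                members = ()
            loci.append(
                RepeatLocus(
                    seq_id=seq_id,
                    start=int(s1) - 1,
                    end=int(e1),
                    motif=motif,
                    canonical_motif=canon,
                    repeat_count=int(count),
                    compound=compound,
                    members=members,
                )
            )
    return loci
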