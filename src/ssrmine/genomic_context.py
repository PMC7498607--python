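"""Genomic-region classification of SSR loci.

With annotation, a locus is assigned by >= 1 nt overlap with priority
CDS > 5'UTR > 3'UTR > intron (inside a gene span but in no CDS/UTR) >
intergenic; the gene's strand decides which UTR is 5' vs 3' (UTR feature
types are taken as already strand-resolved in the GFF3). Without
annotation, the longest open reading frame of the locus template serves as
a coding-region proxy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .io_core import FeatureRecord, revcomp
from .primer_design import FlankedLocus
from .repeat_scan import RepeatLocus

REGION_CDS = "CDS"
REGION_UTR5 = "UTR5"
REGION_UTR3 = "UTR3"
REGION_INTRON = "INTRON"
REGION_INTERGENIC = "INTERGENIC"

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class GenomicContext:
    region: str
    evidence: str  # "annotation" | "orf" | "none"


def _overlaps(locus: RepeatLocus, f: FeatureRecord) -> bool:
    return f.seq_id == locus.seq_id and locus.start < f.end and f.start < locus.end


def classify_by_annotation(
    locus: RepeatLocus, features: list[FeatureRecord]
) -> GenomicContext:
    hit_types = {f.type for f in features if _overlaps(locus, f)}
    if "CDS" in hit_types:
        return GenomicContext(REGION_CDS, "annotation")
    if "five_prime_UTR" in hit_types:
        return GenomicContext(REGION_UTR5, "annotation")
    if "three_prime_UTR" in hit_types:
        return GenomicContext(REGION_UTR3, "annotation")
    if hit_types & {"gene", "mRNA", "intron", "exon"}:
        # inside a gene span but in no coding/UTR feature; an exon-only
        # overlap (e.g. ncRNA) lands here too - non-coding genic
        return GenomicContext(REGION_INTRON, "annotation")
    return GenomicContext(REGION_INTERGENIC, "none")


def find_longest_orf(seq: str, min_len: int = 300) -> tuple[int, int, str] | None:
    """Longest ORF over all six frames: ATG start, stop codon included in
    the span, minimum span ``min_len`` nt. Ties prefer the + strand, then
    the leftmost start (coordinates on the forward sequence)."""
    if len(seq) < 30:
        return None
    best: tuple[int, int, int, str] | None = None  # (-length, strand_rank, start)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        n = len(s)
        for frame in range(3):
            start_codon: int | None = None
            for i in range(frame, n - 2, 3):
                codon = s[i : i + 3]
                if codon == "ATG" and start_codon is None:
                    start_codon = i
                elif codon in _STOPS and start_codon is not None:
                    span = i + 3 - start_codon
                    if span >= min_len:
                        if strand == "+":
                            fwd = (start_codon, i + 3)
                        else:
                            fwd = (n - (i + 3), n - start_codon)
                        key = (-span, 0 if strand == "+" else 1, fwd[0])
                        if best is None or key < best[:3]:
                            best = (*key, strand, fwd)
                    start_codon = None
    if best is None:
        return None
    _, _, _, strand, (a, b) = best
    return (a, b, strand)


def classify_with_fallback(
    fl: FlankedLocus,
    features: list[FeatureRecord] | None = None,
    orf_min: int = 300,
) -> GenomicContext:
    """Annotation-based call when features are given; otherwise the locus
    is called CDS (evidence "orf") when its tract overlaps the template's
    longest ORF, else intergenic."""
    if features is not None:
        return classify_by_annotation(fl.locus, features)
    orf = find_longest_orf(fl.template, min_len=orf_min)
    if orf is None:
        return GenomicContext(REGION_INTERGENIC, "none")
    a, b, _ = orf
    tract_start = len(fl.left_flank)
    tract_end = tract_start + len(fl.tract)
    if tract_start < b and a < tract_end:
        return GenomicContext(REGION_CDS, "orf")
    return GenomicContext(REGION_INTERGENIC, "orf")


def region_counts(contexts: list[GenomicContext]) -> dict[str, int]:
    """Counts per region; always partitions the input exactly."""
    out = {r: 0 for r in (REGION_CDS, REGION_UTR5, REGION_UTR3, REGION_INTRON, REGION_INTERGENIC)}
    for c in contexts:
        out[c.region] += 1
    return out


def write_context_tsv(
    rows: list[tuple[str, GenomicContext]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tregion\tevidence\n")
        for locus_id, ctx in rows:
            fh.write(f"{locus_id}\t{ctx.region}\t{ctx.evidence}\n")
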