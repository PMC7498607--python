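"""SSR flank extraction and primer-pair design.

For each SSR locus the flanking sequence (default 200 nt each side) is
extracted and up to three primer pairs are designed under hard bounds on
primer length, GC content, melting temperature, pair Tm difference and
product size, with a simple additive penalty

    penalty = |len - opt_len| + |Tm - opt_Tm| + 0.5 * |GC - 50|

summed over the two primers for ranking. Melting temperatures are
nearest-neighbor values (SantaLucia & Hicks 2004 parameters) at fixed
standard conditions: 50 mM monovalent salt, 50 nM oligo.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

from Bio.SeqUtils import MeltingTemp as _mt

from .io_core import SequenceRecord, genome_index, revcomp
from .repeat_scan import RepeatLocus

#: Tm conditions, frozen (also printed in output metadata by the CLI).
TM_CONDITIONS = {"Na_mM": 50.0, "oligo_nM": 50.0}


@dataclass(frozen=True)
class DesignConfig:
    primer_len_min: int = 18
    primer_len_opt: int = 20
    primer_len_max: int = 27
    gc_min: float = 40.0
    gc_max: float = 60.0
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    max_tm_diff: float = 3.0
    product_min: int = 100
    product_max: int = 300
    max_homopolymer_in_primer: int = 4
    max_3prime_self_complement: int = 3

    def __post_init__(self):
        for lo, opt, hi in (
            (self.primer_len_min, self.primer_len_opt, self.primer_len_max),
            (self.tm_min, self.tm_opt, self.tm_max),
        ):
            if not lo <= opt <= hi:
                raise ValueError("bounded triples must satisfy min <= opt <= max")
        if not (self.gc_min <= self.gc_max and self.product_min <= self.product_max):
            raise ValueError("invalid GC or product-size bounds")


@dataclass(frozen=True)
class FlankedLocus:
    """An SSR locus with its extracted flanks.

    ``template`` is ``left_flank + tract + right_flank``;
    ``template_start`` is the genomic position of the template's first base.
    """

    locus: RepeatLocus
    left_flank: str
    right_flank: str
    tract: str
    left_truncated: bool
    right_truncated: bool

    @property
    def template(self) -> str:
        return self.left_flank + self.tract + self.right_flank

    @property
    def template_start(self) -> int:
        return self.locus.start - len(self.left_flank)


@dataclass(frozen=True)
class PrimerPair:
    """One ranked primer pair; both sequences are written 5'->3'."""

    forward: str
    reverse: str
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    product_size: int
    penalty: float
    rank: int
    forward_start: int  # template coordinate of forward primer 5' base
    reverse_end: int  # template coordinate one past reverse primer 5' base


def extract_flanks(
    locus: RepeatLocus, genome: list[SequenceRecord], flank_size: int = 200
) -> FlankedLocus:
    """Extract up to ``flank_size`` nt each side of the tract, truncating at
    sequence boundaries and at the nearest run of N (truncation flagged)."""
    idx = genome_index(genome)
    if locus.seq_id not in idx:
        raise ValueError(f"unknown sequence {locus.seq_id!r}")
    seq = idx[locus.seq_id].sequence
    left_lo = max(0, locus.start - flank_size)
    left = seq[left_lo : locus.start]
    n_pos = left.rfind("N")
    if n_pos != -1:
        left = left[n_pos + 1 :]
    right_hi = min(len(seq), locus.end + flank_size)
    right = seq[locus.end : right_hi]
    n_pos = right.find("N")
    if n_pos != -1:
        right = right[:n_pos]
    return FlankedLocus(
        locus=locus,
        left_flank=left,
        right_flank=right,
        tract=seq[locus.start : locus.end],
        left_truncated=len(left) < flank_size,
        right_truncated=len(right) < flank_size,
    )


@lru_cache(maxsize=200_000)
def melting_temperature(primer: str) -> float:
    """Nearest-neighbor duplex Tm in deg C at the fixed standard conditions
    (50 mM Na+, 50 nM oligo, SantaLucia 1998 salt correction)."""
    if len(primer) < 8:
        raise ValueError("primer shorter than 8 nt")
    if "N" in primer:
        raise ValueError("N not allowed in a primer")
    return float(
        _mt.Tm_NN(
            primer,
            nn_table=_mt.DNA_NN4,
            Na=TM_CONDITIONS["Na_mM"],
            dnac1=TM_CONDITIONS["oligo_nM"],
            dnac2=0,
            saltcorr=5,
        )
    )


def gc_percent(seq: str) -> float:
    return 100.0 * sum(c in "GC" for c in seq) / len(seq)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def score_primer(primer: str, cfg: DesignConfig, tm: float | None = None) -> float | None:
    """Penalty of a candidate primer, or None if it is hard-rejected.

    Rejection: length/GC/Tm outside bounds, a homopolymer run longer than
    ``max_homopolymer_in_primer``, or a 3'-end self-complementary stretch
    longer than ``max_3prime_self_complement`` (checked as: the reverse
    complement of the 3'-terminal ``max+1``-mer occurring anywhere in the
    primer).
    """
    n = len(primer)
    if not cfg.primer_len_min <= n <= cfg.primer_len_max:
        return None
    gc = gc_percent(primer)
    if not cfg.gc_min <= gc <= cfg.gc_max:
        return None
    if _max_homopolymer(primer) > cfg.max_homopolymer_in_primer:
        return None
    tail = primer[-(cfg.max_3prime_self_complement + 1) :]
    if revcomp(tail) in primer:
        return None
    if tm is None:
        tm = melting_temperature(primer)
    if not cfg.tm_min <= tm <= cfg.tm_max:
        return None
    return (
        abs(n - cfg.primer_len_opt)
        + abs(tm - cfg.tm_opt)
        + 0.5 * abs(gc - 50.0)
    )


def _candidates(flank: str, cfg: DesignConfig, reverse: bool):
    """Admissible primer candidates from one flank.

    Yields (penalty, start, end, primer_seq, tm, gc) with start/end in
    flank coordinates. For the right flank the candidate primer is the
    reverse complement of the flank substring.
    """
    out = []
    n = len(flank)
    for length in range(cfg.primer_len_min, cfg.primer_len_max + 1):
        for start in range(0, n - length + 1):
            segment = flank[start : start + length]
            primer = revcomp(segment) if reverse else segment
            gc = gc_percent(primer)
            if not cfg.gc_min <= gc <= cfg.gc_max:
                continue
            if _max_homopolymer(primer) > cfg.max_homopolymer_in_primer:
                continue
            tm = melting_temperature(primer)
            pen = score_primer(primer, cfg, tm=tm)
            if pen is None:
                continue
            out.append((pen, start, start + length, primer, tm, gc))
    return out


def design_for_locus(fl: FlankedLocus, cfg: DesignConfig | None = None) -> list[PrimerPair]:
    """Up to 3 ranked primer pairs for one flanked locus.

    Forward candidates come from the left flank, reverse candidates from
    the right flank; every pair spans the full tract, satisfies the
    product-size range and the pair Tm-difference bound. Pairs are ranked
    by penalty sum, ties broken by smaller product size then leftmost
    forward start. An empty result means primer modelling failed.
    """
    cfg = cfg or DesignConfig()
    left, right = fl.left_flank, fl.right_flank
    if not left or not right or "N" in left or "N" in right:
        return []
    fwd = _candidates(left, cfg, reverse=False)
    rev = _candidates(right, cfg, reverse=True)
    if not fwd or not rev:
        return []
    offset_r = len(left) + len(fl.tract)  # template coord of right flank start
    scored = []
    for pf, fs, fe, fseq, ftm, fgc in fwd:
        for pr, rs, re, rseq, rtm, rgc in rev:
            if abs(ftm - rtm) > cfg.max_tm_diff:
                continue
            product = (offset_r + re) - fs
            if not cfg.product_min <= product <= cfg.product_max:
                continue
            scored.append(
                (
                    pf + pr,
                    product,
                    fs,
                    PrimerPair(
                        forward=fseq,
                        reverse=rseq,
                        tm_f=ftm,
                        tm_r=rtm,
                        gc_f=fgc,
                        gc_r=rgc,
                        product_size=product,
                        penalty=pf + pr,
                        rank=0,
                        forward_start=fs,
                        reverse_end=offset_r + re,
                    ),
                )
            )
    scored.sort(key=lambda t: (t[0], t[1], t[2], t[3].forward, t[3].reverse))
    pairs: list[PrimerPair] = []
    seen: set[tuple[str, str]] = set()
    for _, _, _, pair in scored:
        key = (pair.forward, pair.reverse)
        if key in seen:
            continue
        seen.add(key)
        pairs.append(
            PrimerPair(**{**pair.__dict__, "rank": len(pairs) + 1})
        )
        if len(pairs) == 3:
            break
    return pairs


PRIMER_TSV_COLUMNS = [
    "marker_id",
    "rank",
    "forward",
    "reverse",
    "tm_f",
    "tm_r",
    "gc_f",
    "gc_r",
    "product_size",
    "penalty",
]


def write_primers_tsv(
    pairs_by_marker: dict[str, list[PrimerPair]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PRIMER_TSV_COLUMNS) + "\n")
        for marker_id in sorted(pairs_by_marker):
            for p in pairs_by_marker[marker_id]:
                fh.write(
                    "\t".join(
                        [
                            marker_id,
                            str(p.rank),
                            p.forward,
                            p.reverse,
                            f"{p.tm_f:.2f}",
                            f"{p.tm_r:.2f}",
                            f"{p.gc_f:.2f}",
                            f"{p.gc_r:.2f}",
                            str(p.product_size),
                            f"{p.penalty:.3f}",
                        ]
                    )
                    + "\n"
                )
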