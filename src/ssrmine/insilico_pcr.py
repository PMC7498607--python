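"""Electronic PCR: primer binding-site search and amplicon prediction.

A primer binds a target site when the whole primer can be aligned to the
target (semi-global: primer global, target local) within independent
per-primer budgets of mismatches (default 3) and gap columns (default 3).
The primer's 3'-terminal ``seed_word`` bases (default 7) must match the
target exactly - the classic e-PCR 3'-anchored word, which is what gives
the search its specificity; mismatches and gaps are only permitted 5' of
the seed, gaps strictly internally (the 5'-terminal primer base must align
to a target base, so gap columns can never trim a primer end). Alignments
are canonical: an insertion column never sits next to a deletion column -
such a pair is a substitution and is billed as one mismatch, never as two
gaps. Candidate anchor positions are screened over the whole target
and verified with a banded edit alignment vectorized over all candidates,
so the search is exhaustive: it finds exactly the sites a brute-force
semi-global aligner honoring both budgets and the 3'-anchored-seed rule
finds.

Any alignment column against an N in the target counts as a mismatch.
A site whose total cost (mismatches + gaps) is strictly beaten by another
site of the same primer and strand within ``max_gaps`` nt of its 3' end is
suppressed, so a perfect match is reported once rather than alongside
gapped one-off echoes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_core import SequenceRecord, revcomp

_INF = 99
_NBYTE = ord("N")
# alignment-column types (for the canonical-alignment adjacency rule)
_DIAG, _TGAP, _PGAP = 0, 1, 2


@dataclass(frozen=True)
class EPCRConfig:
    max_mismatches: int = 3
    max_gaps: int = 3
    min_product: int = 50
    max_product: int = 2000
    #: length of the exact 3'-anchored word required of every site;
    #: part of the match definition, as in NCBI e-PCR.
    seed_word: int = 7
    anchor_3prime: bool = True

    def __post_init__(self):
        if self.max_mismatches < 0 or self.max_gaps < 0:
            raise ValueError("budgets must be >= 0")
        if self.min_product > self.max_product:
            raise ValueError("min_product must be <= max_product")


@dataclass(frozen=True)
class BindingSite:
    """One primer binding site; [start, end) on the target's + text."""

    seq_id: str
    strand: str
    start: int
    end: int
    mismatches: int
    gaps: int

    @property
    def cost(self) -> int:
        return self.mismatches + self.gaps


@dataclass(frozen=True)
class Amplicon:
    """One predicted PCR product (5'-to-5' span of the two primer sites)."""

    seq_id: str
    start: int
    end: int
    forward_site: BindingSite
    reverse_site: BindingSite
    orientation: str  # "FR": forward on +; "RF": the symmetric orientation

    @property
    def length(self) -> int:
        return self.end - self.start


def _raw_sites(primer: str, text: str, cfg: EPCRConfig) -> list[tuple[int, int, int, int]]:
    """(start, end, mismatches, gaps) for every binding site of ``primer``
    read in the + orientation of ``text``."""
    P, L = len(primer), len(text)
    if P == 0 or L == 0:
        return []
    maxg, maxm = cfg.max_gaps, cfg.max_mismatches
    pad = P + maxg + 1
    t = np.frombuffer(("\x01" * pad + text).encode("latin-1"), dtype=np.uint8)
    p = primer.encode("ascii")
    last = p[-1]
    if cfg.anchor_3prime:
        if P < cfg.seed_word:
            raise ValueError("primer shorter than the 3'-anchored seed word")
        seed = cfg.seed_word
        ok = np.ones(t.size, dtype=bool)
        for j in range(seed):
            m = t == p[P - 1 - j]
            if j:
                ok[:j] = False
                ok[j:] &= m[: t.size - j]
            else:
                ok &= m
        anchors = np.flatnonzero(ok)
        anchors = anchors[anchors >= pad]
        if anchors.size == 0:
            return []
        dp = {(0, 0, _DIAG): np.zeros(anchors.size, dtype=np.int16)}
        first_i = seed
    else:
        anchors = np.arange(pad, pad + L)
        tc = t[anchors]
        dp = {(0, 0, _DIAG): ((tc != last) | (tc == _NBYTE)).astype(np.int16)}
        first_i = 1

    for i in range(first_i, P):
        c = p[P - 1 - i]
        # target-only gap columns (insertions), internal and never adjacent
        # to a deletion column (canonical alignments only)
        for g in range(maxg):
            for o in range(-maxg, maxg + 1):
                for last in (_DIAG, _TGAP):
                    st = dp.get((g, o, last))
                    if st is None:
                        continue
                    key = (g + 1, o + 1, _TGAP)
                    if key in dp:
                        np.minimum(dp[key], st, out=dp[key])
                    else:
                        dp[key] = st.copy()
        new: dict[tuple[int, int, int], np.ndarray] = {}

        def merge(key, arr):
            if key in new:
                np.minimum(new[key], arr, out=new[key])
            else:
                new[key] = arr

        for (g, o, last_col), st in dp.items():
            tchar = t[anchors - (i + o)]
            neq = ((tchar != c) | (tchar == _NBYTE)).astype(np.int16)
            merge((g, o, _DIAG), st + neq)  # match / mismatch column
            # primer base against a gap (deletion): internal only (the
            # 5'-terminal base must align a target base) and never next
            # to an insertion column
            if g < maxg and i < P - 1 and last_col != _TGAP:
                merge((g + 1, o - 1, _PGAP), st.copy())
        for key in list(new):
            arr = new[key]
            arr[arr > maxm] = _INF
            if int(arr.min()) >= _INF:
                del new[key]
        dp = new
        if not dp:
            return []
        # most candidates exceed the mismatch budget within a few bases;
        # drop dead anchors so later steps work on short vectors
        alive = np.zeros(anchors.size, dtype=bool)
        for arr in dp.values():
            alive |= arr < _INF
        if alive.sum() < 0.6 * anchors.size:
            anchors = anchors[alive]
            if anchors.size == 0:
                return []
            dp = {k: v[alive] for k, v in dp.items()}

    best_cost = np.full(anchors.size, _INF, dtype=np.int16)
    best_g = np.zeros(anchors.size, dtype=np.int16)
    best_o = np.zeros(anchors.size, dtype=np.int16)
    for g, o, last_col in sorted(dp):  # ascending (gaps, offset): deterministic
        st = dp[(g, o, last_col)]
        starts = anchors - (P + o) + 1
        valid = (st <= maxm) & (starts >= pad)
        cost = np.where(valid, st + g, _INF)
        better = cost < best_cost
        best_cost = np.where(better, cost, best_cost)
        best_g = np.where(better, np.int16(g), best_g)
        best_o = np.where(better, np.int16(o), best_o)

    sites = []
    for idx in np.flatnonzero(best_cost < _INF):
        g, o, cost = int(best_g[idx]), int(best_o[idx]), int(best_cost[idx])
        e = int(anchors[idx])
        sites.append((e - (P + o) + 1 - pad, e + 1 - pad, cost - g, g))
    return sites


def suppress_dominated(sites: list[tuple[int, int, int, int]], window: int):
    """Drop sites whose cost is strictly beaten by a site whose 3' end lies
    within ``window`` nt. Part of the binding-site definition."""
    kept = []
    by_end = sorted(sites, key=lambda s: (s[1], s[0]))
    for i, s in enumerate(by_end):
        cost = s[2] + s[3]
        dominated = False
        for other in by_end:
            if other is s:
                continue
            if abs(other[1] - s[1]) <= window and other[2] + other[3] < cost:
                dominated = True
                break
        if not dominated:
            kept.append(s)
    return kept


def find_binding_sites(
    primer: str, genome: list[SequenceRecord], cfg: EPCRConfig | None = None
) -> list[BindingSite]:
    """Every binding site of ``primer`` on either strand of every sequence."""
    cfg = cfg or EPCRConfig()
    out: list[BindingSite] = []
    for rec in genome:
        text = rec.sequence
        L = len(text)
        for strand, searched in (("+", text), ("-", revcomp(text))):
            raw = suppress_dominated(_raw_sites(primer, searched, cfg), cfg.max_gaps)
            for s, e, mm, g in raw:
                if strand == "+":
                    out.append(BindingSite(rec.seq_id, "+", s, e, mm, g))
                else:
                    out.append(BindingSite(rec.seq_id, "-", L - e, L - s, mm, g))
    out.sort(key=lambda b: (b.seq_id, b.start, b.strand, b.end))
    return out


def amplify(
    pair, genome: list[SequenceRecord], cfg: EPCRConfig | None = None
) -> list[Amplicon]:
    """All products of a primer pair: convergent forward/reverse binding
    sites on one sequence within the product-size bounds. The product
    length is the inclusive 5'-to-5' span, so a pair re-applied to its own
    design template reproduces the designed product size exactly."""
    cfg = cfg or EPCRConfig()
    fwd_sites = find_binding_sites(pair.forward, genome, cfg)
    rev_sites = find_binding_sites(pair.reverse, genome, cfg)
    out: list[Amplicon] = []
    for rec_id in sorted({s.seq_id for s in fwd_sites} | {s.seq_id for s in rev_sites}):
        f_plus = [s for s in fwd_sites if s.seq_id == rec_id and s.strand == "+"]
        f_minus = [s for s in fwd_sites if s.seq_id == rec_id and s.strand == "-"]
        r_plus = [s for s in rev_sites if s.seq_id == rec_id and s.strand == "+"]
        r_minus = [s for s in rev_sites if s.seq_id == rec_id and s.strand == "-"]
        for f in f_plus:
            for r in r_minus:
                length = r.end - f.start
                if f.start <= r.start and cfg.min_product <= length <= cfg.max_product:
                    out.append(Amplicon(rec_id, f.start, r.end, f, r, "FR"))
        for r in r_plus:
            for f in f_minus:
                length = f.end - r.start
                if r.start <= f.start and cfg.min_product <= length <= cfg.max_product:
                    out.append(Amplicon(rec_id, r.start, f.end, r, f, "RF"))
    out.sort(key=lambda a: (a.seq_id, a.start, a.end, a.orientation))
    return out


def epcr_matrix(
    markers,
    genomes: dict[str, list[SequenceRecord]],
    cfg: EPCRConfig | None = None,
) -> dict[tuple[str, str], list[Amplicon]]:
    """Complete (marker, taxon) -> amplicons matrix using each marker's
    rank-1 primer pair; empty cells are empty lists. Iteration order is
    deterministic: markers sorted by id, taxa sorted by name."""
    cfg = cfg or EPCRConfig()
    matrix: dict[tuple[str, str], list[Amplicon]] = {}
    for marker in sorted(markers, key=lambda m: m.marker_id):
        pair = marker.primer_pairs[0]
        for taxon in sorted(genomes):
            genome = genomes[taxon]
            if not genome:
                raise ValueError(f"unreadable or empty genome for taxon {taxon!r}")
            matrix[(marker.marker_id, taxon)] = amplify(pair, genome, cfg)
    return matrix


AMPLICON_TSV_COLUMNS = [
    "marker_id",
    "taxon",
    "seq_id",
    "start_1based",
    "end_1based",
    "length",
    "mm_f",
    "mm_r",
    "gaps_f",
    "gaps_r",
]


def write_amplicons_tsv(
    matrix: dict[tuple[str, str], list[Amplicon]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(AMPLICON_TSV_COLUMNS) + "\n")
        for (marker_id, taxon), amps in matrix.items():
            for a in amps:
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            marker_id,
                            taxon,
                            a.seq_id,
                            a.start + 1,
                            a.end,
                            a.length,
                            a.forward_site.mismatches,
                            a.reverse_site.mismatches,
                            a.forward_site.gaps,
                            a.reverse_site.gaps,
                        )
                    )
                    + "\n"
                )
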