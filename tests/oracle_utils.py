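"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain per-position Python,
structurally unlike the vectorized implementations it checks.
"""

from __future__ import annotations

import math
from functools import lru_cache

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _primitive(motif: str) -> bool:
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def brute_force_scan(seq: str, min_repeats: dict[int, int]) -> set[tuple[int, int, str]]:
    """Every maximal perfect tandem repeat as (start, end, motif), found by
    testing every (position, motif length) pair."""
    out: set[tuple[int, int, str]] = set()
    # independent N-window splitting
    windows = []
    pos = 0
    for chunk in seq.split("N"):
        if chunk:
            windows.append((pos, chunk))
        pos += len(chunk) + 1
    for off, win in windows:
        n = len(win)
        for k in range(1, 7):
            minc = min_repeats[k]
            if n < k * minc:
                continue
            for i in range(0, n - k + 1):
                if i > 0 and win[i - 1] == win[i + k - 1]:
                    continue  # not the leftmost base of its periodic stretch
                r = 0
                while i + r + k < n and win[i + r] == win[i + r + k]:
                    r += 1
                region_end = i + r + k
                s = i
                while region_end - s >= k * minc and not _primitive(win[s : s + k]):
                    s += 1
                motif = win[s : s + k]
                if region_end - s < k * minc or not _primitive(motif):
                    continue
                count = (region_end - s) // k
                out.add((off + s, off + s + count * k, motif))
    return out


def _suppress(sites, window):
    kept = []
    for s in sites:
        cost = s[2] + s[3]
        if not any(
            o is not s and abs(o[1] - s[1]) <= window and o[2] + o[3] < cost
            for o in sites
        ):
            kept.append(s)
    return sorted(kept)


def brute_force_binding_sites(
    primer: str,
    text: str,
    max_mismatches: int = 3,
    max_gaps: int = 3,
    seed_word: int = 7,
) -> list[tuple[int, int, int, int]]:
    """All (start, end, mismatches, gaps) sites of ``primer`` on the +
    orientation of ``text``: exact 3'-anchored seed, then exhaustive
    enumeration of semi-global alignments of the remaining prefix."""
    P = len(primer)
    seed = primer[P - seed_word :]
    sites = []
    for e in range(seed_word - 1, len(text)):
        if text[e - seed_word + 1 : e + 1] != seed:
            continue

        ti_start = e - seed_word
        max_consume = (P - seed_word) + max_gaps
        DIAG, TGAP, PGAP = "d", "i", "p"

        @lru_cache(maxsize=None)
        def align(pi: int, ti: int, right: str) -> frozenset:
            """Feasible (mm, gaps, last_unconsumed_index) completing
            primer[0..pi] against text ending at ti, where ``right`` is the
            type of the alignment column immediately to the right (canonical
            alignments: insertion and deletion columns are never adjacent)."""
            if ti_start - ti > max_consume:
                return frozenset()
            if pi < 0:
                return frozenset({(0, 0, ti)})
            found = set()
            if ti >= 0:
                ch = text[ti]
                bad = 0 if (ch == primer[pi] and ch != "N") else 1
                for mm, g, st in align(pi - 1, ti - 1, DIAG):  # (mis)match column
                    if mm + bad <= max_mismatches:
                        found.add((mm + bad, g, st))
                if right != PGAP:  # target base vs gap (insertion)
                    for mm, g, st in align(pi, ti - 1, TGAP):
                        if g + 1 <= max_gaps:
                            found.add((mm, g + 1, st))
            # primer base vs gap (deletion): internal only, never 5'-terminal
            if pi > 0 and right != TGAP:
                for mm, g, st in align(pi - 1, ti, PGAP):
                    if g + 1 <= max_gaps:
                        found.add((mm, g + 1, st))
            return frozenset(found)

        cands = []
        for mm, g, st in align(P - seed_word - 1, e - seed_word, DIAG):
            start = st + 1
            if start < 0:
                continue
            o = (e - st) - P
            cands.append((mm + g, g, o, mm, start))
        align.cache_clear()
        if not cands:
            continue
        cost, g, o, mm, start = sorted(cands)[0]
        sites.append((start, e + 1, mm, g))
    return _suppress(sites, max_gaps)


# SantaLucia & Hicks (2004) unified nearest-neighbor parameters:
# (delta H kcal/mol, delta S cal/mol/K) per duplex dinucleotide step.
NN_TABLE = {
    "AA": (-7.6, -21.3), "TT": (-7.6, -21.3),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}


def nn_tm(seq: str, na_mM: float = 50.0, ct_nM: float = 50.0) -> float:
    """Hand summation of the nearest-neighbor Tm at the package's fixed
    conditions (duplex initiation, terminal-AT penalties, SantaLucia 1998
    entropy salt correction, Tm = dH / (dS + R ln CT))."""
    dh, ds = 0.2, -5.7
    for a, b in zip(seq, seq[1:]):
        h, s = NN_TABLE[a + b]
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += 2.2
            ds += 6.9
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    return 1000.0 * dh / (ds + 1.987 * math.log(ct_nM * 1e-9)) - 273.15


def random_additive_tree(n: int, rng):
    """Random unrooted binary tree with branch lengths in [0.5, 2].

    Returns (labels, distance_matrix_list, bipartitions) where
    bipartitions are canonical leaf-side frozensets of internal edges.
    """
    labels = [f"T{i:02d}" for i in range(n)]
    adj: dict[object, dict[object, float]] = {}

    def connect(a, b, ln):
        adj.setdefault(a, {})[b] = ln
        adj.setdefault(b, {})[a] = ln

    def disconnect(a, b):
        del adj[a][b]
        del adj[b][a]

    center = "x0"
    serial = 1
    for leaf in labels[:3]:
        connect(center, leaf, float(rng.uniform(0.5, 2.0)))
    for leaf in labels[3:]:
        edges = [(a, b) for a in adj for b in adj[a] if str(a) < str(b)]
        a, b = edges[rng.integers(0, len(edges))]
        mid = f"x{serial}"
        serial += 1
        ln = adj[a][b]
        split = float(rng.uniform(0.25, 0.75))
        disconnect(a, b)
        connect(a, mid, ln * split)
        connect(mid, b, ln * (1 - split))
        connect(mid, leaf, float(rng.uniform(0.5, 2.0)))

    def dist_from(src):
        d = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, ln in adj[u].items():
                if v not in d:
                    d[v] = d[u] + ln
                    stack.append(v)
        return d

    mat = [[0.0] * n for _ in range(n)]
    for i, a in enumerate(labels):
        d = dist_from(a)
        for j in range(i + 1, n):
            mat[i][j] = mat[j][i] = d[labels[j]]
    ref = labels[0]
    biparts = set()
    for a in adj:
        for b in adj[a]:
            if str(a) < str(b) and str(a).startswith("x") and str(b).startswith("x"):
                # leaves reachable from b avoiding a
                seen = {a, b}
                stack = [b]
                side = set()
                while stack:
                    u = stack.pop()
                    for v in adj[u]:
                        if v not in seen:
                            seen.add(v)
                            stack.append(v)
                            if not str(v).startswith("x"):
                                side.add(v)
                if ref in side:
                    side = set(labels) - side
                if 2 <= len(side) <= n - 2:
                    biparts.add(frozenset(side))
    return labels, mat, biparts


def brute_force_longest_orf(seq: str, min_len: int = 300):
    """Six-frame ORF enumeration: every (ATG .. stop) span, longest wins,
    ties prefer + strand then leftmost forward start."""
    stops = {"TAA", "TAG", "TGA"}
    best = None
    for strand, s in (("+", seq), ("-", rc(seq))):
        n = len(s)
        for start in range(0, n - 2):
            if s[start : start + 3] != "ATG":
                continue
            for j in range(start + 3, n - 2, 3):
                if s[j : j + 3] in stops:
                    span = j + 3 - start
                    if span >= min_len:
                        if strand == "+":
                            fwd = (start, j + 3)
                        else:
                            fwd = (n - (j + 3), n - start)
                        key = (-span, 0 if strand == "+" else 1, fwd[0])
                        if best is None or key < best[0]:
                            best = (key, (*fwd, strand))
                    break
    return None if best is None else best[1]
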