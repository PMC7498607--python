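"""Marker-assay genetic diversity statistics and NJ phylogeny.

Per-locus statistics over diploid fragment-size genotypes:

* expected heterozygosity (gene diversity)  He = 1 - sum_i p_i^2
* observed heterozygosity  Ho = fraction of non-missing individuals
  carrying two distinct alleles
* polymorphism information content (Botstein)
  PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2
* fixation index  F = 1 - Ho/He  (undefined when He = 0)

He deliberately carries no small-sample correction (plain gene
diversity); between-group differentiation is Nei's G_ST =
(H_T - H_S)/H_T with H_S the mean within-group He and H_T computed from
the unweighted mean of group allele frequencies, and between-group
distance is Nei's (1972) standard distance
D = -ln( J_xy / sqrt(J_x J_y) ). Trees are built by neighbor joining
(Saitou-Nei Q-criterion) from shared-allele dissimilarities between
individuals, with bootstrap supports from resampling loci with
replacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode

from .io_core import GenotypeTable


@dataclass(frozen=True)
class LocusStats:
    locus_id: str
    allele_freqs: dict[int, float]
    n_alleles: int
    he: float
    ho: float
    pic: float
    f: float | None


def allele_frequencies(
    gt: GenotypeTable, locus: str, individuals: list[str] | None = None
) -> dict[int, float]:
    inds = individuals if individuals is not None else gt.individuals
    counts: dict[int, int] = {}
    total = 0
    for ind in inds:
        call = gt.calls[(ind, locus)]
        if call is None:
            continue
        for allele in call:
            counts[allele] = counts.get(allele, 0) + 1
            total += 1
    if total == 0:
        return {}
    return {a: c / total for a, c in sorted(counts.items())}


def pic_from_freqs(freqs) -> float:
    p = np.asarray(list(freqs), dtype=float) if not isinstance(freqs, dict) else np.asarray(
        list(freqs.values()), dtype=float
    )
    p2 = p**2
    cross = (p2.sum() ** 2 - (p2**2).sum()) / 2.0  # sum_{i<j} p_i^2 p_j^2
    return float(1.0 - p2.sum() - 2.0 * cross)


def expected_heterozygosity(freqs) -> float:
    p = np.asarray(list(freqs.values()) if isinstance(freqs, dict) else list(freqs), dtype=float)
    return float(1.0 - (p**2).sum())


def locus_stats(gt: GenotypeTable, locus: str) -> LocusStats:
    freqs = allele_frequencies(gt, locus)
    if not freqs:
        raise ValueError(f"locus {locus!r} has no non-missing calls")
    n_typed = 0
    n_het = 0
    for ind in gt.individuals:
        call = gt.calls[(ind, locus)]
        if call is None:
            continue
        n_typed += 1
        if call[0] != call[1]:
            n_het += 1
    he = expected_heterozygosity(freqs)
    ho = n_het / n_typed
    return LocusStats(
        locus_id=locus,
        allele_freqs=freqs,
        n_alleles=len(freqs),
        he=he,
        ho=ho,
        pic=pic_from_freqs(freqs),
        f=(1.0 - ho / he) if he > 0 else None,
    )


def summarize_loci(gt: GenotypeTable) -> list[LocusStats]:
    return [locus_stats(gt, locus) for locus in gt.loci]


def nei_distance(gt: GenotypeTable, group_a: list[str], group_b: list[str]) -> float:
    """Nei (1972) standard genetic distance between two groups of
    individuals; +inf when the groups share no alleles at any locus."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    jx = jy = jxy = 0.0
    n_loci = 0
    for locus in gt.loci:
        fa = allele_frequencies(gt, locus, group_a)
        fb = allele_frequencies(gt, locus, group_b)
        if not fa or not fb:
            continue  # locus untyped in one group: drop from the means
        n_loci += 1
        jx += sum(p * p for p in fa.values())
        jy += sum(p * p for p in fb.values())
        alleles = set(fa) | set(fb)
        jxy += sum(fa.get(a, 0.0) * fb.get(a, 0.0) for a in alleles)
    if n_loci == 0:
        raise ValueError("no locus typed in both groups")
    jx, jy, jxy = jx / n_loci, jy / n_loci, jxy / n_loci
    if jxy == 0:
        return math.inf
    return -math.log(jxy / math.sqrt(jx * jy))


def gst(gt: GenotypeTable, groups: dict[str, list[str]]) -> float | None:
    """Multi-locus Nei G_ST over >= 2 groups; None when H_T == 0."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    hs_sum = ht_sum = 0.0
    n_loci = 0
    for locus in gt.loci:
        per_group = [allele_frequencies(gt, locus, inds) for inds in groups.values()]
        if any(not f for f in per_group):
            continue
        n_loci += 1
        hs_sum += float(np.mean([expected_heterozygosity(f) for f in per_group]))
        alleles = sorted(set().union(*per_group))
        pooled = [float(np.mean([f.get(a, 0.0) for f in per_group])) for a in alleles]
        ht_sum += expected_heterozygosity(pooled)
    if n_loci == 0:
        raise ValueError("no locus typed in every group")
    hs, ht = hs_sum / n_loci, ht_sum / n_loci
    if ht == 0:
        return None
    return (ht - hs) / ht


def shared_allele_distance(gt: GenotypeTable) -> DistanceMatrix:
    """1 - mean proportion of shared alleles between individuals, over
    loci typed in both; 1.0 when no locus is comparable."""
    inds = gt.individuals
    n = len(inds)
    d = np.zeros((n, n))
    calls = {
        ind: [gt.calls[(ind, locus)] for locus in gt.loci] for ind in inds
    }
    for i in range(n):
        for j in range(i + 1, n):
            sims = []
            for ca, cb in zip(calls[inds[i]], calls[inds[j]]):
                if ca is None or cb is None:
                    continue
                shared = 0
                b = list(cb)
                for a in ca:
                    if a in b:
                        shared += 1
                        b.remove(a)
                sims.append(shared / 2.0)
            d[i, j] = d[j, i] = 1.0 - (sum(sims) / len(sims)) if sims else 1.0
    return DistanceMatrix(d, ids=inds)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining (Saitou-Nei) with the Q-criterion.

    Negative branch lengths are clamped to 0 with the deficit moved to the
    sister edge; Q-ties break on the smallest (sorted) label pair. Returns
    an unrooted tree as a trifurcating :class:`~skbio.tree.TreeNode`.
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.data.astype(float).copy()
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    active = list(labels)
    dist = {
        (a, b): d[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }

    def get(a, b):
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    serial = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (m - 2) * get(a, b) - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best:
                    best = key
                    pick = (a, b)
        a, b = pick
        dab = get(a, b)
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent_name = f"_nj{serial}"
        serial += 1
        parent = TreeNode(name=None)
        ca, cb = nodes[a], nodes[b]
        ca.length = la
        cb.length = lb
        parent.append(ca)
        parent.append(cb)
        nodes[parent_name] = parent
        for c in active:
            if c in (a, b):
                continue
            dist[(parent_name, c)] = (get(a, c) + get(b, c) - dab) / 2.0
        active = [c for c in active if c not in (a, b)] + [parent_name]

    a, b, c = active
    dab, dac, dbc = get(a, b), get(a, c), get(b, c)
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    root = TreeNode(name=None)
    for lab, ln in ((a, la), (b, lb), (c, lc)):
        child = nodes[lab]
        child.length = max(ln, 0.0)
        root.append(child)
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Internal-edge bipartitions, each encoded as the canonical leaf side
    (the side not containing the alphabetically first leaf)."""
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(leaves) - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def bootstrap_nj(gt: GenotypeTable, reps: int, seed: int) -> TreeNode:
    """NJ tree of all individuals (shared-allele dissimilarity) with
    bootstrap supports (% of replicates, loci resampled with replacement)
    written as internal node names."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if len(gt.loci) < 2:
        raise ValueError("need at least 2 loci to bootstrap")
    rng = np.random.default_rng(seed)
    full = nj_tree(shared_allele_distance(gt))
    leaves = sorted(t.name for t in full.tips())
    ref = leaves[0]
    counts: dict[frozenset[str], int] = {}
    for _ in range(reps):
        sample = [gt.loci[i] for i in rng.integers(0, len(gt.loci), len(gt.loci))]
        rep_tree = nj_tree(shared_allele_distance(gt.subset_loci(sample)))
        for bp in bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(leaves) - side
        if 2 <= len(side) <= len(leaves) - 2:
            node.name = str(int(round(100.0 * counts.get(side, 0) / reps)))
    return full


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def write_stats_tsv(stats: list[LocusStats], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tn_alleles\the\tho\tpic\tf\n")
        for s in stats:
            f_str = "NA" if s.f is None else f"{s.f:.4f}"
            fh.write(
                f"{s.locus_id}\t{s.n_alleles}\t{s.he:.4f}\t{s.ho:.4f}\t{s.pic:.4f}\t{f_str}\n"
            )
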