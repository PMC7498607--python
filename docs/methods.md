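# Methods

`ssrmine` is a genome-wide microsatellite (SSR) marker-development toolkit:
it scans assemblies for perfect tandem repeats, designs and de-duplicates
primer pairs, predicts cross-taxa amplification by in silico PCR, assigns
genomic context, exports a searchable marker table, and computes
marker-assay diversity statistics with a bootstrap neighbor-joining tree.
This note records the models, parameter choices and numerical conventions
behind each stage, and what the synthetic test panel does and does not
demonstrate.

## Repeat scanning

A locus is a maximal perfect tandem repeat of a *primitive* motif (one
that is not itself a repetition of a shorter word) of length 1–6 nt.
Minimum repeat counts follow the classic MISA-style parameterization for
plant genome surveys: 12 (mono), 8 (di), 5 (tri), 5 (tetra), 4 (penta),
4 (hexa). Conventions:

* A run is reported at its smallest primitive motif length only
  (`AAAA…` is mono-A, never di-AA).
* A tract divisible at two motif phases is reported once, at the leftmost
  start of its maximal periodic stretch; `repeat_count` is
  `floor(stretch / motif length)` and trailing partial copies are dropped.
* Runs of N split a sequence into independent scanning windows, so no
  tract or motif ever contains N.
* Simple loci separated by at most `max_interruption` nt (default 100,
  the MISA default) merge into one compound locus that records its
  members.

Classification: class I = tract > 20 nt, class II ≤ 20 nt; base
composition by motif AT fraction (> 1/2 AT-rich, < 1/2 GC-rich, = 1/2
balanced). Motifs are grouped under a canonical representative — the
lexicographic minimum over all cyclic rotations of the motif and of its
reverse complement — so A/T, AAT/ATT, AAAT/ATTT each count as one group.

Landscape summaries report density (loci per Mbp of total assembly length,
N runs included) and the percentage of nucleotides inside tracts. Because
published totals are sensitive to whether a compound SSR counts once or as
its members, both conventions are available (`count_compound =
"single" | "members"`; default "single": each compound counts once and
its members are excluded from per-motif tables).

The scanner is validated against a brute-force oracle that tests every
(position, motif-length) pair on random sequences with planted repeats.

## Primer design

Flanks of up to 200 nt per side (truncated at contig ends and at the
nearest N run, with a flag) form the design template. The design emulates
the role a Primer3-with-defaults step plays in genome-scale marker
pipelines without reproducing Primer3's internals, which are deliberately
out of scope. Hard constraints (all configurable): primer length 18/20/27
(min/opt/max), GC 40–60 %, Tm 57/60/63 °C, pair ΔTm ≤ 3 °C, product size
100–300 bp spanning the full tract, homopolymer runs ≤ 4, and no
3'-terminal self-complementary stretch longer than 3 (checked as the
reverse complement of the 3'-terminal 4-mer occurring anywhere in the
primer). The penalty of an accepted primer is

    |len − 20| + |Tm − 60| + 0.5·|GC − 50|

and pairs are ranked by penalty sum, ties broken by smaller product then
leftmost forward start; at most three ranked pairs are kept per locus. An
empty result is a design failure and feeds the per-genome success rate.
The scorer is deliberately simple and auditable; there is no
thermodynamic dimer/hairpin model beyond the 3'-complementarity count.

Melting temperatures are nearest-neighbor values (SantaLucia & Hicks 2004
parameters via Biopython's `Tm_NN`) at fixed conditions — 50 mM monovalent
salt, 50 nM oligo, entropy salt correction — chosen once and frozen so
design is deterministic; the tests recompute Tm from a hand-typed copy of
the published ΔH/ΔS table.

## In silico PCR

A primer binds a site when the whole primer aligns to the target
(semi-global: primer global, target local) within independent budgets of
3 mismatches and 3 gap columns per primer. Three definitional rules,
shared by the implementation and the brute-force oracle in the tests:

1. **Exact 3'-anchored seed.** The primer's 3'-terminal `seed_word` bases
   (default 7) must match the target exactly, as in the classic e-PCR
   word. This is what gives the search its specificity: with only a
   single-base anchor, a random 20-mer hits random sequence within the
   3 + 3 budgets at a rate near 0.3 sites/kb/strand, which would flood
   every marker with chance amplicons.
2. **Internal gaps only.** The 5'-terminal primer base must align to a
   target base; gap columns can never trim a primer end.
3. **Canonical alignments.** An insertion column never sits adjacent to a
   deletion column — such a pair is a substitution and is billed as one
   mismatch, never as two gaps.

Even so, a semi-global alignment can legitimately absorb 5'-proximal
edits (deleting a substituted base converts a mismatch into a gap, and
the shifted 5' tail is short), so the synthetic panel destroys primer
sites by editing the 3'-seed region, where no rescue is possible.

Candidate anchors are located genome-wide and verified by a banded
dynamic program vectorized over all candidates, with per-step pruning of
dead candidates; per site the minimal (mismatches + gaps) alignment is
reported (ties prefer fewer gaps, then the smaller span offset). A site
whose cost is strictly beaten by a site of the same primer and strand
within `max_gaps` nt of its 3' end is suppressed, so a perfect match is
reported once rather than alongside one-off gapped echoes. Alignment
columns against N count as mismatches.

Amplicons are convergent forward/reverse site combinations on one
sequence; length is the inclusive 5'-to-5' span, so a pair re-applied to
its own template reproduces the designed product size exactly. Both
orientations are enumerated; products outside 50–2000 bp are dropped.

## Marker pipeline

Markers are named `EMM-<genome>-<serial>` with serials assigned in
(sequence, coordinate) order, so numbering is reproducible. Redundancy
filtering applies two separately switchable rules: exact duplicate
(forward, reverse) primer pairs keep the first locus by coordinate, and
markers whose rank-1 pair amplifies their own source genome more than
once are removed as non-specific. Identical primer pairs across genomes
collapse into one record listing all sources, with Venn-style membership
counts per genome subset.

A marker is polymorphic when any two observed amplicon lengths — the
source genome's expected size included — differ by at least 6 bp, the
resolution of agarose-gel scoring that the threshold models.
Transferability to a clade means presence (≥ 1 amplicon) in every clade
member. Comparative mapping assigns each marker with a unique amplicon in
a chromosome-level assembly to its chromosome (multi-hit markers are
flagged unplaced) and reports per-chromosome counts with their mean and
population standard deviation.

The exported table (TSV and an optional SQLite `markers` table with the
same fixed column order) is queryable by motif type, length class,
transferability, polymorphism and marker id. The per-pair annealing
temperature column is the limiting (lower) of the two primer Tm values.

## Diversity statistics

Per locus, over non-missing diploid calls: allele frequencies from
counts; expected heterozygosity He = 1 − Σp²; observed heterozygosity
Ho = fraction of heterozygous individuals; Botstein's polymorphism
information content PIC = 1 − Σp² − Σ_{i<j} 2p²ᵢp²ⱼ (always ≤ He);
fixation index F = 1 − Ho/He, reported missing when He = 0. He carries no
small-sample correction, matching the gene-diversity default of the
marker-analysis programs this emulates. Between groups: Nei's (1972)
standard distance D = −ln(J_xy/√(J_x J_y)) with J terms averaged over
loci typed in both groups (+∞ when no alleles are shared), and
multi-locus G_ST = (H_T − H_S)/H_T with H_S the mean within-group He and
H_T from the unweighted mean of group frequencies. Note that two groups
fixed for different alleles give G_ST = 1 by this formula.

Trees: neighbor joining (Saitou–Nei Q-criterion) implemented directly so
its numerical conventions are pinned — negative branch lengths are
clamped to zero with the deficit moved to the sister edge, and Q ties
break on the smallest sorted label pair; the scikit-bio NJ implementation
serves as an independent cross-check in the tests. Individual-level
distances for tree building are shared-allele dissimilarities (1 − mean
proportion of shared alleles over loci typed in both individuals).
Bootstrap supports resample loci with replacement and report the
percentage of replicates containing each internal bipartition of the
full-data tree; everything is seeded.

Allele sizes are exact fragment sizes in bp; no binning is applied.

## Synthetic study panel

`presets.four_landraces` emulates the study layout at desk scale: a base
landrace assembly (2 contigs × 15 kb) with 14 planted SSRs spanning
mono–hexa motifs and both length classes, one duplicated cassette (a
genuine multi-hit case), a GFF3 annotation placing loci in 5'UTR, CDS,
intron and 3'UTR, three derived landraces with tract expansions or
contractions (±1–5 repeat units, i.e. ±2–12 bp, straddling the 6 bp
polymorphism rule) and seed-region primer-site substitutions, a diverged
chromosome-level outgroup in which most primer sites are destroyed, and a
two-group diploid assay (20 + 8 individuals × 10 loci) with stated
generating frequencies. Backgrounds are i.i.d. uniform ACGT,
rejection-resampled until scanner-clean, so the plant manifest predicts
scanner output, the e-PCR matrix, polymorphism calls and allele-frequency
expectations exactly.

What the panel does not model: transposable-element and low-complexity
background, assembly gaps and mis-joins, chromosome-scale structure,
realistic divergence processes, or genotyping error. Passing tests
demonstrate the correctness of the algorithms under their stated
definitions, not field performance on real assemblies; on real genomes,
background repetitiveness will raise redundancy and multi-hit rates well
above the panel's values.

Problem sizes throughout (genome lengths, marker counts, 200 bootstrap
replicates, 500-individual recovery checks) were chosen as the smallest
panels at which every stage is exercised and Monte-Carlo checks are
stable.

## Known limitations

* Primer design is a documented stand-in for Primer3, so success rates
  and primer sets are not comparable run-for-run with Primer3-based
  pipelines.
* The e-PCR engine predicts site existence, not amplification
  efficiency; degenerate-base primers are unsupported.
* ORF-based context is a single-ORF heuristic (default minimum 300 nt,
  stop included), not gene prediction; with annotation, a locus
  overlapping only an exon of a non-coding transcript is binned with
  introns as non-coding genic.
* Genotype tables are strictly diploid.
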