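# ssrmine

Genome-wide microsatellite discovery and marker development for plant
genome surveys: scan assemblies for SSRs, characterize the repeat
landscape, design and de-duplicate primer pairs, predict cross-taxa
transferability and length polymorphism by in silico PCR, assign genomic
context, export a searchable marker table, and validate markers with
population-genetic statistics and a bootstrap NJ tree.

It is aimed at researchers developing SSR marker panels for crops with
several available assemblies but little existing marker infrastructure —
the motivating case being clonally propagated landraces of a neglected
crop, where cheap PCR + agarose markers are still the practical
genotyping technology.

## What it computes

* **SSR scan** — all maximal perfect tandem repeats of primitive motifs
  (1–6 nt) at minimum repeat counts 12/8/5/5/4/4 (mono…hexa); class I
  (tract > 20 nt) vs class II; AT-rich / GC-rich / balanced motifs;
  canonical motif groups (rotation + reverse-complement equivalence);
  compound SSRs (interruption ≤ 100 nt); density per Mbp and genome
  fraction.
* **Primer design** — up to 3 ranked pairs per locus from 200 nt flanks
  under length/GC/Tm/product constraints, penalty
  `|len−20| + |Tm−60| + 0.5|GC−50|`, nearest-neighbor Tm at 50 mM Na⁺ /
  50 nM oligo.
* **e-PCR** — binding sites within 3 mismatches and 3 gaps per primer,
  exact 3'-anchored 7-mer seed; amplicons as convergent site pairs,
  50–2000 bp. Markers are *polymorphic* when predicted amplicon lengths
  differ by ≥ 6 bp and *transferable* to a clade when they amplify every
  member.
* **Diversity** — He = 1 − Σp², Ho, Botstein PIC, F = 1 − Ho/He, Nei
  (1972) distance, G_ST, and a bootstrap neighbor-joining tree from
  shared-allele distances.

See `docs/methods.md` for every convention and default.

## Worked example

Generate a seeded synthetic panel (four landrace genomes with planted
SSRs, a diverged outgroup, and a two-group genotype assay), then run the
stages:

```sh
ssrmine fixtures --preset four-landraces --seed 5 --small --out-dir fx/
ssrmine scan   --fasta fx/landrace_a.fa --out loci.tsv --summary summary.json
ssrmine design --loci loci.tsv --fasta fx/landrace_a.fa --out primers.tsv
ssrmine diversity --genotypes fx/genotypes.tsv --bootstrap 50 --seed 3 \
    --out-stats stats.tsv --out-tree tree.nwk
```

which prints

```
6 loci written to loci.tsv
designed 6/6 loci (Tm at 50 mM Na+, 50 nM oligo)
stats -> stats.tsv; tree (50 bootstrap reps) -> tree.nwk
```

`loci.tsv` starts

```
seq_id   start_1based  end_1based  motif  canonical_motif  repeat_count  tract_length  class  composition  compound_flag
contig1  601           614         A      A                14            14            II     AT_RICH      0
contig1  1401          1424        AG     AG               12            24            I      BALANCED     0
```

— the planted mono-A ×14 (14 nt, class II) and (AG)×12 (24 nt, class I)
loci at their planted coordinates. `primers.tsv` carries ranked pairs,
e.g. rank 1 for the AG locus: forward `TCGGTCAACGAAAACCAACGGT`
(Tm 58.99 °C), reverse `ATCATTCGGCAAGCGGTTTAGC` (Tm 57.99 °C), product
294 bp — re-amplifying the source template at exactly 294 bp with zero
mismatches. `stats.tsv` begins

```
locus_id  n_alleles  he      ho      pic     f
L01       5          0.7302  0.7143  0.6935  0.0218
```

i.e. locus L01 segregates 5 alleles with gene diversity 0.73 and near-HW
heterozygosity (F ≈ 0.02).

The whole pipeline (scan → design → dedupe → cluster → e-PCR → calls →
export) runs as one command:

```sh
ssrmine run-all --fasta landrace_a=fx/landrace_a.fa --fasta landrace_b=fx/landrace_b.fa \
    --target-fasta musa_like=fx/musa_like.fa --map-taxon musa_like --out-dir out/
```

producing `out/emm.tsv` + `out/emm.sqlite` (the marker table, queryable
by motif type, class, transferability, polymorphism and id) and
`out/summary.json` with success rates, redundancy, Venn membership and
per-chromosome mapping counts.

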