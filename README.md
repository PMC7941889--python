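# cmline

Discovery and triage of **structured noncoding-RNA motif candidates** by
comparative genomics, at desk scale.

Functional RNAs — riboswitches, ribozymes, snRNAs, structured UTR elements —
are conserved at the level of their base-paired *secondary structure* more
than their sequence. The telltale signal is **covariation**: two homologous
sequences differ at both positions of a base pair, yet both variants still
form a canonical Watson–Crick (A-U, G-C) or wobble (G-U) pair. `cmline`
implements the computational stages of a covariance-model-driven discovery
pipeline for such motifs in large annotated genomes:

1. **Extract** intergenic regions (IGRs) and introns from genome FASTA +
   GFF3, honoring soft-masking of repeats;
2. **Cluster** similar noncoding sequences by single-linkage over pairwise
   similarity hits (external BLAST outfmt-6 tables, or a built-in
   word-seeded aligner with Karlin–Altschul E-values, default cutoff
   E ≤ 1e-6 at word size 7);
3. **Filter** known RNAs/repeats (library hits at E ≤ 1e-9) and likely
   protein-coding clusters (coding-potential P < 0.001);
4. **Classify** every consensus base pair of a structure-annotated
   (Stockholm/WUSS) alignment as *covarying*, *compatible*, *conserved* or
   *unsupported*, and assign a **permutation E-value** to each pair via a
   G-test of the two columns' joint residue table against a
   column-shuffled null (significance at E < 0.05);
5. **Triage** motifs by structural complexity (stems, hairpins, bulges,
   internal loops, multiloops), representation across species, and
   covariation support, with a configurable rank score;
6. **Scan** for functional elements: poly(A)-signal hexamers (AAUAAA /
   AUUAAA) and conserved unpaired segments that are candidate
   protein-binding sites.

A seeded **simulator** generates structured-RNA families evolved with
compensatory substitutions (mutate one side of a pair, restore the partner
with probability `compensation_prob`, G-U allowed as intermediate) and toy
annotated genomes with planted motif families, so every stage is testable
with known ground truth and no downloads.

Covariance-model induction and homolog search themselves (CMfinder,
Infernal, R-scape, RNAcode, BLAST, WindowMasker) are **not** re-implemented:
the pipeline consumes their input/output formats and provides clearly
labeled desk-scale substitutes where needed.

## Worked example

Simulate a 30-sequence family on a two-hairpin structure, analyze its
covariation, and triage it:

```sh
cmline simulate aln --n-seqs 30 --seed 11 --out family.sto
cmline analyze --stockholm family.sto --n-perm 1000 --seed 42 --out pairs.tsv
cmline triage  --stockholm family.sto --n-perm 1000 --seed 42 --out-dir triage-out
```

`analyze` prints a category summary and writes one row per annotated pair:

```
{"covarying": 10, "compatible": 0, "conserved": 0, "unsupported": 0, "insufficient": 0, "significant": 10}

i   j   category   canonical_fraction  pairtype_counts                 statistic  evalue   significant
0   13  covarying  1.000               AU:15,CG:2,GC:3,GU:3,UA:5,UG:2  49.5485    0.00999  true
1   12  covarying  0.967               AU:13,CG:1,GC:4,GG:1,GU:4,...   41.6294    0.00999  true
```

All ten planted pairs show multiple canonical pair types differing on both
sides (*covarying*), each with a G statistic far above the permutation null
(E ≈ 0.01 < 0.05). The triage report:

```
family  [PASS]  rank_score=36.91
  significant covariations: 10 (need >= 1)
  stems: 2 (need >= 2)
  representatives: 30 sequences (need >= 10), 30 species (need >= 5)
  pair support: 10 covarying, 0 compatible, 0 conserved, 0 unsupported
```

The motif passes every screening criterion: significant covariation,
several stems, and wide representation.

An end-to-end run over genomes is driven by a JSON config:

```sh
cmline simulate genome --n-species 5 --seed 7 --out-dir toy/
cmline run --config config.json --seed 7
```

which executes extract → cluster → filter → analyze → triage → elements and
writes a manifest of per-stage counts beside the outputs.

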