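# Methods

## Scope and model

`cmline` targets the comparative-genomics signature of structured RNA:
conserved base pairing maintained by compensatory evolution. The unit of
analysis is a structure-annotated multiple alignment (Stockholm with a WUSS
`#=GC SS_cons` line); upstream of that, the package enumerates the
noncoding search space (IGRs and introns), clusters homologous candidates,
and removes known RNAs and likely coding sequence. Covariance-model
induction (CMfinder), homolog search (Infernal), tree-aware covariation
statistics (R-scape), coding-potential scoring (RNAcode) and repeat masking
(WindowMasker) are consumed through their file formats, not re-implemented;
where a self-contained run needs a stand-in (the built-in pairwise aligner,
the stub discovery mode) it is a simplified, clearly labeled substitute.

## Coordinates and alphabets

Internally all coordinates are 0-based half-open; GFF3 and BED keep their
native conventions and are converted exactly once at I/O. Residues are
normalized to uppercase RNA (T→U) on read; soft-masking (lowercase) is
retained as a parallel boolean track rather than in the residue string, so
pairing logic sees a single alphabet. Ambiguity codes are kept but treated
as non-canonical: a row contributes to a pair's statistics only if both
positions are in {A,C,G,U}.

## Region extraction

Introns are the gaps between consecutive (merged) exons of each transcript;
IGRs are the per-chromosome complement of the union of outermost gene
spans, with orphan transcripts treated as genes to tolerate annotation
dialects. Both are filtered at `min_len` 50 nt — below that a structured
motif of the kind sought here is implausible. IGRs are emitted once on the
'+' strand; the reverse complement is considered during pairwise search
instead. Mask policy for harvesting defaults to *drop* regions more than
50% soft-masked and hard-mask (N) the rest, which keeps repeat-derived
sequence out of seeding without discarding lightly masked regions.

## Built-in pairwise search and clustering

The built-in aligner is a word-seeded (default word size 7), ungapped
X-drop extension with blastn-like +2/−3 scoring. Significance uses the
Karlin–Altschul form E = K·m·n·e^{−λS}: λ is solved exactly from
Σ pᵢpⱼe^{λsᵢⱼ} = 1 (scipy brentq, uniform background), while K — which has
no closed form — is fixed at 0.35, a value in the range typical for this
scoring regime; K shifts E by a constant factor that is small against the
1e-6 cutoff. Gapped extension is omitted: external outfmt-6 tables from a
real aligner are the faithful path for serious use, and the simulator
plants ungapped families. Clusters are single-linkage connected components
(one passing hit in either direction makes an edge), minimum size 3 —
fewer sequences cannot exhibit covariation. Cluster ids derive from the
smallest member id, making the output invariant to input order.

The known-RNA filter removes *members* with any library hit at E ≤ 1e-9
and drops a cluster only when it falls below the minimum size — the least
destructive reading of library-based cleanup. The coding filter removes
whole clusters with coding-potential P < 0.001 (small P = evidence of
coding); clusters without a P-value are retained and flagged "untested".

## Pair classification

For each annotated pair, rows with a gap or ambiguity at either position
are excluded; if fewer than 2 rows remain, or more than half were
excluded, the verdict is *insufficient* (no verdict from tiny subsets).
The canonical set is {AU, UA, CG, GC, GU, UG} — wobble counts both toward
the canonical fraction and as a distinct pair type. With canonical
fraction ≤ 0.9 (the rule is strictly "more than 90%") the pair is
*unsupported*. Otherwise: *covarying* if two observed canonical pair types
differ at **both** positions, *compatible* if at least two canonical types
exist (one-sided changes such as A-U → G-U), else *conserved*. This
descriptive category and the permutation E-value below are kept as two
separate outputs; neither overwrites the other.

## Permutation significance test

Per pair, the statistic is the G-test (likelihood-ratio) statistic of the
4×4 joint residue table of the two columns against independence, over
included rows. The null is built by independently permuting every analyzed
column across rows `n_perm` times (default 1000), pooling statistics over
all annotated pairs to stabilize the tail. The empirical p-value uses the
add-one rule on the average per-pair exceedance count,

    p = (1 + #{null ≥ observed} / n_pairs) / (1 + n_perm),

which reduces to the standard add-one permutation p-value when a single
pair is tested, guarantees p > 0, and keeps p ≤ 1. The E-value is the
Bonferroni scale-up p × n_pairs, capped at n_pairs; significance is
E < 0.05. Constant columns give statistic 0 and the cap.

The null treats rows as exchangeable and is therefore **anti-conservative
for phylogenetically clustered alignments** — shared ancestry alone can
produce joint patterns the column shuffle never generates. A
`collapse_duplicates` option removes identical rows before testing; it is
off by default because representative counts deliberately keep duplicates.
For publication-grade significance a tree-aware method should be used; the
calibration results here hold under the simulator's star tree, where
exchangeability is true.

## Structure statistics and screening

Loop decomposition uses layer-0 (nested) pairs only: a stem is a maximal
run of stacked pairs; each pair's direct children classify its loop as
hairpin (none), bulge/internal (one, offset on one/both sides), or
multiloop (two or more). Pseudoknot pairs (WUSS letters) are parsed,
classified for covariation, and reported via `has_pseudoknot`, but stay out
of the loop taxonomy.

Screening defaults — at least 1 significant covariation, 2 stems, 10
sequences, 5 species — quantify a selection that was originally manual;
"several stem-loops" becomes `min_stems 2`, chosen so single-hairpin motifs
fail the screen yet remain visible in the report rather than being silently
dropped. The rank score

    2·n_significant + 1·n_covarying + 0.5·n_compatible + 1·n_stems + log2(max(n_species, 1))

is an explicit heuristic (weights configurable); ties break
deterministically by motif id.

## Functional elements

The PAS scan reports every overlapping occurrence of AAUAAA/AUUAAA (the
two variants that dominate real PAS usage); the common 12-variant extended
set is available but off by default. Conserved segments are maximal runs of
≥ 5 columns whose majority residue reaches 90% of **all** rows — gaps count
in the denominator, penalizing gappy columns — annotated with the fraction
of base-paired columns from the consensus structure.

## Simulator

`evolve_alignment` draws a root consistent with the structure (paired sites
canonical), then per branch substitutes each site with probability
`subst_rate` (uniform over the 3 alternatives; no transition bias — an
intentional simplification). At a paired site the partner is co-substituted
to a canonical partner with probability `compensation_prob`, G-U included,
reproducing the compensatory pathway between G-C and A-U through the
wobble intermediate. With `compensation_prob` 1 every pair stays 100%
canonical by construction. The default tree is a star, making rows
exchangeable so the permutation null's assumption holds exactly in
calibration tests; a random-binary mode exists to demonstrate the
anti-conservativeness documented above. Indels default to off (gap handling
is tested by post-hoc gap injection, keeping pair ground truth
unambiguous). Ground truth marks a planted pair "detectable" when its
realized columns contain ≥ 2 canonical pair types — a pair that never
varied cannot show covariation no matter the method.

`make_toy_genome` plants one family instance per species inside an intron
(or IGR) of random background genomes with annotated two-exon genes. The
default planted family is three hairpins (~74 nt) at branch substitution
rate 0.08 — about 15–25% divergence between leaves, comparable to a
metazoan-wide structured motif and within reach of the E ≤ 1e-6 cutoff.
Background streams are spawned from a `SeedSequence` so they are
independent of each other and of the family simulator even when seeds
coincide. Occasionally a leaf drifts far enough (~30% divergence) that its
instance falls below the E ≤ 1e-6 detectability of an ungapped
word-seeded search; recovery rates below 100% in such runs reflect that
detection limit, not a clustering fault.

What the simulations do **not** emulate: realistic phylogenies with rate
variation, indel evolution within motifs, repeat families, GC-content
heterogeneity, and alignment error. Passing tests therefore demonstrate
correctness of the machinery under the stated generative model, not
performance on real genomes.

## Problem sizes

The bundled analyses use desk-scale sizes chosen to exercise every code
path with stable statistics: 30-row alignments with 10 annotated pairs,
1000 (power) or 400 (calibration, 200 replicates) permutations, and
5-species toy genomes of 6 kb. All randomness flows from explicit seeds
through `numpy.random.Generator`; identical seeds give identical outputs,
including the end-to-end manifest hash.

## Known limitations

- The permutation E-value is not an R-scape replacement: no tree-aware
  null, no APC-corrected statistics, no fold-and-retest mode.
- The built-in aligner is ungapped and single-hit seeded; use external hit
  tables for anything beyond simulated or very similar sequences.
- Stub discovery stacks equal-length cluster members instead of inferring
  an alignment and structure; it exists to make the workflow exercisable
  end to end, not to discover motifs.
- Printed per-motif covariation counts in the source figures allow manual
  curation; a fixed rule cannot be expected to reproduce them exactly.
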