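"""Synthetic data with known ground truth.

Two generators back the test strategy:

- :func:`evolve_alignment` evolves a structured-RNA family on a star (or
  random binary) tree with compensatory substitutions at paired sites —
  when one side of a pair mutates, the partner is co-substituted to restore
  a canonical pair (G-U permitted as intermediate) with a tunable
  probability.  This gives alignments where the truly covarying pairs are
  known by construction, for power and type-I calibration of the
  covariation test.

- :func:`make_toy_genome` builds small annotated genomes with multi-exon
  genes and one homologous motif instance planted per species, for
  end-to-end extraction -> clustering -> filtering tests.

All randomness flows from a mandatory seed through ``numpy`` Generators;
identical seed + parameters give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import Alignment, CmlineError, Feature, SeqRecord, parse_wuss

__all__ = ["SimulationParams", "ToyGenome", "evolve_alignment", "make_toy_genome",
           "hairpin_structure", "default_family"]

_RNA = "ACGU"
#: canonical partners, wobble included (the G-U intermediate of the
#: compensatory pathway between G-C and A-U)
_PARTNERS = {"A": "U", "C": "G", "G": "CU", "U": "AG"}
_CANONICAL = {"AU", "UA", "CG", "GC", "GU", "UG"}


def hairpin_structure(n_stems: int, stem_len: int = 5, loop_len: int = 4,
                      spacer: int = 3) -> str:
    """WUSS string of ``n_stems`` hairpins separated by unpaired spacers."""
    hp = "<" * stem_len + "." * loop_len + ">" * stem_len
    return ("." * spacer).join([hp] * n_stems)


@dataclass(frozen=True)
class SimulationParams:
    """Settings for the compensatory-evolution simulator.

    ``subst_rate`` is the per-site substitution probability per branch;
    ``compensation_prob`` is the probability that a substitution at a paired
    site is accompanied by a partner change restoring a canonical pair.
    """

    n_seqs: int = 30
    structure: str = hairpin_structure(2)
    subst_rate: float = 0.3
    compensation_prob: float = 0.95
    indel_rate: float = 0.0
    tree: str = "star"  # or "random-binary"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seqs < 2:
            raise CmlineError("n_seqs must be >= 2")
        for name in ("subst_rate", "compensation_prob", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CmlineError(f"{name} must be in [0, 1], got {v}")
        if self.tree not in {"star", "random-binary"}:
            raise CmlineError(f"unknown tree model {self.tree!r}")


def _root_sequence(pairs: list[tuple[int, int]], length: int,
                   rng: np.random.Generator) -> list[str]:
    seq = [_RNA[k] for k in rng.integers(0, 4, size=length)]
    for i, j in pairs:
        seq[j] = _PARTNERS[seq[i]][rng.integers(0, len(_PARTNERS[seq[i]]))]
    return seq


def _evolve_branch(seq: list[str], partner: dict[int, int], rate: float,
                   comp: float, rng: np.random.Generator) -> list[str]:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() >= rate:
            continue
        current = out[i]
        alternatives = [b for b in _RNA if b != current]
        out[i] = alternatives[rng.integers(0, 3)]
        j = partner.get(i)
        if j is not None and rng.random() < comp:
            choices = _PARTNERS[out[i]]
            out[j] = choices[rng.integers(0, len(choices))]
    return out


def evolve_alignment(params: SimulationParams) -> tuple[Alignment, dict]:
    """Simulate a structured-RNA family; returns (alignment, ground truth).

    The truth dict records the planted structure and, per pair, whether the
    realized columns contain at least two distinct canonical pair types
    (the precondition for a pair to be detectable as covarying at all).
    """
    pt = parse_wuss(params.structure)
    pairs = list(pt.pairs)
    partner = {}
    for i, j in pairs:
        partner[i], partner[j] = j, i
    length = pt.length
    rng = np.random.default_rng(params.seed)
    root = _root_sequence(pairs, length, rng)

    leaves: list[list[str]] = []
    if params.tree == "star":
        for _ in range(params.n_seqs):
            leaves.append(_evolve_branch(root, partner, params.subst_rate,
                                         params.compensation_prob, rng))
    else:
        # random binary tree by sequential attachment; every edge gets one
        # branch's worth of substitutions, so leaf depths vary
        lineages = [root, _evolve_branch(root, partner, params.subst_rate,
                                         params.compensation_prob, rng)]
        while len(lineages) < params.n_seqs:
            k = int(rng.integers(0, len(lineages)))
            lineages.append(_evolve_branch(lineages[k], partner,
                                           params.subst_rate,
                                           params.compensation_prob, rng))
        leaves = [_evolve_branch(l, partner, params.subst_rate,
                                 params.compensation_prob, rng)
                  for l in lineages[:params.n_seqs]]

    if params.indel_rate > 0:
        for leaf in leaves:
            for i in range(length):
                if rng.random() < params.indel_rate:
                    leaf[i] = "-"

    rows = []
    for k, leaf in enumerate(leaves, 1):
        species = f"sp{k:04d}"
        rows.append(SeqRecord(f"{species}/1-{length}", "".join(leaf),
                              species=species))
    aln = Alignment(rows, params.structure,
                    metadata={"ID": "simulated-family"})

    pair_truth = []
    for i, j in pairs:
        types = {
            r.residues[i] + r.residues[j]
            for r in rows
            if r.residues[i] + r.residues[j] in _CANONICAL
        }
        pair_truth.append({"pair": (i, j), "n_canonical_types": len(types),
                           "detectable": len(types) >= 2})
    truth = {"structure": params.structure, "pairs": pair_truth}
    return aln, truth


# ---------------------------------------------------------------------------
# Toy genomes with planted motif families
# ---------------------------------------------------------------------------

def default_family(seed: int = 0) -> SimulationParams:
    """A realistic planted family for toy genomes: three hairpins (~74 nt),
    moderate divergence (~16% between any two leaves on the star tree), well
    within reach of the E<=1e-6 similarity cutoff — comparable to the 70-200 nt
    structured motifs the pipeline targets."""
    return SimulationParams(
        structure=hairpin_structure(3, stem_len=8, loop_len=6, spacer=4),
        subst_rate=0.08,
        compensation_prob=0.9,
        seed=seed,
    )

@dataclass
class ToyGenome:
    """Per-species genomes + annotations + coordinates of planted motifs."""

    genomes: dict[str, dict[str, str]]  # species -> {seqid: sequence}
    features: dict[str, list[Feature]]  # species -> GFF features
    truth: list[dict] = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for species, chroms in self.genomes.items():
            with open(outdir / f"{species}.fa", "w") as fh:
                for seqid, seq in chroms.items():
                    fh.write(f">{seqid}\n")
                    for k in range(0, len(seq), 70):
                        fh.write(seq[k:k + 70] + "\n")
            with open(outdir / f"{species}.gff3", "w") as fh:
                fh.write("##gff-version 3\n")
                for f in self.features[species]:
                    attrs = ";".join(f"{k}={v}" for k, v in f.attrs.items())
                    fh.write(f"{f.seqid}\tsim\t{f.type}\t{f.start}\t{f.end}"
                             f"\t.\t{f.strand}\t.\t{attrs}\n")


def _gene_features(seqid: str, gene_id: str, start: int, end: int,
                   exon_len: int) -> list[Feature]:
    """A two-exon gene occupying [start, end) (0-based half-open input)."""
    feats = [
        Feature(seqid, "gene", start + 1, end, "+", {"ID": gene_id}),
        Feature(seqid, "mRNA", start + 1, end, "+",
                {"ID": f"{gene_id}.t1", "Parent": gene_id}),
        Feature(seqid, "exon", start + 1, start + exon_len, "+",
                {"ID": f"{gene_id}.e1", "Parent": f"{gene_id}.t1"}),
        Feature(seqid, "exon", end - exon_len + 1, end, "+",
                {"ID": f"{gene_id}.e2", "Parent": f"{gene_id}.t1"}),
    ]
    return feats


def make_toy_genome(
    n_species: int = 5,
    genome_len: int = 6000,
    planted_family: SimulationParams | None = None,
    seed: int = 0,
    placement: str = "intron",
) -> ToyGenome:
    """Random background genomes with annotated genes and one planted motif
    instance per species (in an intron or an IGR).

    The planted family is evolved with :func:`evolve_alignment` (indels
    forced off so instances align without gaps); the truth table records
    each instance's genomic coordinates.
    """
    if planted_family is not None:
        planted_family = SimulationParams(
            n_seqs=n_species,
            structure=planted_family.structure,
            subst_rate=planted_family.subst_rate,
            compensation_prob=planted_family.compensation_prob,
            indel_rate=0.0,
            tree=planted_family.tree,
            seed=planted_family.seed,
        )
        family, _ = evolve_alignment(planted_family)
        motif_len = family.width
    else:
        family, motif_len = None, 0
    if placement not in {"intron", "IGR"}:
        raise CmlineError(f"unknown placement {placement!r}")

    exon_len, gene_len = 120, 1200
    gene1_start = genome_len // 10
    gene2_start = (genome_len * 6) // 10
    if gene2_start + gene_len >= genome_len or motif_len > gene_len - 2 * exon_len - 40:
        raise CmlineError("genome_len too small to host genes and planted motif")

    genomes: dict[str, dict[str, str]] = {}
    features: dict[str, list[Feature]] = {}
    truth: list[dict] = []
    # spawned child streams: backgrounds are independent of each other AND of
    # the family simulator's stream even when the two seeds coincide
    child_seeds = np.random.SeedSequence(seed).spawn(n_species)
    for idx in range(n_species):
        species = f"sp{idx + 1:04d}"
        seqid = f"{species}_chr1"
        rng = np.random.default_rng(child_seeds[idx])
        seq = list("ACGT"[k] for k in rng.integers(0, 4, size=genome_len))
        feats = []
        feats += _gene_features(seqid, f"{species}_g1", gene1_start,
                                gene1_start + gene_len, exon_len)
        feats += _gene_features(seqid, f"{species}_g2", gene2_start,
                                gene2_start + gene_len, exon_len)
        if family is not None:
            insert = family.rows[idx].ungapped.replace("U", "T")
            if placement == "intron":
                intron_start = gene1_start + exon_len
                intron_end = gene1_start + gene_len - exon_len
                pos = intron_start + (intron_end - intron_start - len(insert)) // 2
            else:
                igr_start = gene1_start + gene_len
                pos = igr_start + (gene2_start - igr_start - len(insert)) // 2
            seq[pos:pos + len(insert)] = list(insert)
            truth.append({"species": species, "seqid": seqid, "start": pos,
                          "end": pos + len(insert), "strand": "+",
                          "placement": placement})
        genomes[species] = {seqid: "".join(seq)}
        features[species] = feats
    return ToyGenome(genomes, features, truth)
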