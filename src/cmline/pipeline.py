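"""End-to-end orchestration: extract -> cluster -> filter -> (motif-discovery
hand-off) -> covariation analysis -> triage -> functional elements.

Covariance-model discovery (CMfinder) and homolog search (Infernal) are an
explicit hand-off point: the pipeline emits per-cluster FASTA files where
their inputs begin and re-enters at Stockholm ingestion.  A ``stub_discovery``
mode bridges the gap for self-contained runs by stacking each surviving
cluster's equal-length members into an alignment with a caller-supplied
consensus structure.

Every run writes its resolved configuration and a manifest of per-stage
counts beside the outputs; identical config + seed reproduce an identical
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import cluster_filter, covariation, functional_elements, genome_prep, triage
from .io_formats import (
    Alignment,
    CmlineError,
    SeqRecord,
    read_fasta,
    read_gff,
    read_hits_table,
    read_stockholm,
    write_bed,
    write_fasta,
)

logger = logging.getLogger("cmline")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run.

    Threshold defaults follow the published screen: all-vs-all similarity at
    E <= 1e-6 (word size 7), known-RNA removal at E <= 1e-9, coding-potential
    removal at P < 0.001, covariation significance at E < 0.05.
    """

    genomes: list[dict] = field(default_factory=list)  # {"fasta":…, "gff":…}
    alignments: list[str] = field(default_factory=list)  # Stockholm re-entry
    outdir: str = "cmline-run"
    seed: int = 0
    min_len: int = 50
    mask_policy: str = "drop"
    word_size: int = 7
    cluster_evalue: float = 1e-6
    min_cluster_size: int = 3
    library_hits: str | None = None
    known_evalue: float = 1e-9
    coding_pvalues: str | None = None
    coding_cutoff: float = 0.001
    stub_discovery: bool = False
    stub_structure: str | None = None
    n_perm: int = 1000
    evalue_threshold: float = 0.05
    min_significant: int = 1
    min_stems: int = 2
    min_sequences: int = 10
    min_species: int = 5
    threads: int = 1  # accepted for interface parity; computation is single-threaded

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _cluster_alignment(cluster, records: dict[str, SeqRecord],
                       structure: str | None) -> Alignment | None:
    """Stub discovery: stack equal-length cluster members as an alignment."""
    members = [records[m] for m in cluster.members if m in records]
    if len(members) < 3:
        return None
    width = len(members[0].residues)
    if any(len(m.residues) != width for m in members):
        logger.warning("cluster %s members differ in length; stub discovery skipped",
                       cluster.id)
        return None
    ss = structure if structure and len(structure) == width else "." * width
    return Alignment(list(members), ss, metadata={"ID": cluster.id})


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(json.dumps(asdict(config), indent=2) + "\n")
    manifest: dict = {"stages": {}, "seed": config.seed}

    if not config.genomes and not config.alignments:
        raise CmlineError("no inputs: provide genomes and/or alignments")

    # ---- extract + harvest -------------------------------------------------
    records: list[SeqRecord] = []
    all_regions = []
    for entry in config.genomes:
        features = read_gff(entry["gff"])
        genome = {
            rec.id: "".join(
                c.lower() if m else c
                for c, m in zip(rec.residues, rec.masked or [False] * len(rec.residues))
            )
            for rec in read_fasta(entry["fasta"])
        }
        seq_lengths = {k: len(v) for k, v in genome.items()}
        regions = genome_prep.extract_introns(features, config.min_len)
        regions += genome_prep.extract_igrs(features, seq_lengths, config.min_len)
        all_regions += regions
        records += genome_prep.harvest_sequences(genome, regions, config.mask_policy)
    if config.genomes:
        write_bed(all_regions, outdir / "regions.bed")
        write_fasta(records, outdir / "noncoding.fa")
    manifest["stages"]["regions"] = len(all_regions)
    manifest["stages"]["harvested"] = len(records)

    # ---- cluster + filter --------------------------------------------------
    clusters = []
    if len(records) >= 2:
        params = cluster_filter.AlignerParams(
            word_size=config.word_size, evalue_cutoff=config.cluster_evalue
        )
        hits = cluster_filter.pairwise_hits(records, params)
        clusters = cluster_filter.build_clusters(hits, config.min_cluster_size)
        manifest["stages"]["pairwise_hits"] = len(hits)
    manifest["stages"]["clusters"] = len(clusters)

    if config.library_hits:
        clusters = cluster_filter.filter_known(
            clusters, read_hits_table(config.library_hits),
            config.known_evalue, config.min_cluster_size,
        )
    manifest["stages"]["after_known_rna_filter"] = len(clusters)

    if config.coding_pvalues:
        clusters = cluster_filter.filter_coding(
            clusters, cluster_filter.read_pvalue_table(config.coding_pvalues),
            config.coding_cutoff,
        )
    manifest["stages"]["after_coding_filter"] = len(clusters)

    by_id = {r.id: r for r in records}
    cluster_dir = outdir / "clusters"
    if clusters:
        cluster_dir.mkdir(exist_ok=True)
        for cl in clusters:
            fname = re.sub(r"[^A-Za-z0-9._-]", "_", cl.id)
            write_fasta([by_id[m] for m in cl.members if m in by_id],
                        cluster_dir / f"{fname}.fa")
        (outdir / "filter_log.json").write_text(json.dumps(
            [{"cluster": c.id, "members": c.members,
              "log": [list(e) for e in c.filter_log]} for c in clusters],
            indent=2) + "\n")

    # ---- motif-discovery hand-off ------------------------------------------
    alignments: list[tuple[str, Alignment]] = []
    for path in config.alignments:
        aln = read_stockholm(path)
        alignments.append((aln.metadata.get("ID", Path(path).stem), aln))
    if config.stub_discovery:
        for cl in clusters:
            aln = _cluster_alignment(cl, by_id, config.stub_structure)
            if aln is not None:
                alignments.append((cl.id, aln))
    manifest["stages"]["alignments"] = len(alignments)

    # ---- covariation analysis + triage + elements --------------------------
    criteria = triage.ScreenCriteria(
        min_significant=config.min_significant, min_stems=config.min_stems,
        min_sequences=config.min_sequences, min_species=config.min_species,
    )
    motifs = []
    element_rows = []
    for motif_id, aln in alignments:
        from .io_formats import parse_wuss

        pt = parse_wuss(aln.ss_cons)
        classifications = covariation.annotate_alignment(aln, pt)
        results = []
        if pt.pairs and aln.n_rows >= 3:
            results = covariation.covariation_test(
                aln, n_perm=config.n_perm, seed=config.seed,
                evalue_threshold=config.evalue_threshold, pt=pt,
            )
        stats = triage.motif_stats(aln, classifications, results, motif_id)
        stats.structure = triage.structure_stats(pt)
        motifs.append(triage.screen(stats, criteria))
        for hit in functional_elements.conserved_site_report(aln):
            element_rows.append((motif_id, hit))
        for row in aln.rows[:1]:  # PAS scan on the first representative
            for hit in functional_elements.scan_pas(row.ungapped):
                element_rows.append((motif_id, hit))

    if motifs:
        df, text = triage.render_report(motifs, criteria)
        df.to_csv(outdir / "motifs.tsv", sep="\t", index=False)
        (outdir / "report.txt").write_text(text + "\n")
    with open(outdir / "elements.tsv", "w") as fh:
        fh.write("motif\tkind\tstart\tend\ttext\tconservation\tpaired_fraction\n")
        for motif_id, hit in element_rows:
            pf = "" if hit.paired_fraction is None else f"{hit.paired_fraction:.3f}"
            fh.write(f"{motif_id}\t{hit.kind}\t{hit.start}\t{hit.end}\t"
                     f"{hit.matched_text}\t{hit.conservation:.3f}\t{pf}\n")
    manifest["stages"]["motifs"] = len(motifs)
    manifest["stages"]["passing_screen"] = sum(1 for m in motifs if m.passes_screen)

    payload = json.dumps(manifest, sort_keys=True)
    manifest["hash"] = hashlib.sha256(payload.encode()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
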