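"""Extraction of intergenic regions (IGRs) and introns from annotated genomes.

The first stage of the discovery pipeline: noncoding space is enumerated
from a GFF3 annotation, and the corresponding (soft-mask-aware) sequences
are harvested from the genome FASTA.  All coordinates here are 0-based
half-open; the GFF3 1-based closed convention is converted exactly once,
on entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from .io_formats import CmlineError, Feature, SeqRecord, read_fasta

__all__ = ["Region", "extract_introns", "extract_igrs", "harvest_sequences",
           "reverse_complement"]

#: transcript-level feature types whose exons define introns
_TRANSCRIPT_TYPES = {"mRNA", "transcript", "ncRNA", "lnc_RNA", "mirna", "rRNA", "tRNA"}

DEFAULT_MIN_LEN = 50


@dataclass(frozen=True)
class Region:
    """A harvested noncoding interval (0-based half-open)."""

    seqid: str
    start: int
    end: int
    strand: str
    kind: str  # "IGR" or "intron"
    provenance: str = ""  # transcript id for introns, empty for IGRs

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CmlineError(f"invalid region {self.seqid}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for start, end in intervals[1:]:
        if start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def extract_introns(features: list[Feature], min_len: int = DEFAULT_MIN_LEN) -> list[Region]:
    """Introns = gaps between consecutive exons of each transcript.

    Overlapping exons within one transcript are merged before gap
    computation; exons without a resolvable Parent are skipped with a
    warning; introns shorter than ``min_len`` are dropped.
    """
    by_transcript: dict[str, list[Feature]] = {}
    for f in features:
        if f.type != "exon":
            continue
        if not f.parent:
            warnings.warn(f"exon at {f.seqid}:{f.start}-{f.end} has no Parent; skipped")
            continue
        for parent in f.parent.split(","):
            by_transcript.setdefault(parent, []).append(f)

    introns: list[Region] = []
    for transcript, exons in sorted(by_transcript.items()):
        seqid = exons[0].seqid
        strand = exons[0].strand if exons[0].strand in {"+", "-"} else "+"
        merged = _merge_intervals([(e.start - 1, e.end) for e in exons])
        for (_, left_end), (right_start, _) in zip(merged, merged[1:]):
            if right_start - left_end >= min_len:
                introns.append(
                    Region(seqid, left_end, right_start, strand, "intron", transcript)
                )
    return introns


def _gene_spans(features: list[Feature]) -> dict[str, list[tuple[int, int]]]:
    """Outermost gene-type spans per seqid; orphan transcripts count as genes."""
    gene_ids = {f.id for f in features if f.type == "gene" and f.id}
    spans: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        is_gene = f.type == "gene"
        is_orphan_transcript = (
            f.type in _TRANSCRIPT_TYPES and f.parent not in gene_ids
        )
        if is_gene or is_orphan_transcript:
            spans.setdefault(f.seqid, []).append((f.start - 1, f.end))
    return {seqid: _merge_intervals(v) for seqid, v in spans.items()}


def extract_igrs(
    features: list[Feature],
    seq_lengths: dict[str, int],
    min_len: int = DEFAULT_MIN_LEN,
) -> list[Region]:
    """IGRs = complement of the union of gene spans, clipped per chromosome.

    Emitted once, on the '+' strand; the reverse complement is considered
    at clustering time.  Raises if a feature's seqid is missing from
    ``seq_lengths``.
    """
    spans = _gene_spans(features)
    for seqid in spans:
        if seqid not in seq_lengths:
            raise CmlineError(f"seqid {seqid!r} not in provided sequence lengths")
    igrs: list[Region] = []
    for seqid in sorted(seq_lengths):
        length = seq_lengths[seqid]
        cursor = 0
        for start, end in spans.get(seqid, []):
            start, end = max(start, 0), min(end, length)
            if start - cursor >= min_len:
                igrs.append(Region(seqid, cursor, start, "+", "IGR"))
            cursor = max(cursor, end)
        if length - cursor >= min_len:
            igrs.append(Region(seqid, cursor, length, "+", "IGR"))
    return igrs


_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


def harvest_sequences(
    genome: dict[str, str] | str | Path,
    regions: list[Region],
    mask_policy: str = "drop",
    max_masked_fraction: float = 0.5,
) -> list[SeqRecord]:
    """Cut region sequences out of the genome, strand- and mask-aware.

    ``genome`` may be a FASTA path or a dict seqid -> raw sequence (lowercase
    = soft-masked).  '-'-strand regions are reverse-complemented.  Policies:

    - ``drop``: discard regions more than ``max_masked_fraction`` masked,
      hard-mask (N) masked residues in the rest (default);
    - ``hard``: keep all regions, masked residues -> N;
    - ``keep``: ignore masking entirely.

    Record ids encode provenance as ``seqid:start-end(strand)``.
    """
    if mask_policy not in {"drop", "hard", "keep"}:
        raise CmlineError(f"unknown mask_policy {mask_policy!r}")
    if not isinstance(genome, dict):
        genome = {rec.id: "".join(
            c.lower() if m else c for c, m in zip(rec.residues, rec.masked)
        ) for rec in read_fasta(genome)}

    records: list[SeqRecord] = []
    for region in regions:
        if region.seqid not in genome:
            raise CmlineError(f"region seqid {region.seqid!r} not in genome")
        chrom = genome[region.seqid]
        if region.end > len(chrom):
            raise CmlineError(
                f"region {region.seqid}:{region.start}-{region.end} exceeds "
                f"sequence length {len(chrom)}"
            )
        raw = chrom[region.start:region.end]
        masked = [c.islower() for c in raw]
        seq = raw.upper().replace("T", "U")
        if mask_policy == "drop" and sum(masked) > max_masked_fraction * len(seq):
            continue
        if mask_policy in {"drop", "hard"}:
            seq = "".join("N" if m else c for c, m in zip(seq, masked))
        if region.strand == "-":
            seq = reverse_complement(seq)
            masked = masked[::-1]
        records.append(
            SeqRecord(
                id=f"{region.seqid}:{region.start}-{region.end}({region.strand})",
                residues=seq,
                masked=tuple(masked),
            )
        )
    return records
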