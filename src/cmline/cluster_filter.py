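"""Clustering of similar noncoding sequences and the known-RNA/coding filters.

Clusters are single-linkage connected components over pairwise similarity
hits.  The faithful path consumes external BLAST outfmt-6 tables; a
desk-scale built-in aligner (exact word seeding, ungapped X-drop extension,
Karlin-Altschul E-values) is provided so the whole pipeline can run
self-contained on small inputs.

Two filters mirror the published screening: removal of members hitting a
known-RNA/repeat library at E <= 1e-9, and removal of clusters a coding-
potential tool calls likely protein-coding at P < 0.001.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.optimize import brentq

from .genome_prep import reverse_complement
from .io_formats import CmlineError, PairwiseHit, SeqRecord

__all__ = [
    "AlignerParams",
    "Cluster",
    "karlin_altschul_lambda",
    "pairwise_hits",
    "build_clusters",
    "filter_known",
    "filter_coding",
    "read_pvalue_table",
]

DEFAULT_MIN_CLUSTER_SIZE = 3
KNOWN_RNA_EVALUE = 1e-9
CODING_P_CUTOFF = 0.001

# Karlin-Altschul K has no closed form; this is a fixed approximation in the
# range typical for blastn-like scoring. Only the exponent (lambda) is solved
# exactly; K shifts E-values by a constant factor small against the 1e-6 cutoff.
_KA_K = 0.35


@dataclass(frozen=True)
class AlignerParams:
    """Built-in aligner settings (defaults mirror the pipeline's word size 7
    and E-value cutoff 1e-6; match/mismatch are blastn-like +2/-3)."""

    word_size: int = 7
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    evalue_cutoff: float = 1e-6
    xdrop: int = 20

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise CmlineError("word_size must be >= 4")
        if self.evalue_cutoff <= 0:
            raise CmlineError("evalue_cutoff must be > 0")


def karlin_altschul_lambda(
    match: int, mismatch: int, freqs: dict[str, float] | None = None
) -> float:
    """Solve sum_i sum_j p_i p_j exp(lambda * s_ij) = 1 for lambda > 0."""
    if freqs is None:
        freqs = {b: 0.25 for b in "ACGU"}
    p = np.array([freqs[b] for b in "ACGU"])

    def f(lam: float) -> float:
        total = 0.0
        for i in range(4):
            for j in range(4):
                s = match if i == j else mismatch
                total += p[i] * p[j] * math.exp(lam * s)
        return total - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, 1e-9, hi)


def _ungapped_extend(a: str, b: str, qpos: int, spos: int, word: int,
                     match: int, mismatch: int, xdrop: int) -> tuple[int, int, int, int, int]:
    """X-drop extension of an exact seed in both directions.

    Returns (score, qstart, qend, sstart, send), 0-based half-open.
    """
    score = word * match
    # right
    best, best_ext = score, 0
    cur, ext = score, 0
    while qpos + word + ext < len(a) and spos + word + ext < len(b):
        cur += match if a[qpos + word + ext] == b[spos + word + ext] else mismatch
        ext += 1
        if cur > best:
            best, best_ext = cur, ext
        elif best - cur > xdrop:
            break
    right = best_ext
    score = best
    # left
    best, best_ext = score, 0
    cur, ext = score, 0
    while qpos - 1 - ext >= 0 and spos - 1 - ext >= 0:
        cur += match if a[qpos - 1 - ext] == b[spos - 1 - ext] else mismatch
        ext += 1
        if cur > best:
            best, best_ext = cur, ext
        elif best - cur > xdrop:
            break
    return best, qpos - best_ext, qpos + word + right, spos - best_ext, spos + word + right


def _best_local_hit(query: str, subject: str, params: AlignerParams) -> tuple[int, int, int, int, int] | None:
    """Best-scoring ungapped local alignment via word seeding + extension."""
    w = params.word_size
    if len(query) < w or len(subject) < w:
        return None
    index: dict[str, list[int]] = {}
    for s in range(len(subject) - w + 1):
        word = subject[s:s + w]
        if "N" not in word:
            index.setdefault(word, []).append(s)
    best = None
    seen_diags: set[tuple[int, int]] = set()
    for q in range(len(query) - w + 1):
        word = query[q:q + w]
        for s in index.get(word, ()):
            diag = q - s
            # skip seeds inside an already-extended alignment on this diagonal
            key = (diag, q // w)
            if key in seen_diags:
                continue
            hit = _ungapped_extend(query, subject, q, s, w,
                                   params.match, params.mismatch, params.xdrop)
            for block in range(hit[1] // w, hit[2] // w + 1):
                seen_diags.add((diag, block))
            if best is None or hit[0] > best[0]:
                best = hit
    return best


def evalue_from_score(score: int, m: int, n: int, lam: float) -> float:
    return _KA_K * m * n * math.exp(-lam * score)


def pairwise_hits(
    records: list[SeqRecord],
    params: AlignerParams | None = None,
    both_strands: bool = True,
) -> list[PairwiseHit]:
    """All-vs-all similarity search with the built-in aligner.

    Self-hits are excluded; all-N records are skipped with a warning.
    With ``both_strands`` the reverse complement of the subject is also
    searched (regions are harvested once on '+').
    """
    params = params or AlignerParams()
    if len(records) < 2:
        raise CmlineError("pairwise_hits needs at least 2 records")
    lam = karlin_altschul_lambda(params.match, params.mismatch)
    usable = []
    for rec in records:
        if set(rec.residues) <= {"N"}:
            warnings.warn(f"record {rec.id} is all N; skipped")
            continue
        usable.append(rec)
    hits: list[PairwiseHit] = []
    for a_idx in range(len(usable)):
        for b_idx in range(a_idx + 1, len(usable)):
            qrec, srec = usable[a_idx], usable[b_idx]
            candidates = [(srec.residues, "+")]
            if both_strands:
                candidates.append((reverse_complement(srec.residues), "-"))
            best = None
            for subject_seq, strand in candidates:
                hit = _best_local_hit(qrec.residues, subject_seq, params)
                if hit and (best is None or hit[0] > best[0][0]):
                    best = (hit, strand, subject_seq)
            if best is None:
                continue
            (score, qs, qe, ss, se), strand, subject_seq = best
            ev = evalue_from_score(score, len(qrec.residues), len(srec.residues), lam)
            if ev > params.evalue_cutoff:
                continue
            ident = sum(
                1 for x, y in zip(qrec.residues[qs:qe], subject_seq[ss:se]) if x == y
            )
            length = qe - qs
            if strand == "-":
                ss, se = len(srec.residues) - se, len(srec.residues) - ss
                sstart, send = se, ss + 1  # reported 1-based, reversed orientation
            else:
                sstart, send = ss + 1, se
            hits.append(
                PairwiseHit(
                    query=qrec.id, subject=srec.id,
                    pident=100.0 * ident / length, length=length,
                    mismatch=length - ident, gapopen=0,
                    qstart=qs + 1, qend=qe, sstart=sstart, send=send,
                    evalue=ev, score=float(score),
                )
            )
    return hits


@dataclass
class Cluster:
    """A connected component of similar sequences with filter provenance."""

    id: str
    members: list[str]
    filter_log: list[tuple[str, tuple[str, ...], str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise CmlineError(f"cluster {self.id} has no members")

    def log(self, stage: str, removed: tuple[str, ...], reason: str) -> None:
        self.filter_log.append((stage, removed, reason))


def build_clusters(
    hits: list[PairwiseHit],
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    evalue_cutoff: float | None = None,
) -> list[Cluster]:
    """Single-linkage clusters: one passing hit in either direction = edge.

    Components with fewer than ``min_size`` members are discarded.  Cluster
    ids are deterministic (the lexicographically smallest member id), so
    permuting the input leaves the output invariant.
    """
    graph = nx.Graph()
    for h in hits:
        if evalue_cutoff is not None and h.evalue > evalue_cutoff:
            continue
        if h.query != h.subject:
            graph.add_edge(h.query, h.subject)
    clusters = []
    for component in nx.connected_components(graph):
        members = sorted(component)
        if len(members) >= min_size:
            clusters.append(Cluster(id=f"cluster-{members[0]}", members=members))
    clusters.sort(key=lambda c: c.id)
    return clusters


def filter_known(
    clusters: list[Cluster],
    library_hits: list[PairwiseHit],
    evalue_cutoff: float = KNOWN_RNA_EVALUE,
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> list[Cluster]:
    """Drop members hitting a known-RNA/repeat library at E <= cutoff.

    Member-level removal first; a cluster is removed wholesale only when it
    falls below ``min_size``.  Every removal is recorded in the filter log.
    """
    flagged = {h.query for h in library_hits if h.evalue <= evalue_cutoff}
    surviving = []
    for cluster in clusters:
        cluster = replace(cluster, members=list(cluster.members),
                          filter_log=list(cluster.filter_log))
        removed = tuple(m for m in cluster.members if m in flagged)
        if removed:
            cluster.members = [m for m in cluster.members if m not in flagged]
            cluster.log("known-RNA", removed, f"library hit at E<={evalue_cutoff:g}")
        if len(cluster.members) < min_size:
            cluster.log("known-RNA", tuple(cluster.members),
                        f"cluster below min_size {min_size} after known-RNA filter")
            continue
        surviving.append(cluster)
    return surviving


def filter_coding(
    clusters: list[Cluster],
    pvalues: dict[str, float],
    cutoff: float = CODING_P_CUTOFF,
) -> list[Cluster]:
    """Remove clusters a coding-potential scan calls coding at P < cutoff.

    Clusters with no P-value are retained but flagged "untested" in the log.
    """
    surviving = []
    for cluster in clusters:
        cluster = replace(cluster, members=list(cluster.members),
                          filter_log=list(cluster.filter_log))
        p = pvalues.get(cluster.id)
        if p is None:
            cluster.log("coding", (), "untested: no coding-potential P-value")
            surviving.append(cluster)
        elif p < cutoff:
            cluster.log("coding", tuple(cluster.members),
                        f"likely coding (P={p:g} < {cutoff:g})")
        else:
            surviving.append(cluster)
    return surviving


def read_pvalue_table(path: str | Path) -> dict[str, float]:
    """2-column TSV: cluster id, coding-potential P-value."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CmlineError(f"{path}:{lineno}: expected 2 columns")
            try:
                table[parts[0]] = float(parts[1])
            except ValueError as exc:
                raise CmlineError(f"{path}:{lineno}: {exc}") from exc
    return table
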