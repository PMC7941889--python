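"""Structural-complexity statistics and candidate screening/ranking.

A motif worth following up is (i) supported by at least one statistically
significant covariation, (ii) structurally complex (several stems rather
than a lone hairpin), and (iii) represented widely across species.  The
numeric thresholds and rank-score weights are explicit heuristics — the
published selection was manual — and every one of them is configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .covariation import CovariationResult, PairClassification, category_counts
from .io_formats import Alignment, PairTable

__all__ = [
    "StructureStats",
    "MotifStats",
    "ScreenCriteria",
    "structure_stats",
    "motif_stats",
    "screen",
    "render_report",
]


@dataclass
class StructureStats:
    """Loop-decomposition summary of a secondary structure (layer-0 pairs)."""

    n_pairs: int = 0
    n_stems: int = 0
    n_hairpin_loops: int = 0
    n_internal_loops: int = 0
    n_bulges: int = 0
    n_multiloops: int = 0
    has_pseudoknot: bool = False


def structure_stats(pt: PairTable) -> StructureStats:
    """Decompose the nested (layer-0) structure into stems and loops.

    A stem is a maximal run of strictly stacked pairs (i,j), (i+1,j-1), ...
    Loops are classified by the standard taxonomy from each pair's direct
    children: none -> hairpin; one child offset on one side only -> bulge,
    on both sides -> internal loop; two or more children -> multiloop.
    Pseudoknot pairs are excluded from the decomposition and reported only
    through ``has_pseudoknot``.
    """
    pairs = sorted(pt.layer0())
    stats = StructureStats(n_pairs=len(pairs), has_pseudoknot=pt.has_pseudoknot)
    if not pairs:
        return stats
    pair_set = set(pairs)

    stats.n_stems = sum(1 for i, j in pairs if (i - 1, j + 1) not in pair_set)

    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    for i, j in pairs:
        # direct children: maximal pairs strictly inside (i, j)
        children = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not children:
            stats.n_hairpin_loops += 1
        elif len(children) == 1:
            (ci, cj) = children[0]
            left, right = ci - i - 1, j - cj - 1
            if left == 0 and right == 0:
                pass  # stacked continuation, not a loop
            elif left == 0 or right == 0:
                stats.n_bulges += 1
            else:
                stats.n_internal_loops += 1
        else:
            stats.n_multiloops += 1
    return stats


@dataclass
class MotifStats:
    """Triage record for one motif alignment."""

    motif_id: str
    n_sequences: int
    n_species: int
    structure: StructureStats
    n_covarying: int = 0
    n_compatible: int = 0
    n_conserved: int = 0
    n_unsupported: int = 0
    n_insufficient: int = 0
    n_significant: int = 0
    rank_score: float = 0.0
    passes_screen: bool = False


def motif_stats(
    aln: Alignment,
    classifications: list[PairClassification],
    covariation_results: list[CovariationResult],
    motif_id: str = "motif",
) -> MotifStats:
    """Aggregate per-pair verdicts into one triage record.

    ``n_sequences`` counts rows with duplicates retained (identical
    homologs from different species are legitimate representatives);
    ``n_species`` counts distinct species labels.
    """
    labels = [s for s in aln.species() if s]
    if len(labels) < aln.n_rows:
        warnings.warn(f"{motif_id}: species labels missing; counting by row id prefix")
    tally = category_counts(classifications)
    return MotifStats(
        motif_id=motif_id,
        n_sequences=aln.n_rows,
        n_species=len(set(labels)) if labels else aln.n_rows,
        structure=StructureStats(),  # filled by caller via structure_stats
        n_covarying=tally["covarying"],
        n_compatible=tally["compatible"],
        n_conserved=tally["conserved"],
        n_unsupported=tally["unsupported"],
        n_insufficient=tally["insufficient"],
        n_significant=sum(1 for r in covariation_results if r.significant),
    )


@dataclass(frozen=True)
class ScreenCriteria:
    """Screening thresholds and rank-score weights (all heuristic knobs)."""

    min_significant: int = 1
    min_stems: int = 2
    min_sequences: int = 10
    min_species: int = 5
    w_significant: float = 2.0
    w_covarying: float = 1.0
    w_compatible: float = 0.5
    w_stems: float = 1.0


def rank_score(stats: MotifStats, criteria: ScreenCriteria) -> float:
    return (
        criteria.w_significant * stats.n_significant
        + criteria.w_covarying * stats.n_covarying
        + criteria.w_compatible * stats.n_compatible
        + criteria.w_stems * stats.structure.n_stems
        + math.log2(max(stats.n_species, 1))
    )


def screen(stats: MotifStats, criteria: ScreenCriteria | None = None) -> MotifStats:
    """Fill ``passes_screen`` and ``rank_score``; returns the same record."""
    criteria = criteria or ScreenCriteria()
    stats.rank_score = rank_score(stats, criteria)
    stats.passes_screen = (
        stats.n_significant >= criteria.min_significant
        and stats.structure.n_stems >= criteria.min_stems
        and stats.n_sequences >= criteria.min_sequences
        and stats.n_species >= criteria.min_species
    )
    return stats


_REPORT_COLUMNS = [
    "motif_id", "n_sequences", "n_species", "n_pairs", "n_stems",
    "n_hairpin_loops", "n_internal_loops", "n_bulges", "n_multiloops",
    "has_pseudoknot", "n_covarying", "n_compatible", "n_conserved",
    "n_unsupported", "n_insufficient", "n_significant", "rank_score",
    "passes_screen",
]


def render_report(
    motifs: list[MotifStats], criteria: ScreenCriteria | None = None
) -> tuple[pd.DataFrame, str]:
    """Rank table (descending rank_score, ties broken by motif_id) + text summary."""
    criteria = criteria or ScreenCriteria()
    rows = []
    for m in motifs:
        record = {
            "motif_id": m.motif_id, "n_sequences": m.n_sequences,
            "n_species": m.n_species, "n_pairs": m.structure.n_pairs,
            "n_stems": m.structure.n_stems,
            "n_hairpin_loops": m.structure.n_hairpin_loops,
            "n_internal_loops": m.structure.n_internal_loops,
            "n_bulges": m.structure.n_bulges,
            "n_multiloops": m.structure.n_multiloops,
            "has_pseudoknot": m.structure.has_pseudoknot,
            "n_covarying": m.n_covarying, "n_compatible": m.n_compatible,
            "n_conserved": m.n_conserved, "n_unsupported": m.n_unsupported,
            "n_insufficient": m.n_insufficient,
            "n_significant": m.n_significant, "rank_score": m.rank_score,
            "passes_screen": m.passes_screen,
        }
        rows.append(record)
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df = df.sort_values(["rank_score", "motif_id"],
                        ascending=[False, True], kind="stable").reset_index(drop=True)

    lines = []
    for _, r in df.iterrows():
        verdict = "PASS" if r.passes_screen else "fail"
        lines.append(f"{r.motif_id}  [{verdict}]  rank_score={r.rank_score:.2f}")
        lines.append(
            f"  significant covariations: {r.n_significant} "
            f"(need >= {criteria.min_significant})"
        )
        lines.append(f"  stems: {r.n_stems} (need >= {criteria.min_stems})")
        lines.append(
            f"  representatives: {r.n_sequences} sequences "
            f"(need >= {criteria.min_sequences}), {r.n_species} species "
            f"(need >= {criteria.min_species})"
        )
        lines.append(
            f"  pair support: {r.n_covarying} covarying, {r.n_compatible} "
            f"compatible, {r.n_conserved} conserved, {r.n_unsupported} unsupported"
        )
    return df, "\n".join(lines)
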