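"""Base-pair covariation analysis of structure-annotated alignments.

Two independent evidence channels are computed per consensus base pair and
deliberately kept separate:

1. a descriptive category in the R2R tradition — *covarying* (two sequences
   differ at BOTH positions yet both form canonical pairs), *compatible*
   (one-sided changes that preserve canonical pairing, e.g. A-U -> G-U),
   *conserved* (a single canonical pair type), or *unsupported* — applied
   only where more than 90% of included rows form canonical Watson-Crick or
   G-U pairs;

2. a permutation significance E-value: the G statistic (log-likelihood-ratio
   test of independence) of the two columns' joint residue table, referred
   to a null built by independently permuting each column across rows,
   Bonferroni-scaled by the number of annotated pairs.

The permutation null treats rows as exchangeable — it knows nothing about
phylogeny, so it is anti-conservative for alignments of closely related
sequences (a tree-aware method should be consulted for publication-grade
significance).  An optional duplicate-row collapse is provided to blunt the
worst of this; it is off by default because representative counts keep
duplicates on purpose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import Alignment, CmlineError, PairTable, parse_wuss

__all__ = [
    "CANONICAL_PAIRS",
    "PairClassification",
    "CovariationResult",
    "classify_pair",
    "annotate_alignment",
    "covariation_test",
    "category_counts",
]

#: Watson-Crick + G-U wobble, the pair types counted as structure-supporting
CANONICAL_PAIRS = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})

CANONICAL_FRACTION_THRESHOLD = 0.9  # strictly "more than 90%"
MAX_EXCLUDED_FRACTION = 0.5
DEFAULT_EVALUE_THRESHOLD = 0.05
DEFAULT_N_PERM = 1000

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass
class PairClassification:
    """Descriptive verdict for one consensus base pair."""

    pair: tuple[int, int]
    pairtype_counts: dict[str, int]
    n_included: int
    n_excluded: int
    canonical_fraction: float
    category: str  # covarying | compatible | conserved | unsupported | insufficient
    layer: int = 0


def classify_pair(
    column_i: str, column_j: str, layer: int = 0, pair: tuple[int, int] = (0, 1)
) -> PairClassification:
    """Categorize one pair of alignment columns.

    Rows with a gap or ambiguity code at either position are excluded.
    Decision order: *insufficient* (fewer than 2 usable rows, or more than
    half the rows excluded), *unsupported* (canonical fraction <= 0.9),
    *covarying* (two observed canonical pair types differing at both
    positions), *compatible* (>= 2 canonical pair types), else *conserved*.
    """
    if len(column_i) != len(column_j) or not column_i:
        raise CmlineError("columns must be non-empty and of equal length")
    counts: dict[str, int] = {}
    n_excluded = 0
    for a, b in zip(column_i, column_j):
        if a in _CODE and b in _CODE:
            counts[a + b] = counts.get(a + b, 0) + 1
        else:
            n_excluded += 1
    n_included = len(column_i) - n_excluded

    if n_included < 2 or n_excluded > MAX_EXCLUDED_FRACTION * len(column_i):
        category, canonical_fraction = "insufficient", 0.0
        if n_included:
            canonical_fraction = (
                sum(c for t, c in counts.items() if t in CANONICAL_PAIRS) / n_included
            )
        return PairClassification(pair, counts, n_included, n_excluded,
                                  canonical_fraction, category, layer)

    canonical = {t: c for t, c in counts.items() if t in CANONICAL_PAIRS}
    canonical_fraction = sum(canonical.values()) / n_included
    if canonical_fraction <= CANONICAL_FRACTION_THRESHOLD:
        category = "unsupported"
    else:
        types = list(canonical)
        covarying = any(
            t1[0] != t2[0] and t1[1] != t2[1]
            for k, t1 in enumerate(types)
            for t2 in types[k + 1:]
        )
        if covarying:
            category = "covarying"
        elif len(types) >= 2:
            category = "compatible"
        else:
            category = "conserved"
    return PairClassification(pair, counts, n_included, n_excluded,
                              canonical_fraction, category, layer)


def annotate_alignment(
    aln: Alignment, pt: PairTable | None = None
) -> list[PairClassification]:
    """Classify every annotated pair (pseudoknot pairs too, tagged by layer)."""
    if pt is None:
        pt = parse_wuss(aln.ss_cons)
    out = []
    for (i, j), layer in zip(pt.pairs, pt.layer):
        out.append(classify_pair(aln.columns(i), aln.columns(j), layer, (i, j)))
    return out


def category_counts(classifications: list[PairClassification]) -> dict[str, int]:
    tally = {k: 0 for k in
             ("covarying", "compatible", "conserved", "unsupported", "insufficient")}
    for c in classifications:
        tally[c.category] += 1
    return tally


@dataclass
class CovariationResult:
    """Permutation-test verdict for one consensus base pair."""

    pair: tuple[int, int]
    statistic: float
    evalue: float
    significant: bool


def _encode_columns(aln: Alignment, columns: list[int]) -> np.ndarray:
    """Integer-code selected columns; 4 marks gap/ambiguity (excluded rows)."""
    mat = np.full((aln.n_rows, len(columns)), 4, dtype=np.int8)
    for r, row in enumerate(aln.rows):
        for k, c in enumerate(columns):
            mat[r, k] = _CODE.get(row.residues[c], 4)
    return mat


def _g_stat(ci: np.ndarray, cj: np.ndarray) -> float:
    """G statistic of the 4x4 joint table of two coded columns vs independence.

    Rows where either column is coded 4 (gap/ambiguity) are excluded.
    """
    mask = (ci < 4) & (cj < 4)
    if mask.sum() < 2:
        return 0.0
    a, b = ci[mask], cj[mask]
    table = np.bincount(a * 4 + b, minlength=16).reshape(4, 4).astype(float)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    expected = np.outer(rows, cols) / n
    nz = table > 0
    return float(2.0 * (table[nz] * np.log(table[nz] / expected[nz])).sum())


def covariation_test(
    aln: Alignment,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    pt: PairTable | None = None,
    collapse_duplicates: bool = False,
) -> list[CovariationResult]:
    """Permutation significance test for every annotated base pair.

    Null model: each alignment column independently permuted across rows,
    ``n_perm`` times, statistics pooled over all annotated pairs.  The
    empirical p-value uses the add-one rule on the average per-pair
    exceedance count, p = (1 + #{null >= obs}/n_pairs) / (1 + n_perm), and
    the E-value is the Bonferroni scale-up p * n_pairs.  A pair is called
    significant when its E-value is below ``evalue_threshold``.
    """
    if aln.n_rows < 3:
        raise CmlineError("covariation_test needs at least 3 rows")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; E-value resolution is coarse")
    if pt is None:
        pt = parse_wuss(aln.ss_cons)
    pairs = list(pt.pairs)
    if not pairs:
        raise CmlineError("no annotated pairs in consensus structure")

    work = aln
    if collapse_duplicates:
        seen: dict[str, None] = {}
        kept = [r for r in aln.rows if not (r.residues in seen or seen.update({r.residues: None}))]
        work = Alignment(kept, aln.ss_cons, aln.metadata)

    columns = sorted({c for p in pairs for c in p})
    col_index = {c: k for k, c in enumerate(columns)}
    coded = _encode_columns(work, columns)
    n_rows = coded.shape[0]

    observed = np.array(
        [_g_stat(coded[:, col_index[i]], coded[:, col_index[j]]) for i, j in pairs]
    )

    rng = np.random.default_rng(seed)
    n_pairs = len(pairs)
    null = np.empty((n_perm, n_pairs))
    for p_idx in range(n_perm):
        permuted = np.empty_like(coded)
        for k in range(coded.shape[1]):
            permuted[:, k] = coded[rng.permutation(n_rows), k]
        for q, (i, j) in enumerate(pairs):
            null[p_idx, q] = _g_stat(permuted[:, col_index[i]], permuted[:, col_index[j]])

    pooled = np.sort(null.ravel())
    results = []
    for q, (i, j) in enumerate(pairs):
        exceed = pooled.size - np.searchsorted(pooled, observed[q], side="left")
        p = (1.0 + exceed / n_pairs) / (1.0 + n_perm)
        evalue = min(p * n_pairs, float(n_pairs))
        results.append(
            CovariationResult((i, j), float(observed[q]), evalue,
                              evalue < evalue_threshold)
        )
    return results
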