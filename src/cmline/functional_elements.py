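"""Light functional triage: polyadenylation-signal scanning and conserved
unpaired segments as candidate protein-binding or regulatory sites."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .io_formats import Alignment, parse_wuss

__all__ = ["ElementHit", "PAS_HEXAMERS", "PAS_EXTENDED", "scan_pas",
           "conserved_site_report"]

#: the two dominant mammalian poly(A) hexamers
PAS_HEXAMERS = ("AAUAAA", "AUUAAA")

#: the common 12-variant set (optional; single-base deviations from AAUAAA)
PAS_EXTENDED = (
    "AAUAAA", "AUUAAA", "AGUAAA", "UAUAAA", "CAUAAA", "GAUAAA",
    "AAUAUA", "AAUACA", "AAUAGA", "ACUAAA", "AAGAAA", "AAUGAA",
)


@dataclass
class ElementHit:
    """A candidate functional element, 0-based half-open coordinates."""

    kind: str  # "PAS" or "conserved-segment"
    start: int
    end: int
    matched_text: str
    conservation: float
    paired_fraction: float | None = None  # fraction of columns base-paired


def scan_pas(seq: str, variants: tuple[str, ...] = PAS_HEXAMERS) -> list[ElementHit]:
    """Report every (overlapping) occurrence of a poly(A)-signal hexamer."""
    seq = seq.upper().replace("T", "U")
    hits = []
    for i in range(len(seq)):
        for v in variants:
            if seq.startswith(v, i):
                hits.append(ElementHit("PAS", i, i + len(v), v, 1.0))
    hits.sort(key=lambda h: (h.start, h.matched_text))
    return hits


def conserved_site_report(
    aln: Alignment, min_fraction: float = 0.9, min_len: int = 5
) -> list[ElementHit]:
    """Maximal runs of highly conserved alignment columns.

    A column is conserved when its majority residue reaches ``min_fraction``
    of ALL rows (gaps count against, penalizing gappy columns).  Runs of at
    least ``min_len`` such columns are reported with their consensus text,
    mean conservation, and the fraction of columns that are base-paired in
    the consensus structure.
    """
    if aln.n_rows < 2:
        raise ValueError("conserved_site_report needs >= 2 rows")
    n = aln.n_rows
    freqs, consensus = [], []
    for c in range(aln.width):
        counts = Counter(
            r.residues[c] for r in aln.rows if r.residues[c] in "ACGU"
        )
        if counts:
            res, best = counts.most_common(1)[0]
        else:
            res, best = "N", 0
        freqs.append(best / n)
        consensus.append(res)

    paired_cols: set[int] = set()
    try:
        pt = parse_wuss(aln.ss_cons)
        paired_cols = {c for p in pt.pairs for c in p}
    except Exception:
        pass

    hits: list[ElementHit] = []
    start = None
    for c in range(aln.width + 1):
        ok = c < aln.width and freqs[c] >= min_fraction
        if ok and start is None:
            start = c
        elif not ok and start is not None:
            if c - start >= min_len:
                cols = range(start, c)
                hits.append(
                    ElementHit(
                        "conserved-segment", start, c,
                        "".join(consensus[start:c]),
                        sum(freqs[k] for k in cols) / (c - start),
                        sum(1 for k in cols if k in paired_cols) / (c - start),
                    )
                )
            start = None
    return hits
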