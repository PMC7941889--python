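"""Independent reference implementations used only to check the package.

Each oracle is written from the definition, along a different code path
than the implementation it validates (brute-force scans, boolean position
arrays, naive union-find), so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

CANONICAL = {"AU", "UA", "CG", "GC", "GU", "UG"}


def random_nested_structure(rng: np.random.Generator, max_depth: int = 6
                            ) -> tuple[str, set[tuple[int, int]]]:
    """Generate a random nested WUSS string with its pair set known by
    construction (the structure is built from the pairs, not parsed)."""

    def gen(depth: int) -> tuple[str, list[tuple[int, int]]]:
        s, pairs = "", []
        for _ in range(rng.integers(0, 4)):
            if depth < max_depth and rng.random() < 0.45:
                inner, inner_pairs = gen(depth + 1)
                offset = len(s) + 1
                pairs.append((len(s), len(s) + len(inner) + 1))
                pairs += [(a + offset, b + offset) for a, b in inner_pairs]
                s += "<" + inner + ">"
            else:
                s += "."
        return s, pairs

    s, pairs = gen(0)
    if not s:
        s = "."
    return s, set(pairs)


def classify_pair_oracle(col_i: str, col_j: str) -> str:
    """Rule-by-rule restatement of the pair-category definition."""
    included = [(a, b) for a, b in zip(col_i, col_j) if a in "ACGU" and b in "ACGU"]
    n_excluded = len(col_i) - len(included)
    if len(included) < 2 or n_excluded > 0.5 * len(col_i):
        return "insufficient"
    canonical_types = {a + b for a, b in included if a + b in CANONICAL}
    n_canon = sum(1 for a, b in included if a + b in CANONICAL)
    if n_canon / len(included) <= 0.9:
        return "unsupported"
    for t1 in canonical_types:
        for t2 in canonical_types:
            if t1[0] != t2[0] and t1[1] != t2[1]:
                return "covarying"
    if len(canonical_types) >= 2:
        return "compatible"
    return "conserved"


def loop_stats_oracle(pairs: set[tuple[int, int]]) -> dict[str, int]:
    """Loop decomposition via parent assignment over a boolean forest."""
    pairs = sorted(pairs)
    stats = {"n_stems": 0, "n_hairpin_loops": 0, "n_internal_loops": 0,
             "n_bulges": 0, "n_multiloops": 0}
    pair_set = set(pairs)
    for i, j in pairs:
        if (i - 1, j + 1) not in pair_set:
            stats["n_stems"] += 1
    # parent of a pair = smallest enclosing pair
    for i, j in pairs:
        children = [
            (a, b) for a, b in pairs
            if i < a and b < j
            and not any(i < c < a and b < d < j for c, d in pairs)
        ]
        if not children:
            stats["n_hairpin_loops"] += 1
        elif len(children) == 1:
            (a, b) = children[0]
            left, right = a - i - 1, j - b - 1
            if left == 0 and right == 0:
                continue
            if left == 0 or right == 0:
                stats["n_bulges"] += 1
            else:
                stats["n_internal_loops"] += 1
        else:
            stats["n_multiloops"] += 1
    return stats


def complement_intervals_oracle(spans: list[tuple[int, int]], length: int
                                ) -> list[tuple[int, int]]:
    """Interval complement by per-position boolean array."""
    covered = np.zeros(length, dtype=bool)
    for s, e in spans:
        covered[max(s, 0):min(e, length)] = True
    out, start = [], None
    for pos in range(length + 1):
        free = pos < length and not covered[pos]
        if free and start is None:
            start = pos
        elif not free and start is not None:
            out.append((start, pos))
            start = None
    return out


def introns_oracle(exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Gaps inside the transcript span via a boolean array."""
    if not exons:
        return []
    lo = min(s for s, _ in exons)
    hi = max(e for _, e in exons)
    covered = np.zeros(hi - lo, dtype=bool)
    for s, e in exons:
        covered[s - lo:e - lo] = True
    out, start = [], None
    for pos in range(len(covered) + 1):
        gap = pos < len(covered) and not covered[pos]
        if gap and start is None:
            start = pos
        elif not gap and start is not None:
            out.append((start + lo, pos + lo))
            start = None
    return out


class UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self) -> list[frozenset[str]]:
        groups: dict[str, set[str]] = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return [frozenset(g) for g in groups.values()]
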