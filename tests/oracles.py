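"""Independent brute-force oracles used by the tests.

Deliberately naive: subset enumeration, per-base bitmaps, per-window
Python loops.  Nothing here shares code with the package's vectorized
implementations.
"""

from __future__ import annotations

import math
from itertools import combinations

REAL = "ACGT"


def oracle_column_support(rows: list[str], c: int) -> int:
    best = 0
    for b in REAL:
        n = sum(1 for row in rows if row[c] == b)
        best = max(best, n)
    return best


def oracle_seeds(rows: list[str], L: int, S: int) -> list[int]:
    """Window starts where >= S species share an identical clean L-mer,
    by explicit enumeration of all species subsets of size S."""
    ncol = len(rows[0])
    out = []
    for w in range(ncol - L + 1):
        words = [row[w : w + L] for row in rows]
        found = False
        for subset in combinations(range(len(rows)), S):
            first = words[subset[0]]
            if any(ch not in REAL for ch in first):
                continue
            if all(words[i] == first for i in subset[1:]):
                found = True
                break
        if found:
            out.append(w)
    return out


def oracle_exactplus(
    rows: list[str], ref_index: int, ref_offset: int, L: int, S: int, E: int
):
    """All maximal intervals satisfying seed containment plus the
    per-column >= E rule, with edge-trimmed reference spans.

    Returns a list of dicts with col_start/col_end/ref_start/ref_end/
    min_support/seeded_by (elements with empty reference spans dropped).
    """
    ncol = len(rows[0])
    support = [oracle_column_support(rows, c) for c in range(ncol)]
    good = [s >= E for s in support]
    seeds = oracle_seeds(rows, L, S) if ncol >= L else []

    # brute-force column -> reference position
    col_ref = []
    pos = ref_offset
    for ch in rows[ref_index]:
        if ch == "-":
            col_ref.append(None)
        else:
            col_ref.append(pos)
            pos += 1

    out = []
    c = 0
    while c < ncol:
        if not good[c]:
            c += 1
            continue
        d = c
        while d < ncol and good[d]:
            d += 1
        contained = [w for w in seeds if w >= c and w + L <= d]
        if contained:
            covered = [col_ref[i] for i in range(c, d) if col_ref[i] is not None]
            if covered:
                out.append(
                    dict(
                        col_start=c,
                        col_end=d,
                        ref_start=covered[0],
                        ref_end=covered[-1] + 1,
                        min_support=min(support[c:d]),
                        seeded_by=len(contained),
                    )
                )
        c = d
    return out


def oracle_percent_identity(a: str, b: str, ungapped: bool) -> float:
    matches = denom = 0
    for x, y in zip(a.upper(), b.upper()):
        if ungapped and ("-" in (x, y)):
            continue
        denom += 1
        if x == y and x in REAL:
            matches += 1
    return 100.0 * matches / denom


def bitmap_intersection(a, b, region_len: int):
    """(shared_count over A, shared bp) via per-base boolean arrays."""
    mask_a = [False] * region_len
    mask_b = [False] * region_len
    for s, e in a:
        for i in range(max(0, s), min(region_len, e)):
            mask_a[i] = True
    for s, e in b:
        for i in range(max(0, s), min(region_len, e)):
            mask_b[i] = True
    shared_bp = sum(1 for x, y in zip(mask_a, mask_b) if x and y)
    count = 0
    for s, e in a:
        if any(mask_b[i] for i in range(max(0, s), min(region_len, e))):
            count += 1
    return count, shared_bp


def bitmap_coverage(ivs, region_len: int) -> float:
    mask = [False] * region_len
    for s, e in ivs:
        for i in range(max(0, s), min(region_len, e)):
            mask[i] = True
    return sum(mask) / region_len


def oracle_motif_score(window: str, freqs, background: float = 0.25) -> float:
    """Per-window log-odds by explicit loop; -inf on any non-ACGT char."""
    total = 0.0
    for j, ch in enumerate(window):
        if ch not in REAL:
            return -math.inf
        total += math.log2(freqs[j][REAL.index(ch)] / background)
    return total


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0
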