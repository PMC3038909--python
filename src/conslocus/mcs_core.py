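"""Exact-match seed-and-extend detection of multi-species conserved sequences.

The detector scans a gapped multiple alignment for *seeds* — windows of
``L`` consecutive columns in which some fixed subset of at least ``S``
species carries an identical, fully ungapped, N-free ``L``-mer — and then
extends each seed column-by-column in both directions for as long as at
least ``E`` species share an identical non-gap, non-N base in the next
column (the agreeing subset may change from column to column).  Extended
intervals that overlap or abut are merged; the result is a set of
disjoint, maximal conserved elements reported in reference coordinates.

The default parameters ``L=7, S=5, E=4`` (the "7-5-4" setting) target
seven-species mammalian locus alignments.  Gap and ``N`` characters are
never identical to anything, so they terminate both seeds and extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from conslocus.alignment_io import (
    MultiAlignment,
    RefCoordMap,
    project_to_reference,
)

_BASES = b"ACGT"


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class SeedParams:
    """Conservation parameters (seed length, seed support, extension support).

    ``L``: seed length in alignment columns.  ``S``: minimum number of
    species that must share an identical seed word.  ``E``: minimum number
    of species identical per extension column.  Defaults are the 7-5-4
    setting.
    """

    L: int = 7
    S: int = 5
    E: int = 4

    def validate(self, n_species: int | None = None) -> None:
        if self.L < 1:
            raise ParameterError(f"L must be >= 1, got {self.L}")
        if not 2 <= self.E <= self.S:
            raise ParameterError(f"need 2 <= E <= S, got E={self.E}, S={self.S}")
        if n_species is not None and self.S > n_species:
            raise ParameterError(
                f"S={self.S} exceeds the {n_species} species in the alignment"
            )


@dataclass
class MCS:
    """A maximal conserved interval.

    ``ref_start``/``ref_end`` are 0-based half-open reference coordinates
    (reference-gap columns at the edges of the column span are trimmed
    from the reported interval; interior reference gaps do not split an
    element).  ``min_support`` is the minimum per-column count of
    identical species over the column span; ``seeded_by`` counts the seed
    windows contained in the element.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    col_start: int
    col_end: int
    min_support: int
    seeded_by: int

    @property
    def length_bp(self) -> int:
        return self.ref_end - self.ref_start

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start:
            raise ValueError("MCS must cover at least one reference base")


@dataclass
class McsSummary:
    count: int
    total_bp: int
    min_len: int | None
    max_len: int | None
    mean_len: float | None
    fraction_of_region: float


def _encode(aln: MultiAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Return (digit matrix with A,C,G,T -> 0..3, validity mask).

    Gap and N columns are invalid (digit value is arbitrary there).
    """
    m = aln.to_matrix()
    digits = np.zeros_like(m)
    valid = np.zeros(m.shape, dtype=bool)
    for d, b in enumerate(_BASES):
        hit = m == b
        digits[hit] = d
        valid |= hit
    return digits, valid


def column_support(aln: MultiAlignment, require_ref: bool = False) -> np.ndarray:
    """Per-column count of species sharing the most common real base.

    With ``require_ref`` the count is restricted to species matching the
    reference base (0 where the reference is gapped or N).
    """
    digits, valid = _encode(aln)
    if require_ref:
        r = aln.reference_index
        agree = valid & valid[r] & (digits == digits[r])
        return agree.sum(axis=0).astype(np.int64)
    counts = np.zeros((4, aln.n_columns), dtype=np.int64)
    for d in range(4):
        counts[d] = ((digits == d) & valid).sum(axis=0)
    return counts.max(axis=0)


def _window_codes(digits: np.ndarray, valid: np.ndarray, L: int) -> np.ndarray:
    """Integer code of each species' L-mer at every window start.

    Windows containing a gap or N get a unique negative code per species
    so they can never match anything.
    """
    n_species, n_cols = digits.shape
    n_win = n_cols - L + 1
    powers = 4 ** np.arange(L - 1, -1, -1, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(digits.astype(np.int64), L, axis=1)
    codes = win @ powers  # (n_species, n_win)
    ok = np.lib.stride_tricks.sliding_window_view(valid, L, axis=1).all(axis=2)
    sentinel = -(np.arange(n_species, dtype=np.int64) + 1)[:, None]
    return np.where(ok, codes, np.broadcast_to(sentinel, (n_species, n_win)))


def find_seeds(
    aln: MultiAlignment,
    params: SeedParams = SeedParams(),
    seed_rule: str = "word",
    require_ref: bool = False,
) -> list[tuple[int, int]]:
    """All qualifying seed windows, as half-open column intervals.

    Under the default ``word`` rule a window qualifies when >= S species
    carry an identical ungapped N-free L-mer (a fixed agreeing subset
    across the window).  Under ``per-column`` the agreeing subset may vary
    by column: a window qualifies when every one of its L columns has
    >= S species sharing an identical real base.
    """
    params.validate(aln.n_species)
    L = params.L
    if aln.n_columns < L:
        return []
    if seed_rule == "per-column":
        support = column_support(aln, require_ref=require_ref)
        good = support >= params.S
        run = np.lib.stride_tricks.sliding_window_view(good, L).all(axis=1)
        return [(int(w), int(w) + L) for w in np.flatnonzero(run)]
    if seed_rule != "word":
        raise ParameterError(f"unknown seed_rule {seed_rule!r}")
    if 4**L > np.iinfo(np.int64).max // 4:
        raise ParameterError(f"seed length L={params.L} too large")
    digits, valid = _encode(aln)
    codes = _window_codes(digits, valid, L)
    if require_ref:
        ref_codes = codes[aln.reference_index]
        mult = ((codes == ref_codes) & (ref_codes >= 0)).sum(axis=0)
    else:
        # max multiplicity of any (valid) code among species, per window
        srt = np.sort(codes, axis=0)
        n_species = srt.shape[0]
        mult = np.ones(srt.shape[1], dtype=np.int64)
        run = np.ones(srt.shape[1], dtype=np.int64)
        for s in range(1, n_species):
            same = (srt[s] == srt[s - 1]) & (srt[s] >= 0)
            run = np.where(same, run + 1, 1)
            mult = np.maximum(mult, run)
    return [(int(w), int(w) + L) for w in np.flatnonzero(mult >= params.S)]


def extend_and_merge(
    aln: MultiAlignment,
    seeds: list[tuple[int, int]],
    params: SeedParams = SeedParams(),
    coord: RefCoordMap | None = None,
    require_ref: bool = False,
) -> list[MCS]:
    """Extend seeds under the per-column >= E rule and merge the results.

    Every seed column already satisfies the extension predicate (S >= E),
    so the extension of a seed is exactly the maximal run of qualifying
    columns that contains it; overlapping and book-ended extensions
    collapse into the same run.  Elements whose trimmed reference span is
    empty (all reference-gap columns) are dropped, as they have no
    reportable coordinates.
    """
    params.validate(aln.n_species)
    if not seeds:
        return []
    for a, b in seeds:
        if a < 0 or b > aln.n_columns:
            raise IndexError(f"seed ({a}, {b}) outside alignment")
    if coord is None:
        coord = project_to_reference(aln)
    support = column_support(aln, require_ref=require_ref)
    good = support >= params.E
    # maximal runs of qualifying columns
    padded = np.concatenate(([False], good, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    runs = list(zip(edges[0::2], edges[1::2]))  # half-open column runs

    seed_starts = np.array(sorted(a for a, _ in seeds))
    out: list[MCS] = []
    for start, end in runs:
        # seeds fully inside the run (a >= start and a + L <= end)
        lo = np.searchsorted(seed_starts, start)
        hi = np.searchsorted(seed_starts, end - params.L, side="right")
        n_seeds = int(hi - lo)
        if n_seeds == 0:
            continue
        span = coord.ref_span(int(start), int(end))
        if span is None:
            continue
        out.append(
            MCS(
                ref_chrom=aln.ref_chrom,
                ref_start=span[0],
                ref_end=span[1],
                col_start=int(start),
                col_end=int(end),
                min_support=int(support[start:end].min()),
                seeded_by=n_seeds,
            )
        )
    return out


def run_exactplus(
    aln: MultiAlignment,
    params: SeedParams = SeedParams(),
    seed_rule: str = "word",
    require_ref: bool = False,
    region_bp: int | None = None,
) -> tuple[list[MCS], McsSummary]:
    """Seed, extend, merge and summarize in one call.

    ``region_bp`` defaults to the reference extent of the alignment (the
    analyzed interval).  Deterministic for fixed input.
    """
    if region_bp is None:
        region_bp = aln.ref_length
    if aln.n_columns < params.L:
        return [], summarize_mcs([], region_bp)
    coord = project_to_reference(aln)
    seeds = find_seeds(aln, params, seed_rule=seed_rule, require_ref=require_ref)
    mcs = extend_and_merge(aln, seeds, params, coord, require_ref=require_ref)
    return mcs, summarize_mcs(mcs, region_bp)


def summarize_mcs(mcs: list[MCS], region_bp: int) -> McsSummary:
    """Count, total bp, length range/mean and fraction of the region."""
    if region_bp <= 0:
        raise ParameterError(f"region_bp must be positive, got {region_bp}")
    lengths = [m.length_bp for m in mcs]
    total = sum(lengths)
    if not lengths:
        return McsSummary(0, 0, None, None, None, 0.0)
    return McsSummary(
        count=len(lengths),
        total_bp=total,
        min_len=min(lengths),
        max_len=max(lengths),
        mean_len=total / len(lengths),
        fraction_of_region=total / region_bp,
    )


def write_mcs_bed(mcs: list[MCS], n_species: int, path) -> None:
    """Write elements as BED6; score is min_support scaled to 0-1000."""
    close = False
    if isinstance(path, (str, bytes)):
        path = open(path, "w")
        close = True
    try:
        for i, m in enumerate(mcs, start=1):
            score = round(1000 * m.min_support / n_species)
            path.write(
                f"{m.ref_chrom}\t{m.ref_start}\t{m.ref_end}\t"
                f"MCS_{i}\t{score}\t+\n"
            )
    finally:
        if close:
            path.close()
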