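"""Read-depth segmental-duplication calling.

Duplicated sequence attracts an excess of whole-genome shotgun reads, so
segmental duplications (SDs) show up as runs of windows with
overrepresented depth of coverage.  This module consumes a windowed
depth profile directly (read recruitment is upstream), estimates the
diploid background by trimmed moments, flags windows exceeding
``mu + k*sigma`` and emits maximal runs of at least ``m`` consecutive
flagged windows as SD calls with copy-number estimates
``2 * mean_depth / background_mean`` (background depth corresponds to
copy number 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DepthProfile:
    """Per-window read counts over one chromosome.

    Windows are contiguous, non-overlapping (``step == window_size``) and
    ordered; window *i* covers ``[i*w, (i+1)*w)`` bp.
    """

    chrom: str
    window_size: int
    counts: np.ndarray
    step: int | None = None

    def __post_init__(self) -> None:
        if self.step is None:
            self.step = self.window_size
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("depth counts must be non-negative")

    @property
    def n_windows(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class SdParams:
    """Calling parameters.

    ``k``: threshold in background standard deviations above the mean.
    ``m``: minimum number of elevated windows per call.
    ``trim_fraction``: fraction trimmed from each tail when estimating the
    background (robustness against the duplications themselves).
    ``merge_gap``: elevated runs separated by at most this many
    background windows are merged into one call — at realistic coverage
    a small fraction of truly duplicated windows dips below the
    ``mu + k*sigma`` cut by Poisson chance, and such single-window
    dropouts should not split a duplication.  Set to 0 for strict
    consecutive runs.
    """

    k: float = 3.0
    m: int = 3
    trim_fraction: float = 0.05
    merge_gap: int = 2

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclass
class SDCall:
    """A called duplication: a merged run of elevated windows."""

    chrom: str
    start: int  # bp, 0-based half-open
    end: int
    n_windows: int
    mean_depth: float
    copy_number_estimate: float


def make_depth_profile(
    read_starts=None,
    per_base_depth=None,
    chrom_length: int | None = None,
    w: int = 1000,
    chrom: str = "chr",
) -> DepthProfile:
    """Bin read start positions (or average per-base depth) into windows.

    Exactly one of ``read_starts`` / ``per_base_depth`` must be given.
    The last partial window is dropped.
    """
    if (read_starts is None) == (per_base_depth is None):
        raise ValueError("provide exactly one of read_starts or per_base_depth")
    if read_starts is not None:
        if chrom_length is None:
            raise ValueError("chrom_length required with read_starts")
        starts = np.asarray(read_starts, dtype=np.int64)
        if starts.size and (starts.min() < 0 or starts.max() >= chrom_length):
            raise ValueError("read positions outside [0, chrom_length)")
        n_win = chrom_length // w
        counts = np.bincount(starts // w, minlength=n_win)[:n_win]
        return DepthProfile(chrom, w, counts.astype(float))
    depth = np.asarray(per_base_depth, dtype=float)
    n_win = depth.size // w
    counts = depth[: n_win * w].reshape(n_win, w).mean(axis=1)
    return DepthProfile(chrom, w, counts)


def estimate_background(
    profile: DepthProfile, trim_fraction: float = 0.05
) -> tuple[float, float]:
    """Trimmed mean and standard deviation of the window counts.

    ``trim_fraction`` of the windows is discarded from each tail of the
    sorted counts before taking moments (sample SD, ddof=1).
    """
    counts = profile.counts
    if counts.size < 10:
        raise ValueError(f"need >= 10 windows, got {counts.size}")
    srt = np.sort(counts)
    cut = int(np.floor(trim_fraction * srt.size))
    core = srt[cut : srt.size - cut] if cut else srt
    mu = float(core.mean())
    sigma = float(core.std(ddof=1)) if core.size > 1 else 0.0
    return mu, sigma


def call_sd(
    profile: DepthProfile,
    params: SdParams = SdParams(),
    background: tuple[float, float] | None = None,
) -> list[SDCall]:
    """Call duplications as runs of depth-elevated windows.

    Windows with ``count > mu + k*sigma`` are flagged; flagged runs
    separated by at most ``merge_gap`` background windows are merged, and
    merged runs containing at least ``m`` flagged windows become calls
    (call boundaries span first to last flagged window).  With a
    degenerate background (``sigma == 0``) any count strictly above
    ``mu`` is flagged.  Deterministic.
    """
    if background is None:
        background = estimate_background(profile, params.trim_fraction)
    mu, sigma = background
    if mu <= 0:
        raise ValueError("background mean must be positive to estimate copy number")
    flagged = np.flatnonzero(profile.counts > mu + params.k * sigma)
    clusters: list[tuple[int, int, int]] = []  # (first, last+1, n_flagged)
    for i in flagged:
        if clusters and i - (clusters[-1][1] - 1) <= params.merge_gap + 1:
            clusters[-1] = (clusters[-1][0], int(i) + 1, clusters[-1][2] + 1)
        else:
            clusters.append((int(i), int(i) + 1, 1))
    calls: list[SDCall] = []
    w = profile.window_size
    for a, b, n_flag in clusters:
        if n_flag < params.m:
            continue
        mean_depth = float(profile.counts[a:b].mean())
        calls.append(
            SDCall(
                chrom=profile.chrom,
                start=int(a) * w,
                end=int(b) * w,
                n_windows=int(b - a),
                mean_depth=mean_depth,
                copy_number_estimate=2.0 * mean_depth / mu,
            )
        )
    return calls


def read_depth_tsv(path, chrom: str = "chr", w: int = 1000) -> DepthProfile:
    """Read a 2-column (position, depth) TSV or 4-column bedGraph."""
    positions: list[int] = []
    depths: list[float] = []
    close = False
    if isinstance(path, (str, bytes)):
        path = open(path)
        close = True
    try:
        for line in path:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) >= 4:  # bedGraph: chrom start end value
                chrom = fields[0]
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
                positions.extend(range(start, end))
                depths.extend([value] * (end - start))
            else:
                positions.append(int(fields[0]))
                depths.append(float(fields[1]))
    finally:
        if close:
            path.close()
    if not positions:
        raise ValueError("empty depth file")
    per_base = np.zeros(max(positions) + 1)
    per_base[np.asarray(positions)] = depths
    return make_depth_profile(per_base_depth=per_base, w=w, chrom=chrom)


def write_calls(calls: list[SDCall], bed_path, tsv_path=None) -> None:
    """Calls as BED6 (copy number in the score slot) plus optional TSV."""
    with open(bed_path, "w") if isinstance(bed_path, (str, bytes)) else _nullcm(bed_path) as fh:
        for i, c in enumerate(calls, start=1):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\tSD_{i}\t"
                f"{c.copy_number_estimate:.2f}\t+\n"
            )
    if tsv_path is not None:
        with open(tsv_path, "w") if isinstance(tsv_path, (str, bytes)) else _nullcm(tsv_path) as fh:
            fh.write("chrom\tstart\tend\tn_windows\tmean_depth\tcopy_number\n")
            for c in calls:
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\t{c.n_windows}\t"
                    f"{c.mean_depth:.3f}\t{c.copy_number_estimate:.3f}\n"
                )


class _nullcm:
    """Context manager passing through an already-open file handle."""

    def __init__(self, fh):
        self.fh = fh

    def __enter__(self):
        return self.fh

    def __exit__(self, *exc):
        return False
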