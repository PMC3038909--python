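"""Interval algebra over BED-style tracks.

Filters conserved elements against coding/transcript annotations
(whole-element removal on any overlap, the enrichment step for non-coding
elements), intersects two element tracks (e.g. the detector's output
against a published conserved-element track), and computes region
coverage.  All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

FEATURE_CLASSES = ("coding", "mRNA", "spliced-EST", "prediction", "other")

#: GFF3 feature types mapped to annotation classes; everything else -> "other"
_GFF3_CLASS = {
    "CDS": "coding",
    "exon": "coding",
    "mRNA": "mRNA",
    "EST_match": "spliced-EST",
    "gene_prediction": "prediction",
}


class TrackFormatError(ValueError):
    """Malformed BED/GFF3 input; the message cites the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    feature_class: str = "other"
    name: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")


@dataclass
class AnnotationSet:
    """A set of annotation intervals indexed for overlap queries."""

    intervals: list[GenomicInterval]
    _index: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for iv in self.intervals:
            self._index.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        tree = self._index.get(chrom)
        if tree is None:
            return []
        return sorted(
            (hit.data for hit in tree.overlap(start, end)),
            key=lambda iv: (iv.start, iv.end),
        )

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._index.get(chrom)
        return tree is not None and bool(tree.overlap(start, end))


@dataclass
class IntersectionReport:
    """Asymmetric overlap report between track A and track B.

    ``shared_count`` counts A-elements with >= 1 bp of overlap in B;
    ``shared_bp`` is the size of the per-base set intersection (symmetric
    in A and B, unlike the count).
    """

    shared_count: int
    shared_bp: int
    fraction_of_region: float
    per_element: list[tuple[tuple, list[tuple], int]]


def load_annotations(path, format: str = "bed") -> AnnotationSet:
    """Load a BED or GFF3 annotation file.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    A malformed line raises :class:`TrackFormatError` citing its number.
    """
    if format not in ("bed", "gff3"):
        raise ValueError(f"unknown annotation format {format!r}")
    intervals: list[GenomicInterval] = []
    close = False
    if isinstance(path, (str, bytes)):
        path = open(path)
        close = True
    try:
        for lineno, line in enumerate(path, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else "."
                    cls = fields[4] if len(fields) > 4 and fields[4] in FEATURE_CLASSES else "other"
                else:
                    if len(fields) < 9:
                        raise ValueError("fewer than 9 GFF3 columns")
                    chrom = fields[0]
                    start = int(fields[3]) - 1  # 1-based inclusive -> 0-based
                    end = int(fields[4])
                    cls = _GFF3_CLASS.get(fields[2], "other")
                    name = _gff3_attr(fields[8], "ID") or fields[2]
                intervals.append(GenomicInterval(chrom, start, end, cls, name))
            except (ValueError, IndexError) as exc:
                raise TrackFormatError(
                    f"{format} parse error at line {lineno}: {line!r} ({exc})"
                ) from exc
    finally:
        if close:
            path.close()
    return AnnotationSet(intervals)


def _gff3_attr(attrs: str, key: str) -> str | None:
    for item in attrs.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def filter_noncoding(mcs: list, ann: AnnotationSet) -> tuple[list, list]:
    """Partition elements into (kept, removed) by annotation overlap.

    An element is removed iff it overlaps ANY annotation interval by at
    least 1 bp — whole-element removal, no trimming.  Works on any object
    with ``ref_chrom``, ``ref_start`` and ``ref_end`` attributes.
    """
    kept, removed = [], []
    for m, (chrom, s, e) in zip(mcs, _as_tuples(mcs)):
        if ann.overlaps(chrom, s, e):
            removed.append(m)
        else:
            kept.append(m)
    return kept, removed


def _as_tuples(intervals) -> list[tuple[str, int, int]]:
    out = []
    for iv in intervals:
        if hasattr(iv, "ref_start"):
            out.append((iv.ref_chrom, iv.ref_start, iv.ref_end))
        elif hasattr(iv, "start"):
            out.append((iv.chrom, iv.start, iv.end))
        else:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            out.append((chrom, start, end))
    return out


def _merge(tuples: list[tuple[str, int, int]]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in sorted(tuples):
        runs = by_chrom.setdefault(chrom, [])
        if runs and s <= runs[-1][1]:
            runs[-1] = (runs[-1][0], max(runs[-1][1], e))
        else:
            runs.append((s, e))
    return by_chrom


def intersect_tracks(a, b, region_bp: int) -> IntersectionReport:
    """Intersect element track A with track B.

    ``shared_count`` is the number of A-elements touched by B;
    ``shared_bp`` the total per-base intersection;
    ``fraction_of_region`` is shared_bp / region_bp.  ``per_element``
    lists, for each shared A-element, the overlapping B-elements and the
    overlap in bp.
    """
    if region_bp <= 0:
        raise ValueError(f"region_bp must be positive, got {region_bp}")
    a_t = _as_tuples(a)
    b_t = _as_tuples(b)
    b_index: dict[str, IntervalTree] = {}
    for chrom, s, e in b_t:
        b_index.setdefault(chrom, IntervalTree()).addi(s, e)
    shared_count = 0
    per_element = []
    for chrom, s, e in a_t:
        tree = b_index.get(chrom)
        hits = sorted((h.begin, h.end) for h in tree.overlap(s, e)) if tree else []
        if hits:
            shared_count += 1
            bp = sum(min(e, he) - max(s, hs) for hs, he in hits)
            per_element.append(((chrom, s, e), [(chrom, hs, he) for hs, he in hits], bp))
    # per-base intersection of the two merged unions
    shared_bp = 0
    a_merged = _merge(a_t)
    b_merged = _merge(b_t)
    for chrom, a_runs in a_merged.items():
        b_runs = b_merged.get(chrom, [])
        i = j = 0
        while i < len(a_runs) and j < len(b_runs):
            lo = max(a_runs[i][0], b_runs[j][0])
            hi = min(a_runs[i][1], b_runs[j][1])
            if hi > lo:
                shared_bp += hi - lo
            if a_runs[i][1] < b_runs[j][1]:
                i += 1
            else:
                j += 1
    return IntersectionReport(
        shared_count=shared_count,
        shared_bp=shared_bp,
        fraction_of_region=shared_bp / region_bp,
        per_element=per_element,
    )


def region_coverage(intervals, region: tuple[str, int, int]) -> float:
    """Fraction of a region covered by the union of (clipped) intervals."""
    chrom, rs, re_ = region
    if re_ <= rs:
        raise ValueError("empty region")
    clipped = [
        (c, max(s, rs), min(e, re_))
        for c, s, e in _as_tuples(intervals)
        if c == chrom and min(e, re_) > max(s, rs)
    ]
    merged = _merge(clipped).get(chrom, [])
    covered = sum(e - s for s, e in merged)
    return covered / (re_ - rs)


def write_bed(intervals, path) -> None:
    """Write intervals (tuples or objects) as minimal BED."""
    close = False
    if isinstance(path, (str, bytes)):
        path = open(path, "w")
        close = True
    try:
        for chrom, s, e in _as_tuples(intervals):
            path.write(f"{chrom}\t{s}\t{e}\n")
    finally:
        if close:
            path.close()
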