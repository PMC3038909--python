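"""CTCF-style binding-motif modelling, logo computation, scanning and
occupancy calling.

A motif model is a per-position nucleotide frequency matrix built from an
ungapped set of orthologous site sequences.  Typical CTCF sites are 20 bp
long with two conserved cores, one over bases 4-8 and one over bases
10-18 (1-based); those core positions are carried on the model for
reporting.  Scanning scores every window by log-odds against a uniform
background and reports hits above a relative-score cutoff; sites are then
grouped into low-, medium- and high-occupancy classes (LowOc/MedOc/
HighOc) from motif-match strength and, optionally, ChIP-seq tag density,
and cross-dataset occupancy patterns are labelled (species-specific vs
shared).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

OCCUPANCY_CLASSES = ("LowOc", "MedOc", "HighOc", "none")


@dataclass
class MotifModel:
    """Per-position nucleotide frequency matrix with conserved-core marks.

    ``freqs`` has shape (length, 4) in A,C,G,T order; rows sum to 1.
    ``core1``/``core2`` are 1-based inclusive position spans of the two
    conserved cores (``None`` for motifs too short to carry them).
    Background is uniform 0.25 per base.
    """

    freqs: np.ndarray
    consensus: str
    pseudocount: float = 0.01
    core1: tuple[int, int] | None = (4, 8)
    core2: tuple[int, int] | None = (10, 18)
    background: float = 0.25

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValueError("freqs must have shape (length, 4)")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("per-position frequencies must sum to 1")
        for core in (self.core1, self.core2):
            if core is not None and not (1 <= core[0] <= core[1] <= self.length):
                raise ValueError(f"core {core} outside [1, {self.length}]")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """log2(f / background) per position and base."""
        return np.log2(self.freqs / self.background)

    @property
    def max_score(self) -> float:
        """Best attainable log-odds sum (score of the consensus)."""
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        """Worst attainable log-odds sum over ACGT windows."""
        return float(self.log_odds.min(axis=1).sum())

    def relative_score(self, score: float) -> float:
        """Normalise a log-odds score to [0, 1].

        0 is the worst and 1 the best attainable window score — the
        standard PSSM relative score, so one mutated base in a long
        motif costs a proportionally small amount.
        """
        span = self.max_score - self.min_score
        if span == 0:  # completely uninformative model
            return 1.0 if np.isfinite(score) else -np.inf
        return (score - self.min_score) / span


@dataclass
class MotifHit:
    """A scored motif occurrence in forward coordinates.

    ``relative_score`` rescales the log-odds score so that the worst
    attainable window is 0 and the consensus is 1; reverse-strand hits
    keep forward start/end with ``strand='-'``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    score: float
    relative_score: float
    occupancy_class: str = "none"

    def __post_init__(self) -> None:
        if self.relative_score > 1 + 1e-12:
            raise ValueError("relative_score cannot exceed 1")


@dataclass(frozen=True)
class OccupancyThresholds:
    """Relative-score cutoffs for the three occupancy classes.

    The source classification combines motif-match strength with mapped
    ChIP-seq tag density; the numeric cutoffs here are explicit tunable
    stand-ins (0.70/0.80/0.90 of the maximum log-odds by default), with an
    optional minimum supporting tag count for the HighOc call.
    """

    tau_low: float = 0.70
    tau_med: float = 0.80
    tau_high: float = 0.90
    tag_density_cut: int | None = None

    def __post_init__(self) -> None:
        if not self.tau_low < self.tau_med < self.tau_high <= 1:
            raise ValueError(
                f"need tau_low < tau_med < tau_high <= 1, got "
                f"{self.tau_low}, {self.tau_med}, {self.tau_high}"
            )


@dataclass
class OccupancyPattern:
    site: tuple[str, int, int]
    per_dataset: dict[str, str]  # dataset -> "occupied" | "unoccupied"
    label: str


def build_motif(
    site_sequences: list[str],
    pseudocount: float = 0.01,
    core1: tuple[int, int] | None = "auto",
    core2: tuple[int, int] | None = "auto",
) -> MotifModel:
    """Build a frequency-matrix model from equal-length ungapped sequences.

    Column frequencies are (count + pseudocount) / (column total + 4 x
    pseudocount); ``N`` contributes to no base.  The consensus is the
    argmax base per column with alphabetical tie-breaking.  Gapped inputs
    are rejected (degap before calling).  With the default ``"auto"`` the
    canonical CTCF cores (bases 4-8 and 10-18) are attached when the
    motif is long enough.
    """
    if len(site_sequences) < 2:
        raise ValueError("need at least 2 site sequences")
    L = len(site_sequences[0])
    counts = np.zeros((L, 4), dtype=float)
    for seq in site_sequences:
        if len(seq) != L:
            raise ValueError(
                f"unequal sequence lengths: {len(seq)} vs {L} ({seq!r})"
            )
        s = seq.upper()
        if "-" in s:
            raise ValueError(f"gapped site sequence not allowed: {seq!r}")
        for j, b in enumerate(s):
            if b in _BASE_INDEX:
                counts[j, _BASE_INDEX[b]] += 1
    freqs = (counts + pseudocount) / (
        counts.sum(axis=1, keepdims=True) + 4 * pseudocount
    )
    consensus = "".join(BASES[j] for j in freqs.argmax(axis=1))
    if core1 == "auto":
        core1 = (4, 8) if L >= 8 else None
    if core2 == "auto":
        core2 = (10, 18) if L >= 18 else None
    return MotifModel(freqs, consensus, pseudocount, core1, core2)


def logo_heights(model: MotifModel) -> tuple[np.ndarray, np.ndarray]:
    """Sequence-logo column statistics.

    Returns ``(ic, heights)``: per-position information content
    ``IC_j = 2 + sum_b f_jb log2 f_jb`` in bits (0 log 0 := 0; no
    small-sample correction) and per-base symbol heights
    ``f_jb * IC_j`` (shape (length, 4)).
    """
    f = model.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(f), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    ic = np.clip(ic, 0.0, 2.0)  # guard FP round-off at the boundaries
    return ic, f * ic[:, None]


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _score_windows(seq: str, model: MotifModel) -> np.ndarray:
    """Log-odds score at every offset; -inf where the window has non-ACGT."""
    L = model.length
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    digits = np.zeros(arr.size, dtype=np.int64)
    valid = np.zeros(arr.size, dtype=bool)
    for i, b in enumerate(BASES.encode("ascii")):
        hit = arr == b
        digits[hit] = i
        valid |= hit
    win = np.lib.stride_tricks.sliding_window_view(digits, L)
    ok = np.lib.stride_tricks.sliding_window_view(valid, L).all(axis=1)
    lom = model.log_odds
    scores = lom[np.arange(L), win].sum(axis=1)
    scores[~ok] = -np.inf
    return scores


def scan_sequence(
    seq: str,
    model: MotifModel,
    min_relative_score: float = 0.70,
    strands: str = "both",
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Slide the model over a sequence and report qualifying hits.

    Every offset is scored on the plus strand and, with
    ``strands="both"``, on the reverse complement as well; hits with
    ``relative_score >= min_relative_score`` are returned sorted by
    position (overlapping hits are all reported).  A sequence shorter
    than the motif yields an empty list.
    """
    if strands not in ("plus", "both"):
        raise ValueError(f"unknown strands {strands!r}")
    L = model.length
    if len(seq) < L:
        return []
    hits: list[MotifHit] = []

    span = model.max_score - model.min_score

    def collect(scores: np.ndarray, strand: str) -> None:
        if span == 0:
            rel = np.where(np.isfinite(scores), 1.0, -np.inf)
        else:
            rel = (scores - model.min_score) / span
        for i in np.flatnonzero(rel >= min_relative_score):
            if strand == "+":
                start = offset + int(i)
            else:
                start = offset + len(seq) - L - int(i)
            hits.append(
                MotifHit(
                    chrom=chrom,
                    start=start,
                    end=start + L,
                    strand=strand,
                    score=float(scores[i]),
                    relative_score=float(rel[i]),
                )
            )

    collect(_score_windows(seq, model), "+")
    if strands == "both":
        collect(_score_windows(reverse_complement(seq), model), "-")
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def classify_occupancy_class(
    hit: "MotifHit | float",
    thresholds: OccupancyThresholds = OccupancyThresholds(),
    tag_count: int | None = None,
) -> str:
    """Assign LowOc/MedOc/HighOc/none from relative score (and tag count).

    Boundaries are inclusive upward (a score exactly at tau_med is
    MedOc).  The HighOc call additionally requires ``tag_count >=
    tag_density_cut`` when both are provided; a strong-motif site failing
    the tag cut falls through to MedOc.  Monotone in relative score.
    """
    rel = hit.relative_score if isinstance(hit, MotifHit) else float(hit)
    tag_ok = (
        thresholds.tag_density_cut is None
        or tag_count is None
        or tag_count >= thresholds.tag_density_cut
    )
    if rel >= thresholds.tau_high and tag_ok:
        return "HighOc"
    if rel >= thresholds.tau_med:
        return "MedOc"
    if rel >= thresholds.tau_low:
        return "LowOc"
    return "none"


def call_site_occupancy(
    site: tuple[str, int, int],
    datasets: dict[str, list[tuple[str, int, int]]],
    dataset_species: dict[str, str],
) -> OccupancyPattern:
    """Call a site occupied/unoccupied per dataset and label the pattern.

    A dataset occupies the site iff any of its intervals overlaps it by
    >= 1 bp.  The label is ``"shared"`` when occupied datasets span >= 2
    species, ``"<species>-specific"`` when they all map to one species,
    and ``"unoccupied"`` otherwise.
    """
    if not datasets:
        raise ValueError("empty dataset map")
    chrom, s, e = site
    per_dataset: dict[str, str] = {}
    occupied_species: set[str] = set()
    for name, ivs in datasets.items():
        occ = any(c == chrom and min(e, ie) > max(s, is_) for c, is_, ie in ivs)
        per_dataset[name] = "occupied" if occ else "unoccupied"
        if occ:
            occupied_species.add(dataset_species[name])
    if not occupied_species:
        label = "unoccupied"
    elif len(occupied_species) == 1:
        label = f"{next(iter(occupied_species))}-specific"
    else:
        label = "shared"
    return OccupancyPattern(site=site, per_dataset=per_dataset, label=label)


def write_meme(model: MotifModel, path, name: str = "MOTIF1") -> None:
    """Write the model in MEME minimal format."""
    close = False
    if isinstance(path, (str, bytes)):
        path = open(path, "w")
        close = True
    try:
        path.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        path.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        path.write(f"MOTIF {name}\n")
        path.write(
            f"letter-probability matrix: alength= 4 w= {model.length}\n"
        )
        for row in model.freqs:
            path.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
    finally:
        if close:
            path.close()


def write_logo_tsv(model: MotifModel, path) -> None:
    """Logo table: position (1-based), base, height, column IC."""
    ic, heights = logo_heights(model)
    close = False
    if isinstance(path, (str, bytes)):
        path = open(path, "w")
        close = True
    try:
        path.write("position\tbase\theight\tic\n")
        for j in range(model.length):
            for k, b in enumerate(BASES):
                path.write(f"{j + 1}\t{b}\t{heights[j, k]:.6f}\t{ic[j]:.6f}\n")
    finally:
        if close:
            path.close()


def write_hits_bed(hits: list[MotifHit], path) -> None:
    """Hits as BED6; score slot carries relative score scaled to 0-1000."""
    close = False
    if isinstance(path, (str, bytes)):
        path = open(path, "w")
        close = True
    try:
        for i, h in enumerate(hits, start=1):
            score = max(0, round(1000 * h.relative_score))
            path.write(
                f"{h.chrom}\t{h.start}\t{h.end}\thit_{i}\t{score}\t{h.strand}\n"
            )
    finally:
        if close:
            path.close()


def plot_logo(model: MotifModel, ax=None):  # pragma: no cover - decoration
    """Rudimentary matplotlib sequence logo (letters as scaled text)."""
    import matplotlib.pyplot as plt

    ic, heights = logo_heights(model)
    if ax is None:
        _, ax = plt.subplots(figsize=(0.45 * model.length, 2.2))
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    for j in range(model.length):
        y = 0.0
        for k in np.argsort(heights[j]):
            h = heights[j, k]
            if h <= 0:
                continue
            b = BASES[k]
            ax.text(
                j + 0.5, y, b, ha="center", va="bottom",
                fontsize=18, color=colors[b],
                transform=ax.transData,
                fontstretch="condensed",
                clip_on=True,
            )
            y += h
    ax.set_xlim(0, model.length)
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xticks(np.arange(model.length) + 0.5)
    ax.set_xticklabels(np.arange(1, model.length + 1))
    return ax
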