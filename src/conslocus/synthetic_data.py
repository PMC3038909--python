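"""Synthetic inputs with planted ground truth.

Every pipeline stage can be exercised without external data: a
multi-species alignment simulator (a reference sequence from which the
other species diverge site-wise, with planted low-divergence conserved
blocks and single-column gaps), a motif-instance planter, and a Poisson
read-depth simulator with copy-number-elevated segments.

All generators are pure functions of their spec, seed included —
identical specs give byte-identical output.  The substitution model is a
site-independent uniform flip to one of the other three bases; the
exact-match detector responds only to per-column agreement counts, so no
phylogenetic branch structure is modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from conslocus.alignment_io import MultiAlignment
from conslocus.motif_scan import MotifModel, BASES
from conslocus.sd_depth import DepthProfile

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAP_BYTE = ord("-")


@dataclass(frozen=True)
class PlantedBlock:
    """A conserved block: low divergence in the first ``conserved_species_count``
    rows (the reference counts as one of them) over columns [start, end)."""

    start: int
    end: int
    conserved_species_count: int = 5
    within_block_mismatch: float = 0.0


@dataclass
class SimAlignmentSpec:
    n_species: int = 7
    length: int = 1000
    background_mismatch: float = 0.5
    gap_rate: float = 0.0
    planted_blocks: list[PlantedBlock] = field(default_factory=list)
    rng_seed: int = 0
    ref_chrom: str = "chrS"
    ref_offset: int = 0

    def validate(self) -> None:
        if self.n_species < 2 or self.length < 1:
            raise ValueError("need >= 2 species and >= 1 column")
        for p in (self.background_mismatch, self.gap_rate):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        prev_end = 0
        for b in sorted(self.planted_blocks, key=lambda b: b.start):
            if not (0 <= b.start < b.end <= self.length):
                raise ValueError(f"block ({b.start}, {b.end}) outside alignment")
            if b.start < prev_end:
                raise ValueError("planted blocks overlap")
            if not 1 <= b.conserved_species_count <= self.n_species:
                raise ValueError("conserved_species_count out of range")
            if not 0 <= b.within_block_mismatch <= 1:
                raise ValueError("within_block_mismatch outside [0, 1]")
            prev_end = b.end


@dataclass(frozen=True)
class PlantedDup:
    start: int  # bp
    end: int
    copy_number: float = 4.0


@dataclass
class SimDepthSpec:
    genome_length: int = 1_000_000
    mean_depth: float = 20.0  # expected reads per window at copy number 2
    window_size: int = 1000
    planted_dups: list[PlantedDup] = field(default_factory=list)
    rng_seed: int = 0
    chrom: str = "chrS"

    def validate(self) -> None:
        if self.genome_length < self.window_size:
            raise ValueError("genome shorter than one window")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")
        prev_end = 0
        for d in sorted(self.planted_dups, key=lambda d: d.start):
            if not (0 <= d.start < d.end <= self.genome_length):
                raise ValueError(f"dup ({d.start}, {d.end}) outside genome")
            if d.start < prev_end:
                raise ValueError("planted dups overlap")
            if d.copy_number < 1:
                raise ValueError("copy_number must be >= 1")
            prev_end = d.end


@dataclass
class SyntheticTruth:
    """Planted features, in the coordinates of the simulated object."""

    blocks: list[PlantedBlock] = field(default_factory=list)
    motif_positions: list[int] = field(default_factory=list)
    dup_intervals: list[PlantedDup] = field(default_factory=list)
    rng_seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "rng_seed": self.rng_seed,
            "blocks": [asdict(b) for b in self.blocks],
            "motif_positions": list(self.motif_positions),
            "dup_intervals": [asdict(d) for d in self.dup_intervals],
        }
        close = False
        if isinstance(path, (str, bytes)):
            path = open(path, "w")
            close = True
        try:
            json.dump(payload, path, indent=1)
        finally:
            if close:
                path.close()


def simulate_alignment(spec: SimAlignmentSpec) -> tuple[MultiAlignment, SyntheticTruth]:
    """Draw a reference row and diverge the other species from it.

    Outside planted blocks every non-reference species substitutes each
    site with ``background_mismatch`` (uniformly to one of the other
    three bases) and gaps each site with ``gap_rate``.  Inside a block,
    the first ``conserved_species_count`` rows (reference included) use
    the block's ``within_block_mismatch`` instead and receive no gaps.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n, L = spec.n_species, spec.length
    ref_digits = rng.integers(0, 4, size=L)
    rows = [_BASE_ARR[ref_digits].tobytes().decode()]

    # per-(species, site) mismatch rate and gap mask
    for s in range(1, n):
        rate = np.full(L, spec.background_mismatch)
        gap_ok = np.ones(L, dtype=bool)
        for b in spec.planted_blocks:
            if s < b.conserved_species_count:
                rate[b.start : b.end] = b.within_block_mismatch
                gap_ok[b.start : b.end] = False
        mutate = rng.random(L) < rate
        # uniform flip to one of the other three bases
        shift = rng.integers(1, 4, size=L)
        digits = np.where(mutate, (ref_digits + shift) % 4, ref_digits)
        row = _BASE_ARR[digits].copy()
        gaps = (rng.random(L) < spec.gap_rate) & gap_ok
        row[gaps] = _GAP_BYTE
        rows.append(row.tobytes().decode())

    names = ["ref"] + [f"sp{i}" for i in range(1, n)]
    aln = MultiAlignment(
        species_names=names,
        rows=rows,
        reference_index=0,
        ref_chrom=spec.ref_chrom,
        ref_offset=spec.ref_offset,
    )
    truth = SyntheticTruth(blocks=list(spec.planted_blocks), rng_seed=spec.rng_seed)
    return aln, truth


def simulate_motif_dataset(
    background_length: int,
    model: MotifModel,
    n_sites: int,
    per_position_mutation: float = 0.05,
    rng_seed: int = 0,
) -> tuple[str, SyntheticTruth]:
    """Plant motif instances at non-overlapping uniform positions.

    Each instance is the model consensus with every position mutated
    independently with ``per_position_mutation`` (to one of the other
    three bases).  The background is uniform random sequence.
    """
    L = model.length
    if n_sites * L > background_length / 2:
        raise ValueError(
            f"{n_sites} sites of {L} bp overcrowd a {background_length} bp background"
        )
    rng = np.random.default_rng(rng_seed)
    seq = _BASE_ARR[rng.integers(0, 4, size=background_length)].copy()
    positions: list[int] = []
    attempts = 0
    while len(positions) < n_sites:
        attempts += 1
        if attempts > 1000 * max(n_sites, 1):
            raise ValueError("could not place non-overlapping sites")
        p = int(rng.integers(0, background_length - L + 1))
        if any(p < q + L and q < p + L for q in positions):
            continue
        positions.append(p)
    consensus_digits = np.array([BASES.index(b) for b in model.consensus])
    for p in sorted(positions):
        mutate = rng.random(L) < per_position_mutation
        shift = rng.integers(1, 4, size=L)
        digits = np.where(mutate, (consensus_digits + shift) % 4, consensus_digits)
        seq[p : p + L] = _BASE_ARR[digits]
    truth = SyntheticTruth(motif_positions=sorted(positions), rng_seed=rng_seed)
    return seq.tobytes().decode(), truth


def simulate_depth(spec: SimDepthSpec) -> tuple[DepthProfile, SyntheticTruth]:
    """Poisson window counts with copy-number-elevated planted segments.

    Window counts are Poisson with mean ``mean_depth * cn/2`` where the
    effective copy number ``cn`` of a window is 2 plus the planted excess
    weighted by the fraction of the window inside the duplication.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    w = spec.window_size
    n_win = spec.genome_length // w
    cn = np.full(n_win, 2.0)
    for d in spec.planted_dups:
        for i in range(d.start // w, min(n_win - 1, (d.end - 1) // w) + 1):
            lo, hi = i * w, (i + 1) * w
            frac = (min(hi, d.end) - max(lo, d.start)) / w
            cn[i] += (d.copy_number - 2.0) * frac
    counts = rng.poisson(spec.mean_depth * cn / 2.0).astype(float)
    profile = DepthProfile(chrom=spec.chrom, window_size=w, counts=counts)
    truth = SyntheticTruth(dup_intervals=list(spec.planted_dups), rng_seed=spec.rng_seed)
    return profile, truth


def write_depth_bedgraph(profile: DepthProfile, path) -> None:
    close = False
    if isinstance(path, (str, bytes)):
        path = open(path, "w")
        close = True
    try:
        w = profile.window_size
        for i, c in enumerate(profile.counts):
            path.write(f"{profile.chrom}\t{i * w}\t{(i + 1) * w}\t{c:g}\n")
    finally:
        if close:
            path.close()
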