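"""Multiple-alignment I/O and reference-coordinate projection.

A :class:`MultiAlignment` holds equal-length gapped rows over
``{A,C,G,T,N,-}`` with one row designated as the reference species.  All
coordinates are 0-based half-open internally (BED convention); the
reference offset anchors alignment columns to genome positions so that
detected elements can be reported as BED intervals.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN-")
GAP = "-"

#: sentinel in RefCoordMap.column_to_ref for columns where the reference is gapped
REF_GAP = -1

_VALID_RE = re.compile(r"[^ACGTN-]")


class AlignmentFormatError(ValueError):
    """Raised for structurally invalid alignment input."""


@dataclass
class MultiAlignment:
    """An equal-length gapped alignment of several species.

    Parameters
    ----------
    species_names : list of str
        Unique identifiers, one per row.
    rows : list of str
        Upper-case strings over ``{A,C,G,T,N,-}``, all the same length.
    reference_index : int
        Index of the reference species row.
    ref_chrom : str
        Chromosome/sequence name of the reference.
    ref_offset : int
        0-based genome coordinate of the first non-gap reference base.
    """

    species_names: list[str]
    rows: list[str]
    reference_index: int = 0
    ref_chrom: str = "chr"
    ref_offset: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentFormatError("alignment has no rows")
        if len(self.species_names) != len(self.rows):
            raise AlignmentFormatError("species_names and rows differ in length")
        if len(set(self.species_names)) != len(self.species_names):
            raise AlignmentFormatError("species names are not unique")
        ncol = len(self.rows[0])
        if ncol < 1:
            raise AlignmentFormatError("alignment has zero columns")
        for name, row in zip(self.species_names, self.rows):
            if len(row) != ncol:
                raise AlignmentFormatError(
                    f"row {name!r} has length {len(row)}, expected {ncol}"
                )
        if not 0 <= self.reference_index < len(self.rows):
            raise IndexError("reference_index out of range")
        ref = self.rows[self.reference_index]
        if set(ref) <= {GAP}:
            raise AlignmentFormatError("reference row contains no non-gap base")

    @property
    def n_species(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def reference_name(self) -> str:
        return self.species_names[self.reference_index]

    @property
    def reference_row(self) -> str:
        return self.rows[self.reference_index]

    @property
    def ref_length(self) -> int:
        """Number of reference bases covered (non-gap reference columns)."""
        return self.n_columns - self.reference_row.count(GAP)

    def to_matrix(self) -> np.ndarray:
        """Return the alignment as a (n_species, n_columns) byte matrix."""
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_species, self.n_columns)


@dataclass
class RefCoordMap:
    """Bidirectional map between alignment columns and reference positions.

    ``column_to_ref[i]`` is the 0-based reference position of column *i*,
    or :data:`REF_GAP` where the reference row is gapped.  Restricted to
    non-gap columns the map is strictly increasing and bijective.
    """

    column_to_ref: np.ndarray
    ref_to_column: dict[int, int] = field(repr=False)

    def ref_span(self, col_start: int, col_end: int) -> tuple[int, int] | None:
        """Reference interval covered by columns [col_start, col_end).

        Reference-gap columns at either edge are trimmed; returns ``None``
        if every column in the span is a reference gap.
        """
        span = self.column_to_ref[col_start:col_end]
        covered = span[span != REF_GAP]
        if covered.size == 0:
            return None
        return int(covered[0]), int(covered[-1]) + 1


def _clean_row(name: str, seq: str) -> str:
    row = seq.upper()
    if _VALID_RE.search(row):
        bad = sorted(set(_VALID_RE.findall(row)))
        log.warning("row %r: characters %s mapped to N", name, bad)
        row = _VALID_RE.sub("N", row)
    return row


def parse_alignment(
    path,
    format: str = "aligned-fasta",
    reference_name: str | None = None,
    ref_chrom: str | None = None,
    ref_offset: int | None = None,
) -> MultiAlignment:
    """Read a multiple alignment from aligned multi-FASTA or MAF.

    For MAF, only the first block is read (locus-scale inputs are single
    blocks) and the reference line's ``start`` field supplies
    ``ref_offset``; a minus-strand reference line is rejected.  Lower-case
    bases are upper-cased and characters outside ``{A,C,G,T,N,-}`` become
    ``N`` with a logged warning.

    Parameters
    ----------
    path : str or file-like
    format : {"aligned-fasta", "maf"}
    reference_name : str, optional
        Species to use as reference; defaults to the first record.  For
        MAF the name matches either the full ``src`` (``mouse.chr11``) or
        its species prefix (``mouse``).
    ref_chrom, ref_offset :
        Override the reference chromosome/offset (mainly for FASTA input,
        which carries no coordinates; defaults "chr" and 0).
    """
    if format == "aligned-fasta":
        try:
            aln = AlignIO.read(path, "fasta")
        except ValueError as exc:
            raise AlignmentFormatError(str(exc)) from exc
        names = [rec.id for rec in aln]
        rows = [_clean_row(rec.id, str(rec.seq)) for rec in aln]
        off = 0 if ref_offset is None else ref_offset
        chrom = "chr" if ref_chrom is None else ref_chrom
        ref_idx = 0
        if reference_name is not None:
            if reference_name not in names:
                raise KeyError(f"reference {reference_name!r} not in alignment")
            ref_idx = names.index(reference_name)
        return MultiAlignment(names, rows, ref_idx, chrom, off)

    if format == "maf":
        try:
            block = next(AlignIO.parse(path, "maf"))
        except StopIteration:
            raise AlignmentFormatError("MAF file contains no alignment block")
        names, rows, annot = [], [], []
        for rec in block:
            names.append(rec.id)
            rows.append(_clean_row(rec.id, str(rec.seq)))
            annot.append(rec.annotations)
        ref_idx = 0
        if reference_name is not None:
            ref_idx = _find_maf_reference(names, reference_name)
        if annot[ref_idx].get("strand", 1) != 1:
            raise AlignmentFormatError(
                "reference MAF line is on the minus strand; only plus-strand "
                "reference alignments are supported"
            )
        src = names[ref_idx]
        chrom = src.split(".", 1)[1] if "." in src else src
        off = int(annot[ref_idx]["start"])
        if ref_chrom is not None:
            chrom = ref_chrom
        if ref_offset is not None:
            off = ref_offset
        return MultiAlignment(names, rows, ref_idx, chrom, off)

    raise ValueError(f"unknown alignment format {format!r}")


def _find_maf_reference(names: list[str], reference_name: str) -> int:
    for i, n in enumerate(names):
        if n == reference_name or n.split(".", 1)[0] == reference_name:
            return i
    raise KeyError(f"reference {reference_name!r} not in MAF block")


def write_alignment(aln: MultiAlignment, path) -> None:
    """Write as aligned multi-FASTA (round-trips rows and names exactly)."""
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(aln.species_names, aln.rows)
    )
    AlignIO.write(msa, path, "fasta")


def project_to_reference(aln: MultiAlignment) -> RefCoordMap:
    """Map each alignment column to its reference genome position.

    Non-gap reference columns map to ``ref_offset, ref_offset+1, ...``;
    columns where the reference row is gapped map to :data:`REF_GAP`.
    """
    ref = np.frombuffer(aln.reference_row.encode("ascii"), dtype=np.uint8)
    nongap = ref != ord(GAP)
    col_to_ref = np.full(aln.n_columns, REF_GAP, dtype=np.int64)
    col_to_ref[nongap] = aln.ref_offset + np.arange(int(nongap.sum()))
    ref_to_col = {int(r): int(c) for c, r in enumerate(col_to_ref) if r != REF_GAP}
    return RefCoordMap(column_to_ref=col_to_ref, ref_to_column=ref_to_col)


def percent_identity(a: str, b: str, mode: str = "all-columns") -> float:
    """Percent identity between two pre-aligned sequences.

    ``all-columns`` divides matches by the full alignment length;
    ``ungapped-columns`` excludes columns where either sequence is gapped.
    ``N`` never counts as a match, to itself or anything else.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if mode not in ("all-columns", "ungapped-columns"):
        raise ValueError(f"unknown mode {mode!r}")
    a = a.upper()
    b = b.upper()
    matches = 0
    denom = 0
    for x, y in zip(a, b):
        if mode == "ungapped-columns" and (x == GAP or y == GAP):
            continue
        denom += 1
        if x == y and x not in (GAP, "N"):
            matches += 1
    if denom == 0:
        raise ZeroDivisionError("no comparable columns")
    return 100.0 * matches / denom
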