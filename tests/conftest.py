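import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


def random_alignment_rows(rng, n_species, n_cols, mismatch, gap_rate, n_rate=0.0):
    """Random gapped rows derived from a shared ancestral sequence."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    ref = rng.integers(0, 4, size=n_cols)
    rows = []
    for s in range(n_species):
        digits = np.where(
            rng.random(n_cols) < mismatch,
            (ref + rng.integers(1, 4, size=n_cols)) % 4,
            ref,
        )
        row = bases[digits].copy()
        row[rng.random(n_cols) < gap_rate] = ord("-")
        row[rng.random(n_cols) < n_rate] = ord("N")
        rows.append(row.tobytes().decode())
    # keep the reference row usable: ensure at least one non-gap base
    if set(rows[0]) <= {"-"}:
        rows[0] = "A" + rows[0][1:]
    return rows


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
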