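import numpy as np
import pytest

from tetragam.data import DoseMatrix, GameteMatrix, MarkerDef


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_markers(n, chromosome="1", role="other", start_bp=1000, step_bp=1000):
    return [
        MarkerDef(f"S{chromosome}_{start_bp + j * step_bp}", chromosome,
                  start_bp + j * step_bp, role)
        for j in range(n)
    ]


@pytest.fixture
def small_doses():
    markers = make_markers(4)
    dose = np.array(
        [
            [0.0, 1.0, 2.0, 1.0],
            [1.0, 1.0, np.nan, 0.0],
            [2.0, 0.0, 1.0, 1.0],
        ]
    )
    return DoseMatrix(samples=["h1", "h2", "h3"], markers=markers, dose=dose)


def gametes_from_counts(counts_per_marker, chromosome="1", roles=None):
    """Build a GameteMatrix whose column tallies equal the given counts.

    ``counts_per_marker`` is a list of (n_AA, n_AM, n_MM); all markers share
    the same number of gametes.
    """
    n = sum(counts_per_marker[0])
    assert all(sum(c) == n for c in counts_per_marker)
    cols = []
    for n_aa, n_am, n_mm in counts_per_marker:
        cols.append(np.array([0] * n_aa + [1] * n_am + [2] * n_mm, dtype=np.int8))
    roles = roles or ["other"] * len(counts_per_marker)
    markers = [
        MarkerDef(f"S{chromosome}_{1000 * (j + 1)}", chromosome, 1000 * (j + 1), roles[j])
        for j in range(len(counts_per_marker))
    ]
    return GameteMatrix(
        gametes=[f"g{i}" for i in range(n)],
        markers=markers,
        genotype=np.column_stack(cols),
    )
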