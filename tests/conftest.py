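"""Shared fixtures and independent brute-force oracles.

The oracles re-derive expected results by direct enumeration, independently
of the library code paths they check: a window-by-window motif scanner, the
Benjamini-Hochberg step-up definition applied literally, and a positional
sequence comparator.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctrascan.motif import MotifModel, build_pwm_from_consensus, reverse_complement

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COLS = "ACGT"


def naive_score(model: MotifModel, window: str) -> float:
    """Score one window by explicit per-position lookup."""
    total = 0.0
    for i, ch in enumerate(window.upper()):
        col = _COLS.find(ch)
        if col >= 0:
            total += model.weights[i, col]
    return total


def naive_scan(
    model: MotifModel, sequence: str, threshold_fraction: float, strands: str
) -> list[tuple[int, str, float]]:
    """Enumerate every window on the requested strands; return passing ones.

    Hits are (offset-of-leftmost-base-on-sequence, strand, score), sorted by
    offset then strand, mirroring the scanner's reporting convention.
    """
    L = model.length
    maximum = model.max_score
    threshold = threshold_fraction * maximum - 1e-9 * max(1.0, abs(maximum))
    hits = []
    for off in range(len(sequence) - L + 1):
        s = naive_score(model, sequence[off : off + L])
        if s >= threshold:
            hits.append((off, "+", s))
    if strands == "both":
        rc = reverse_complement(sequence)
        for off in range(len(rc) - L + 1):
            s = naive_score(model, rc[off : off + L])
            if s >= threshold:
                hits.append((len(sequence) - L - off, "-", s))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def naive_bh(pvalues) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{k>=i} m p_(k)/k."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = np.inf
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        running_min = min(running_min, m * p[idx] / (rank_from_top + 1))
        adjusted[idx] = min(running_min, 1.0)
    return adjusted


def random_motif_model(rng: np.random.Generator) -> MotifModel:
    """A random small model: consensus-like or arbitrary non-negative matrix."""
    length = int(rng.integers(4, 13))
    if rng.random() < 0.5:
        letters = rng.choice(list("ACGTN"), size=length, p=[0.2] * 4 + [0.2])
        consensus = "".join(letters)
        if all(c == "N" for c in consensus):
            consensus = consensus[:-1] + "A"
        return build_pwm_from_consensus(consensus)
    weights = rng.uniform(0, 2, size=(length, 4))
    return MotifModel(weights=weights)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def consensus_model() -> MotifModel:
    return build_pwm_from_consensus("TTAANNNNNNNTTAAC")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
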