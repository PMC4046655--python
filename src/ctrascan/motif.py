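"""Position-weight-matrix models of the CtrA binding box and sequence scanning.

The CtrA response regulator recognises a bipartite DNA box whose canonical
consensus is ``TTAA-N7-TTAAC`` (two half-sites separated by a seven-base
spacer).  A motif model assigns every position a non-negative weight per base;
a window's score is the sum of the weights of its bases, and a site is called
wherever the score reaches a fixed fraction (default 85%) of the maximum
achievable score.

Two constructors are provided: from an IUPAC consensus string (each specified
position contributes weight 1, ``N`` positions contribute nothing) and from a
numeric length x 4 weight table.  Scanning covers one or both strands and
reports every window above threshold; overlapping hits are all kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Canonical CtrA box consensus: TTAA, seven-base spacer, TTAAC.
CTRA_CONSENSUS = "TTAANNNNNNNTTAAC"

#: Fraction of the maximum PWM score a window must reach to be called a site.
DEFAULT_THRESHOLD_FRACTION = 0.85

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a DNA string (non-ACGTN characters pass through)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifModel:
    """A per-position, per-base scoring model over the DNA alphabet.

    Attributes
    ----------
    weights
        Array of shape ``(length, 4)`` with columns in A, C, G, T order.
        All entries are non-negative after construction.
    source
        ``"consensus"`` or ``"matrix"`` depending on the constructor used.
    """

    weights: np.ndarray
    source: str = "matrix"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise ValueError("weights must be a (length x 4) array with length >= 1")
        if not np.isfinite(w).all():
            raise ValueError("weights must be finite")
        if (w < 0).any():
            raise ValueError("weights must be non-negative; rescale the matrix first")
        object.__setattr__(self, "weights", w)

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def max_score(self) -> float:
        """Sum over positions of the per-position maximum weight."""
        return float(self.weights.max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    """One above-threshold window in a scanned sequence.

    ``offset`` is the 0-based position of the match's leftmost base on the
    scanned sequence regardless of strand; ``perfect`` flags windows that
    attain the model maximum (the "perfect site" of the regulon analysis, as
    opposed to a merely "conserved" one passing the threshold).
    """

    offset: int
    strand: str
    score: float
    score_fraction: float
    perfect: bool


def build_pwm_from_consensus(consensus: str) -> MotifModel:
    """Build a motif model from an A/C/G/T/N consensus string.

    Each specified position gets weight 1 for its base and 0 otherwise; ``N``
    positions are all-zero and never contribute to the score or the maximum.
    The maximum score therefore equals the number of non-N positions.
    """
    if not consensus:
        raise ValueError("consensus string is empty")
    consensus = consensus.upper()
    weights = np.zeros((len(consensus), 4))
    for i, ch in enumerate(consensus):
        if ch == "N":
            continue
        if ch not in _BASE_INDEX:
            raise ValueError(
                f"illegal consensus character {ch!r} at position {i + 1}"
            )
        weights[i, _BASE_INDEX[ch]] = 1.0
    return MotifModel(weights=weights, source="consensus")


def build_pwm_from_matrix(
    matrix: Sequence[Sequence[float]] | np.ndarray, rescale: bool = True
) -> MotifModel:
    """Build a motif model from a length x 4 numeric table (columns A,C,G,T).

    With ``rescale`` (the default) each position has its minimum weight
    subtracted so all weights are non-negative.  This keeps the within-position
    ranking intact while making the fraction-of-maximum threshold well defined
    for log-odds-style matrices with negative entries.
    """
    try:
        w = np.array(matrix, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"motif matrix is not numeric/rectangular: {exc}") from exc
    if w.ndim != 2 or w.shape[1] != 4:
        raise ValueError(
            f"motif matrix must have exactly 4 columns (A,C,G,T); got shape {w.shape}"
        )
    if not np.isfinite(w).all():
        raise ValueError("motif matrix contains non-finite values")
    if rescale:
        w = w - w.min(axis=1, keepdims=True)
    return MotifModel(weights=w, source="matrix")


def _encode(sequence: str) -> np.ndarray:
    """Map a DNA string to integer codes A,C,G,T -> 0..3, anything else -> 4."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def score_window(model: MotifModel, window: str) -> float:
    """Score a single window of exactly the model's length.

    Characters outside A/C/G/T contribute 0 at their position.
    """
    if len(window) != model.length:
        raise ValueError(
            f"window length {len(window)} != motif length {model.length}"
        )
    codes = _encode(window)
    padded = np.hstack([model.weights, np.zeros((model.length, 1))])
    return float(padded[np.arange(model.length), codes].sum())


def scan_sequence(
    model: MotifModel,
    sequence: str,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    strands: str = "both",
) -> list[MotifHit]:
    """Report every window scoring at least ``threshold_fraction * max_score``.

    Hits are sorted by offset, then strand; reverse-strand hits are reported
    at the offset of the match's leftmost base on the given sequence.
    Overlapping hits are all reported.
    """
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    max_score = model.max_score
    if max_score == 0:
        raise ValueError(
            "model max_score is 0 (all-N consensus?): threshold is undefined"
        )
    n, L = len(sequence), model.length
    if n < L:
        logger.warning(
            "sequence (length %d) shorter than motif (length %d): no hits", n, L
        )
        return []

    threshold = threshold_fraction * max_score
    hits: list[MotifHit] = []

    def _collect(seq: str, strand: str) -> None:
        codes = _encode(seq)
        padded = np.hstack([model.weights, np.zeros((L, 1))])
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        scores = padded[np.arange(L)[None, :], windows].sum(axis=1)
        # tiny epsilon guards float threshold comparisons on rescaled matrices
        eps = 1e-9 * max(1.0, abs(max_score))
        for off in np.flatnonzero(scores >= threshold - eps):
            s = float(scores[off])
            offset = int(off) if strand == "+" else n - L - int(off)
            hits.append(
                MotifHit(
                    offset=offset,
                    strand=strand,
                    score=s,
                    score_fraction=s / max_score,
                    perfect=bool(abs(s - max_score) <= eps),
                )
            )

    _collect(sequence, "+")
    if strands == "both":
        _collect(reverse_complement(sequence), "-")
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# File interfaces


def read_matrix_tsv(path: str | Path, rescale: bool = True) -> MotifModel:
    """Read a motif weight matrix from TSV with header ``pos A C G T``."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BASES if c not in df.columns]
    if missing:
        raise ValueError(f"matrix file {path} lacks columns {missing}")
    if "pos" in df.columns:
        df = df.sort_values("pos")
    return build_pwm_from_matrix(df[list(BASES)].to_numpy(), rescale=rescale)


def write_matrix_tsv(model: MotifModel, path: str | Path) -> None:
    df = pd.DataFrame(model.weights, columns=list(BASES))
    df.insert(0, "pos", np.arange(1, model.length + 1))
    df.to_csv(path, sep="\t", index=False)


def hits_to_frame(
    hits_by_sequence: Iterable[tuple[str, Iterable[MotifHit]]]
) -> pd.DataFrame:
    """Tabulate hits as (sequence_id, offset, strand, score, score_fraction, perfect)."""
    rows = [
        {
            "sequence_id": seq_id,
            "offset": h.offset,
            "strand": h.strand,
            "score": h.score,
            "score_fraction": h.score_fraction,
            "perfect": h.perfect,
        }
        for seq_id, hits in hits_by_sequence
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["sequence_id", "offset", "strand", "score", "score_fraction", "perfect"],
    )


def write_hits_tsv(
    hits_by_sequence: Iterable[tuple[str, Iterable[MotifHit]]], path: str | Path
) -> None:
    hits_to_frame(hits_by_sequence).to_csv(path, sep="\t", index=False)
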