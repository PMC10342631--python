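"""Sequence-complexity and composition metrics for the filter cascade.

Two complexity statistics are used to discard low-complexity repeat
consensuses and spacers:

* **DUST score** — a triplet-redundancy statistic.  With ``k = L - 2``
  overlapping triplet positions and ``c_t`` the count of each distinct
  triplet, the score is ``sum_t c_t (c_t - 1) / 2`` divided by ``k - 1``.
  A sequence whose triplets are all distinct scores 0; a homopolymer of
  length L scores ``(L-2)(L-3)/2 / (L-3)``, far above any sensible cutoff.
  Higher means *lower* complexity.

* **Trifonov (linguistic) complexity** — the product over word sizes
  ``m = 1..M`` of the observed m-mer vocabulary size divided by its maximum
  possible value ``min(4^m, L - m + 1)``.  Equals 1 only when every
  vocabulary is saturated; tends to 0 for repetitive sequences.  The word
  size cap defaults to ``M = min(7, L - 1)`` since vocabularies of short
  repeat consensuses saturate trivially beyond that.
"""

from __future__ import annotations

from collections import Counter
from itertools import product as _iproduct

import numpy as np

__all__ = [
    "ComplexityScores",
    "dust_score",
    "trifonov_complexity",
    "gc_content",
    "tetranucleotide_profile",
    "TETRAMERS",
]

_ACGT = set("ACGT")

TETRAMERS: tuple[str, ...] = tuple(
    "".join(p) for p in _iproduct("ACGT", repeat=4)
)
_TETRA_INDEX = {t: i for i, t in enumerate(TETRAMERS)}


def _check_acgt(seq: str) -> None:
    if set(seq) - _ACGT:
        bad = sorted(set(seq) - _ACGT)
        raise ValueError(f"sequence contains non-ACGT symbols: {bad}")


from dataclasses import dataclass


@dataclass(frozen=True)
class ComplexityScores:
    """Bundle of the three per-sequence composition statistics."""

    dust: float
    trifonov: float
    gc_percent: float


def dust_score(seq: str) -> float:
    """Triplet-redundancy score; 0 when every overlapping triplet is unique.

    Returns 0 for sequences too short to evaluate (fewer than 2 triplets).
    """
    if len(seq) < 1:
        raise ValueError("empty sequence")
    _check_acgt(seq)
    k = len(seq) - 2
    if k < 2:
        return 0.0
    counts = Counter(seq[i : i + 3] for i in range(k))
    raw = sum(c * (c - 1) // 2 for c in counts.values())
    return raw / (k - 1)


def trifonov_complexity(seq: str, max_word: int = 7) -> float:
    """Linguistic complexity: product of vocabulary-saturation fractions.

    ``prod_{m=1..M} V_m / min(4^m, L - m + 1)`` with ``M = min(max_word, L-1)``.
    """
    length = len(seq)
    if length < 2:
        raise ValueError("need at least 2 bp")
    _check_acgt(seq)
    m_cap = min(max_word, length - 1)
    score = 1.0
    for m in range(1, m_cap + 1):
        observed = len({seq[i : i + m] for i in range(length - m + 1)})
        possible = min(4 ** m, length - m + 1)
        score *= observed / possible
    return score


def gc_content(seq: str) -> float:
    """GC content in percent (0-100)."""
    if not seq:
        raise ValueError("empty sequence")
    _check_acgt(seq)
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def complexity_scores(seq: str, max_word: int = 7) -> ComplexityScores:
    return ComplexityScores(
        dust=dust_score(seq),
        trifonov=trifonov_complexity(seq, max_word),
        gc_percent=gc_content(seq),
    )


def tetranucleotide_profile(seq: str) -> np.ndarray:
    """Overlapping 4-mer frequency vector (length 256, lexicographic order,
    sums to 1).  Used for alignment-free comparison of repeat consensuses."""
    if len(seq) < 4:
        raise ValueError("need at least 4 bp for a tetranucleotide profile")
    _check_acgt(seq)
    vec = np.zeros(256, dtype=float)
    for i in range(len(seq) - 3):
        vec[_TETRA_INDEX[seq[i : i + 4]]] += 1
    return vec / vec.sum()
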