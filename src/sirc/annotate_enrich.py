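"""Annotation overlap, shuffle-null positional enrichment, and motif scans.

The enrichment statistic follows the convention score = log10(observed /
expected), where *observed* is the number of query intervals overlapping a
category by >= 1 bp and *expected* is the mean of the same count over
random re-placements of the query intervals (lengths and chromosome
preserved, placements uniform and non-overlapping).  Empirical p-values use
the add-one shuffle estimator and are Benjamini-Hochberg adjusted across
categories.

Cis-regulatory element (CRE) scanning matches IUPAC degenerate consensus
strings on both strands and assigns each (cassette, motif) pair a binomial
tail p-value for its match count given the per-position match probability
under a background base composition, again BH-adjusted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .seqcore import AnnotationInterval, Interval, SircRecord
from .structure import revcomp

__all__ = [
    "EnrichmentResult",
    "CreMotif",
    "overlap_counts",
    "positional_enrichment",
    "scan_cres",
    "read_motifs",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class CreMotif:
    id: str
    consensus: str
    description: str = ""

    def __post_init__(self) -> None:
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(
                f"motif {self.id}: invalid IUPAC code(s) {sorted(bad)}"
            )

    @property
    def revcomp(self) -> str:
        return self.consensus.upper().translate(_IUPAC_COMP)[::-1]


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    observed: int
    expected: float
    score: float | None   # log10(observed/expected); None when expected == 0
    p: float
    q: float


def _category_tree(annotations: Iterable[AnnotationInterval]
                   ) -> tuple[dict[str, IntervalTree], list[str]]:
    trees: dict[str, IntervalTree] = {}
    categories: set[str] = set()
    for ann in annotations:
        categories.add(ann.category)
        trees.setdefault(ann.interval.chrom, IntervalTree()).addi(
            ann.interval.start, ann.interval.end, ann.category
        )
    return trees, sorted(categories)


def _count(trees: dict[str, IntervalTree], categories: list[str],
           intervals: Iterable[tuple[str, int, int]]) -> dict[str, int]:
    counts = dict.fromkeys(categories, 0)
    for chrom, start, end in intervals:
        tree = trees.get(chrom)
        if tree is None:
            continue
        hit_cats = {iv.data for iv in tree.overlap(start, end)}
        for cat in hit_cats:
            counts[cat] += 1
    return counts


def overlap_counts(query: Sequence[Interval],
                   annotations: Iterable[AnnotationInterval]) -> dict[str, int]:
    """Per-category count of query intervals overlapping >= 1 bp; a query
    interval touching n categories contributes 1 to each."""
    trees, categories = _category_tree(annotations)
    return _count(trees, categories,
                  ((q.chrom, q.start, q.end) for q in query))


def _shuffle_intervals(query: Sequence[Interval],
                       universe: Mapping[str, int],
                       rng: np.random.Generator) -> list[tuple[str, int, int]]:
    """Uniform random re-placement, lengths and chromosome preserved,
    placements pairwise non-overlapping (self-overlaps re-drawn)."""
    placed: dict[str, list[tuple[int, int]]] = {}
    out = []
    for iv in sorted(query, key=lambda v: (v.chrom, -len(v))):
        chrom_len = universe[iv.chrom]
        length = len(iv)
        if length > chrom_len:
            raise ValueError(f"interval longer than chromosome {iv.chrom}")
        taken = placed.setdefault(iv.chrom, [])
        for _ in range(1000):
            start = int(rng.integers(0, chrom_len - length + 1))
            end = start + length
            if all(e <= start or end <= s for s, e in taken):
                taken.append((start, end))
                out.append((iv.chrom, start, end))
                break
        else:
            raise RuntimeError("could not place shuffled interval")
    return out


def positional_enrichment(query: Sequence[Interval],
                          annotations: Iterable[AnnotationInterval],
                          universe: Mapping[str, int],
                          n_shuffles: int = 1000,
                          seed: int | np.random.Generator = 0
                          ) -> list[EnrichmentResult]:
    """Shuffle-null positional enrichment of query intervals per category."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    for iv in query:
        if iv.chrom not in universe or iv.end > universe[iv.chrom]:
            raise ValueError(f"query interval {iv} outside universe")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    trees, categories = _category_tree(annotations)
    observed = _count(trees, categories,
                      ((q.chrom, q.start, q.end) for q in query))
    null = {cat: np.empty(n_shuffles) for cat in categories}
    for i in range(n_shuffles):
        counts = _count(trees, categories,
                        _shuffle_intervals(query, universe, rng))
        for cat in categories:
            null[cat][i] = counts[cat]
    pvals = []
    results = []
    for cat in categories:
        obs = observed[cat]
        exp = float(null[cat].mean())
        if exp > 0 and obs > 0:
            score: float | None = math.log10(obs / exp)
        elif exp > 0:
            score = float("-inf")
        else:
            score = None
        if obs >= exp:
            p = (1 + int((null[cat] >= obs).sum())) / (1 + n_shuffles)
        else:
            p = (1 + int((null[cat] <= obs).sum())) / (1 + n_shuffles)
        pvals.append(p)
        results.append((cat, obs, exp, score, p))
    qvals = stats.false_discovery_control(pvals) if pvals else []
    return [
        EnrichmentResult(cat, obs, exp, score, p, float(q))
        for (cat, obs, exp, score, p), q in zip(results, qvals)
    ]


# ---------------------------------------------------------------------------
# CRE scanning
# ---------------------------------------------------------------------------

def _motif_regex(consensus: str) -> re.Pattern:
    # lookahead so overlapping matches are counted
    body = "".join(
        ch if len(IUPAC[ch]) == 1 else f"[{IUPAC[ch]}]"
        for ch in consensus.upper()
    )
    return re.compile(f"(?=({body}))")


def _match_prob(consensus: str, bg: Mapping[str, float]) -> float:
    p = 1.0
    for ch in consensus.upper():
        p *= sum(bg[b] for b in IUPAC[ch])
    return p


def count_motif_matches(seq: str, motif: CreMotif) -> int:
    """Occurrences of the degenerate pattern on both strands (a palindromic
    motif is counted once per site)."""
    fwd = len(_motif_regex(motif.consensus).findall(seq))
    if motif.revcomp == motif.consensus.upper():
        return fwd
    return fwd + len(_motif_regex(motif.revcomp).findall(seq))


def scan_cres(cassettes: Sequence[SircRecord], motifs: Sequence[CreMotif],
              genome, background: Mapping[str, float] | None = None,
              q_max: float = 0.01,
              degenerate_max_prob: float = 0.05) -> pd.DataFrame:
    """Scan cassette sequences for CRE motifs; returns one row per
    (cassette, motif) pair with >= 1 match, with binomial p and BH q values
    and a ``significant`` flag (q < q_max).

    Motifs whose per-position match probability under the background reaches
    ``degenerate_max_prob`` are flagged degenerate and excluded from testing.
    """
    from .copynumber import _as_dict

    gd = _as_dict(genome)
    seqs = {c.sirc_id: c.sequence(gd) for c in cassettes}
    if background is None:
        allseq = "".join(seqs.values())
        total = max(1, len(allseq))
        background = {b: allseq.count(b) / total for b in "ACGT"}
    rows = []
    pvals = []
    for motif in motifs:
        p_fwd = _match_prob(motif.consensus, background)
        p_rev = _match_prob(motif.revcomp, background)
        if max(p_fwd, p_rev) >= degenerate_max_prob:
            continue  # degenerate motif: matches saturate, not testable
        m = len(motif.consensus)
        palindromic = motif.revcomp == motif.consensus.upper()
        for cid, seq in seqs.items():
            npos = len(seq) - m + 1
            if npos <= 0:
                continue
            obs = count_motif_matches(seq, motif)
            if palindromic:
                n_trials, p_hit = npos, p_fwd
            else:
                n_trials, p_hit = 2 * npos, (p_fwd + p_rev) / 2
            p = float(stats.binom.sf(obs - 1, n_trials, p_hit)) if obs else 1.0
            rows.append(
                {"sirc_id": cid, "motif_id": motif.id,
                 "consensus": motif.consensus, "n_matches": obs, "p": p}
            )
            pvals.append(p)
    df = pd.DataFrame(
        rows, columns=["sirc_id", "motif_id", "consensus", "n_matches", "p"]
    )
    if len(df):
        df["q"] = stats.false_discovery_control(np.array(pvals))
        df["significant"] = df["q"] < q_max
        df = df[df["n_matches"] > 0].reset_index(drop=True)
    else:
        df["q"] = []
        df["significant"] = []
    return df


def read_motifs(path: str | Path) -> list[CreMotif]:
    """Motif TSV: columns id, consensus, description (header optional)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if cols[0].lower() in ("id", "motif_id"):
            continue
        desc = cols[2] if len(cols) > 2 else ""
        out.append(CreMotif(cols[0], cols[1].upper(), desc))
    return out
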