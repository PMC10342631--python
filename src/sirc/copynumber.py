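"""Genome-wide exact and k-mismatch occurrence counting.

Exact counting (``count_exact``) slides the query over every chromosome,
counting possibly overlapping matches on the forward strand and, by
default, matches of the reverse complement (minus-strand occurrences).

Approximate search (``find_with_mismatches``) finds every position whose
Hamming distance to the query is <= k — substitutions only, no indels,
which models repeat copies "altered by up to k mismatches".  The production
path partitions the query into k+1 exact seed blocks (pigeonhole: any hit
with <= k mismatches contains at least one exact block), locates blocks by
string search and verifies candidates with a vectorized Hamming count; the
contract is exact equivalence with a sliding-Hamming scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .seqcore import AnnotationInterval, GenomeSequence, Interval, SircRecord
from .structure import revcomp

__all__ = [
    "Hit",
    "HitList",
    "count_exact",
    "find_with_mismatches",
    "hidden_copies",
    "dr_census",
    "hits_to_bed",
]


@dataclass(frozen=True)
class Hit:
    interval: Interval
    mismatches: int
    strand: str


@dataclass
class HitList:
    query_id: str
    hits: list[Hit]

    def __len__(self) -> int:
        return len(self.hits)


def _as_dict(genome) -> dict[str, str]:
    if isinstance(genome, str):
        return {"seq": genome}
    if isinstance(genome, GenomeSequence):
        return {genome.name: genome.seq}
    if isinstance(genome, Mapping):
        return dict(genome)
    return {g.name: g.seq for g in genome}


def _find_all(s: str, pattern: str) -> list[int]:
    out = []
    i = s.find(pattern)
    while i != -1:
        out.append(i)
        i = s.find(pattern, i + 1)
    return out


def count_exact(genome, query: str, both_strands: bool = True) -> int:
    """Number of (possibly overlapping) exact occurrences of ``query``;
    minus-strand occurrences (reverse-complement matches) included when
    ``both_strands``."""
    if not query:
        raise ValueError("empty query")
    total = 0
    rc = revcomp(query)
    for seq in _as_dict(genome).values():
        total += len(_find_all(seq, query))
        if both_strands and rc != query:
            total += len(_find_all(seq, rc))
    return total


def _hamming_hits(seq: str, arr: np.ndarray, query: str, k: int) -> list[tuple[int, int]]:
    """Pigeonhole-seeded k-mismatch positions of ``query`` in one sequence."""
    m = len(query)
    n = len(seq)
    if n < m:
        return []
    qarr = np.frombuffer(query.encode(), dtype=np.uint8)
    nblocks = k + 1
    base, extra = divmod(m, nblocks)
    starts = []
    off = 0
    for b in range(nblocks):
        bl = base + (1 if b < extra else 0)
        starts.append((off, bl))
        off += bl
    cand: set[int] = set()
    for off, bl in starts:
        block = query[off : off + bl]
        for p in _find_all(seq, block):
            s0 = p - off
            if 0 <= s0 <= n - m:
                cand.add(s0)
    out = []
    for s0 in sorted(cand):
        mm = int(np.count_nonzero(arr[s0 : s0 + m] != qarr))
        if mm <= k:
            out.append((s0, mm))
    return out


def find_with_mismatches(genome, query: str, k: int = 5,
                         both_strands: bool = True,
                         query_id: str = "query") -> HitList:
    """All positions with Hamming distance <= k to the query (length
    preserved; substitutions only)."""
    if k >= len(query):
        raise ValueError("k must be smaller than the query length")
    hits: list[Hit] = []
    rc = revcomp(query)
    for chrom, seq in _as_dict(genome).items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for pos, mm in _hamming_hits(seq, arr, query, k):
            hits.append(Hit(Interval(chrom, pos, pos + len(query)), mm, "+"))
        if both_strands and rc != query:
            for pos, mm in _hamming_hits(seq, arr, rc, k):
                hits.append(Hit(Interval(chrom, pos, pos + len(query)), mm, "-"))
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.strand))
    return HitList(query_id, hits)


def hidden_copies(genome, cassette: SircRecord, k: int = 5) -> int:
    """Count full-cassette occurrences within <= k substitutions elsewhere in
    the genome (hits overlapping the cassette's own locus are excluded)."""
    gd = _as_dict(genome)
    seq = cassette.sequence(gd)
    hl = find_with_mismatches(gd, seq, k=k, query_id=cassette.sirc_id)
    return sum(
        1 for h in hl.hits if not h.interval.overlaps(cassette.interval)
    )


def dr_census(genome, dr_consensuses: Mapping[str, str] | Sequence[tuple[str, str]],
              annotations: Iterable[AnnotationInterval],
              both_strands: bool = True) -> pd.DataFrame:
    """Exact occurrences of each DR consensus intersected with each
    annotation category: one row per (dr_id, category) with the number of
    occurrences overlapping >= 1 bp of that category."""
    if not isinstance(dr_consensuses, Mapping):
        dr_consensuses = dict(dr_consensuses)
    gd = _as_dict(genome)
    trees: dict[tuple[str, str], IntervalTree] = {}
    categories: set[str] = set()
    for ann in annotations:
        categories.add(ann.category)
        key = (ann.interval.chrom, ann.category)
        trees.setdefault(key, IntervalTree()).addi(
            ann.interval.start, ann.interval.end
        )
    rows = []
    for dr_id, dr_seq in dr_consensuses.items():
        occ: list[tuple[str, int, int]] = []
        rc = revcomp(dr_seq)
        for chrom, seq in gd.items():
            for p in _find_all(seq, dr_seq):
                occ.append((chrom, p, p + len(dr_seq)))
            if both_strands and rc != dr_seq:
                for p in _find_all(seq, rc):
                    occ.append((chrom, p, p + len(dr_seq)))
        for cat in sorted(categories):
            count = sum(
                1
                for chrom, s0, e0 in occ
                if (chrom, cat) in trees and trees[(chrom, cat)].overlap(s0, e0)
            )
            rows.append({"dr_id": dr_id, "category": cat, "count": count})
    return pd.DataFrame(rows, columns=["dr_id", "category", "count"])


def hits_to_bed(hitlist: HitList, path) -> None:
    """One BED line per hit; the score column carries the mismatch count."""
    with open(path, "w") as fh:
        for h in hitlist.hits:
            iv = h.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{hitlist.query_id}"
                f"\t{h.mismatches}\t{h.strand}\n"
            )
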