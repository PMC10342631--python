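"""Maximal exact direct-repeat discovery and cassette assembly.

The detector works window-by-window over a chromosome:

1. :func:`find_maximal_repeats` enumerates *maximal repeated pairs* — two
   non-overlapping occurrences of the same substring that cannot be extended
   by one base on either side without breaking the equality (the classic
   vmatch-style maximal repeat, restricted to non-overlapping occurrence
   pairs, which excludes self-overlapping tandem-style matches).
2. :func:`assemble_cassettes` chains occurrences of each seed's repeat unit
   into candidate cassettes: 2-8 equal-length units whose gaps (spacers)
   fall inside configurable bounds relative to the unit length.  Flanking
   degenerate units are admitted by re-matching against the running
   consensus within a Hamming-distance budget.

Coordinates in returned seeds and candidates are absolute (window offsets
applied).  Windows containing ``N`` must be pre-split by the caller; the
genome-level driver :func:`scan_genome` does this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .seqcore import GenomeSequence, Interval, SircRecord

__all__ = [
    "ScanParams",
    "RepeatSeed",
    "CandidateCassette",
    "find_maximal_repeats",
    "assemble_cassettes",
    "build_consensus",
    "scan_genome",
]


@dataclass(frozen=True)
class ScanParams:
    """Detector bounds, mirroring the observed cassette geometry:
    repeat units of 10-29 bp, 2-8 units per cassette, spacers between half
    and three unit lengths."""

    min_dr_len: int = 10
    max_dr_len: int = 29
    min_units: int = 2
    max_units: int = 8
    min_spacer: float = 0.5   # fraction of DR length
    max_spacer: float = 3.0   # fraction of DR length
    max_unit_mismatch_frac: float = 0.2
    window: int = 10_000

    def __post_init__(self) -> None:
        if self.min_dr_len > self.max_dr_len:
            raise ValueError("min_dr_len must be <= max_dr_len")
        if self.min_units < 2:
            raise ValueError("min_units must be >= 2")
        if not (0 <= self.max_unit_mismatch_frac < 0.5):
            raise ValueError("max_unit_mismatch_frac must be in [0, 0.5)")

    @property
    def max_span(self) -> int:
        """Largest possible cassette footprint; used as window overlap."""
        return self.max_units * self.max_dr_len + int(
            (self.max_units - 1) * self.max_spacer * self.max_dr_len
        )


@dataclass(frozen=True, order=True)
class RepeatSeed:
    """A maximal repeated pair: genome[pos_a:pos_a+length] ==
    genome[pos_b:pos_b+length], occurrences non-overlapping."""

    chrom: str
    pos_a: int
    pos_b: int
    length: int


@dataclass
class CandidateCassette(SircRecord):
    """A cassette before filtration; consensus is provisional."""

    consensus_ties: tuple[int, ...] = ()
    truncated: bool = False


def find_maximal_repeats(window: str | GenomeSequence,
                         params: ScanParams | None = None,
                         chrom: str = "",
                         offset: int = 0) -> list[RepeatSeed]:
    """Enumerate maximal repeated pairs of length >= ``min_dr_len``.

    A pair (i, j, L), i + L <= j, is reported iff the two occurrences are
    equal, left-maximal (i == 0 or s[i-1] != s[j-1]) and right-maximal
    (j + L == n or s[i+L] != s[j+L]).  Results are sorted by position.
    """
    if params is None:
        params = ScanParams()
    if isinstance(window, GenomeSequence):
        chrom = chrom or window.name
        s = window.seq
    else:
        s = window
    n = len(s)
    k = params.min_dr_len
    if n < 2 * k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(s[i : i + k], []).append(i)

    out: list[RepeatSeed] = []
    seen: set[tuple[int, int]] = set()
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions) - 1):
            i = positions[ai]
            for bi in range(ai + 1, len(positions)):
                j = positions[bi]
                # only the leftmost k-mer of a matching run is left-maximal;
                # this both enforces maximality and deduplicates diagonals
                if i > 0 and s[i - 1] == s[j - 1]:
                    continue
                length = k
                while j + length < n and s[i + length] == s[j + length]:
                    length += 1
                if j >= i + length and (i, j) not in seen:
                    seen.add((i, j))
                    out.append(RepeatSeed(chrom, i + offset, j + offset, length))
    out.sort()
    return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_consensus(units: list[str]) -> tuple[str, tuple[int, ...]]:
    """Per-column majority consensus of equal-length unit sequences.

    Ties are broken by fixed base order A < C < G < T; tied column indices
    are returned alongside the consensus so records can flag them.
    """
    if len(units) < 2:
        raise ValueError("need at least 2 units")
    length = len(units[0])
    if any(len(u) != length for u in units):
        raise ValueError("units must have equal length")
    cons = []
    ties = []
    for col in range(length):
        counts: dict[str, int] = {}
        for u in units:
            counts[u[col]] = counts.get(u[col], 0) + 1
        best = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == best)
        if len(winners) > 1:
            ties.append(col)
        cons.append(winners[0])
    return "".join(cons), tuple(ties)


def _exact_occurrences(s: str, pattern: str) -> list[int]:
    out = []
    i = s.find(pattern)
    while i != -1:
        out.append(i)
        i = s.find(pattern, i + 1)
    return out


def _chain_positions(positions: list[int], length: int,
                     params: ScanParams) -> list[list[int]]:
    """Split sorted occurrence positions into runs whose inter-unit gaps lie
    within the spacer bounds."""
    lo = params.min_spacer * length
    hi = params.max_spacer * length
    chains: list[list[int]] = []
    cur = [positions[0]]
    for p in positions[1:]:
        gap = p - (cur[-1] + length)
        if lo <= gap <= hi:
            cur.append(p)
        else:
            if len(cur) >= params.min_units:
                chains.append(cur)
            cur = [p]
    if len(cur) >= params.min_units:
        chains.append(cur)
    return chains


def _extend_chain(s: str, chain: list[int], length: int,
                  params: ScanParams) -> list[int]:
    """Admit degenerate flanking units by consensus re-matching."""
    budget = int(params.max_unit_mismatch_frac * length)
    if budget == 0:
        return chain
    lo = max(1, math.ceil(params.min_spacer * length))
    hi = math.floor(params.max_spacer * length)
    n = len(s)
    chain = list(chain)
    changed = True
    while changed and len(chain) < params.max_units:
        changed = False
        cons, _ = build_consensus([s[p : p + length] for p in chain])
        # leftward
        best = None
        for gap in range(lo, hi + 1):
            p = chain[0] - gap - length
            if p < 0:
                break
            mm = _hamming(s[p : p + length], cons)
            if mm <= budget and (best is None or mm < best[0]):
                best = (mm, p)
        if best is not None:
            chain.insert(0, best[1])
            changed = True
            continue
        # rightward
        best = None
        for gap in range(lo, hi + 1):
            p = chain[-1] + length + gap
            if p + length > n:
                break
            mm = _hamming(s[p : p + length], cons)
            if mm <= budget and (best is None or mm < best[0]):
                best = (mm, p)
        if best is not None:
            chain.append(best[1])
            changed = True
    return chain


def assemble_cassettes(seeds: list[RepeatSeed],
                       window: str | GenomeSequence,
                       params: ScanParams | None = None,
                       chrom: str = "",
                       offset: int = 0) -> list[CandidateCassette]:
    """Chain seed-unit occurrences into candidate cassettes.

    For every distinct seed repeat-unit sequence within the detector length
    bounds, all exact occurrences in the window are chained under the spacer
    bounds; chains are then extended with mismatch-tolerant flanking units
    and capped at ``max_units`` (capped chains are flagged ``truncated``).
    Overlapping candidates are resolved in favour of more units, then a
    longer span.
    """
    if params is None:
        params = ScanParams()
    if isinstance(window, GenomeSequence):
        chrom = chrom or window.name
        s = window.seq
    else:
        s = window
    if not seeds:
        return []
    chrom = chrom or seeds[0].chrom

    unit_seqs: set[str] = set()
    for seed in seeds:
        if params.min_dr_len <= seed.length <= params.max_dr_len:
            unit_seqs.add(s[seed.pos_a - offset : seed.pos_a - offset + seed.length])

    raw: list[CandidateCassette] = []
    for u in sorted(unit_seqs, key=lambda x: (len(x), x)):
        length = len(u)
        positions = _exact_occurrences(s, u)
        if len(positions) < 2:
            continue
        for chain in _chain_positions(positions, length, params):
            chain = _extend_chain(s, chain, length, params)
            truncated = len(chain) > params.max_units
            if truncated:
                chain = chain[: params.max_units]
            units = [
                Interval(chrom, p + offset, p + offset + length) for p in chain
            ]
            spacers = [
                Interval(chrom, a.end, b.start)
                for a, b in zip(units, units[1:])
            ]
            cons, ties = build_consensus([s[p : p + length] for p in chain])
            raw.append(
                CandidateCassette(
                    interval=Interval(chrom, units[0].start, units[-1].end),
                    units=units,
                    spacers=spacers,
                    dr_consensus=cons,
                    consensus_ties=ties,
                    truncated=truncated,
                )
            )
    return _dedupe(raw)


def _dedupe(cands: list[CandidateCassette]) -> list[CandidateCassette]:
    """Drop span-identical duplicates, then resolve overlapping candidates:
    keep the one with more units, then the longer span, then leftmost."""
    bykey: dict[tuple, CandidateCassette] = {}
    for c in cands:
        key = (c.interval.chrom, c.interval.start, c.interval.end, c.n_units)
        if key not in bykey:
            bykey[key] = c
    ranked = sorted(
        bykey.values(),
        key=lambda c: (-c.n_units, -(len(c.interval)), c.interval.start,
                       len(c.dr_consensus)),
    )
    kept: list[CandidateCassette] = []
    for c in ranked:
        if not any(c.interval.overlaps(k.interval) for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return kept


def _segments_without_n(seq: str) -> list[tuple[int, str]]:
    segs = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "N":
            if start is not None:
                segs.append((start, seq[start:i]))
                start = None
        elif start is None:
            start = i
    if start is not None:
        segs.append((start, seq[start:]))
    return segs


def scan_genome(genome: list[GenomeSequence],
                params: ScanParams | None = None,
                progress: "callable | None" = None) -> list[CandidateCassette]:
    """Windowed genome-wide scan.  Windows overlap by the maximal cassette
    span so no cassette straddles undetected; duplicates from overlap zones
    are removed by span."""
    if params is None:
        params = ScanParams()
    overlap = params.max_span
    step = max(params.window - overlap, params.window // 2)
    out: list[CandidateCassette] = []
    for gs in genome:
        for seg_off, seg in _segments_without_n(gs.seq):
            pos = 0
            while pos < len(seg):
                chunk = seg[pos : pos + params.window]
                if len(chunk) >= 2 * params.min_dr_len:
                    off = seg_off + pos
                    seeds = find_maximal_repeats(chunk, params, gs.name, off)
                    out.extend(
                        assemble_cassettes(seeds, chunk, params, gs.name, off)
                    )
                if progress is not None:
                    progress(gs.name, pos)
                if pos + params.window >= len(seg):
                    break
                pos += step
    return _dedupe(out)
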