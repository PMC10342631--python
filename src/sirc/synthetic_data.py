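"""Synthetic genomes with ground-truth cassettes, decoys and hidden copies.

The generator emits a background genome of i.i.d. bases at a configurable
GC fraction with non-overlapping implants:

* **cassettes** — 2-8 copies of a repeat unit (10-29 bp) separated by
  mutually dissimilar spacers.  Every cassette is rejection-sampled until it
  passes the default filter cascade (complexity, GC, merged-spacer rules,
  tandem screen) and until a scan of the implant recovers exactly its
  planted unit coordinates, so detection tests have exact ground truth.
* **decoys** — each class is engineered to fail exactly one designated
  filter rule while passing the rules designated to the other classes:
  tandem decoys (a unit, a lightly mutated unit as spacer, a unit — a
  near-perfect three-copy tandem whose lone spacer is nonetheless a complex
  sequence), low-complexity decoys (trinucleotide-repeat units → DUST),
  GC decoys (AT-only units that are otherwise complex → GC rule), and
  high-copy decoys (a two-unit cassette whose single spacer is scattered
  across the genome beyond the copy-number cutoff).
* **MGE-like elements** — identical multi-copy elements each carrying one
  sequence identical to a cassette's repeat unit, for copy-number census
  tests.
* **hidden copies** — full-cassette copies carrying a fixed number of
  substitutions, positioned inside repeat units so the copy is no longer
  detectable as a cassette (verified by scanning), as a mutated "hidden"
  repeat copy should be.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import complexity
from .filter_pipeline import FilterConfig
from .repeat_scan import ScanParams, assemble_cassettes, find_maximal_repeats
from .seqcore import GenomeSequence, Interval
from .structure import detect_tandem

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_genome",
    "mutate_sequence",
    "truth_to_frame",
]

_BASES = "ACGT"
_MIN_SEPARATION = 100   # bp between implants; beyond any spacer bound
_MARGIN = 30            # bp of context used when verifying implants


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 1_000_000
    chrom_name: str = "chr1"
    gc_background: float = 0.36
    n_cassettes: int = 20
    dr_len_range: tuple[int, int] = (10, 29)
    unit_count_range: tuple[int, int] = (2, 8)
    spacer_frac_range: tuple[float, float] = (0.6, 2.5)
    unit_mutation_rate: float = 0.0
    spacer_max_identity: float = 0.5
    n_tandem_decoys: int = 10
    n_lowcomplexity_decoys: int = 10
    n_gc_decoys: int = 5
    n_highcopy_decoys: int = 5
    n_mge_like: int = 3
    mge_copies: int = 5
    n_hidden_copies: int = 0      # per cassette (round-robin over cassettes)
    hidden_copy_subs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cassettes", "n_tandem_decoys", "n_lowcomplexity_decoys",
                     "n_gc_decoys", "n_highcopy_decoys", "n_mge_like",
                     "n_hidden_copies"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TruthRecord:
    implant_id: str
    kind: str               # cassette | tandem_decoy | lowcomplexity_decoy |
                            # gc_decoy | highcopy_decoy | spacer_fill |
                            # mge_like | hidden_copy
    interval: Interval
    parent_id: str = ""
    dr_length: int = 0
    n_units: int = 0
    mutation_count: int = 0
    designated_rule: str = ""
    unit_starts: tuple[int, ...] = ()
    dr_sequence: str = ""


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    at = (1 - gc) / 2
    p = [at, gc / 2, gc / 2, at]
    return "".join(rng.choice(list(_BASES), size=n, p=p))


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[int(rng.integers(0, 3))]


def mutate_sequence(seq: str, n_subs: int,
                    seed: int | np.random.Generator = 0,
                    positions: Sequence[int] | None = None) -> str:
    """Substitute exactly ``n_subs`` positions (each to a different base);
    the Hamming distance to the input is exactly ``n_subs``."""
    if n_subs > len(seq):
        raise ValueError("n_subs exceeds sequence length")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if positions is None:
        positions = rng.choice(len(seq), size=n_subs, replace=False)
    elif len(positions) != n_subs:
        raise ValueError("positions length must equal n_subs")
    out = list(seq)
    for p in positions:
        out[p] = _other_base(rng, out[p])
    return "".join(out)


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / n


def _passes_dr_rules(u: str, fc: FilterConfig) -> bool:
    d = complexity.dust_score(u)
    t = complexity.trifonov_complexity(u)
    g = complexity.gc_content(u)
    return (d < fc.dust_max and t > fc.trifonov_min
            and d * len(u) < fc.dust_times_len_max
            and t / len(u) > fc.trifonov_over_len_min
            and g not in fc.gc_exclude)


def _spacer_rules_ok(spacers: Sequence[str], fc: FilterConfig) -> bool:
    merged = "".join(spacers)
    if len(merged) < 2:
        return False
    t = complexity.trifonov_complexity(merged)
    return (t > fc.spacer_trifonov_min
            and t / len(spacers) > fc.spacer_trifonov_over_count_min)


def _scan_implant(seq: str, rng: np.random.Generator, gc: float,
                  params: ScanParams, left_forbid: str, right_forbid: str):
    """Scan an implant with background margins; returns candidate list."""
    left = _rand_seq(rng, _MARGIN, gc)
    right = _rand_seq(rng, _MARGIN, gc)
    if left_forbid and left[-1] == left_forbid:
        left = left[:-1] + _other_base(rng, left_forbid)
    if right_forbid and right[0] == right_forbid:
        right = _other_base(rng, right_forbid) + right[1:]
    window = left + seq + right
    seeds = find_maximal_repeats(window, params, "w", 0)
    return assemble_cassettes(seeds, window, params, "w", 0), _MARGIN


@dataclass
class _Implant:
    seq: str
    kind: str
    meta: dict = field(default_factory=dict)
    left_forbid: str = ""
    right_forbid: str = ""


# ---------------------------------------------------------------------------
# implant builders
# ---------------------------------------------------------------------------

def _draw_spacers(rng: np.random.Generator, cfg: SimConfig, length: int,
                  n_spacers: int, frac_range: tuple[float, float],
                  fc: FilterConfig) -> list[str] | None:
    lo = max(math.ceil(frac_range[0] * length), 1)
    hi = max(math.floor(frac_range[1] * length), lo)
    for _ in range(200):
        spacers = []
        for i in range(n_spacers):
            slen = int(rng.integers(lo, hi + 1))
            s = _rand_seq(rng, slen, cfg.gc_background)
            # fixed boundary bases so the chars flanking consecutive units
            # always differ -> exact-repeat seeds equal the planted unit
            first = _BASES[i % 4]
            last = _BASES[(i + 2) % 4]
            s = first + s[1:-1] + last
            spacers.append(s)
        ok = all(
            _identity(a, b) < cfg.spacer_max_identity
            for i, a in enumerate(spacers)
            for b in spacers[i + 1 :]
        )
        if ok and _spacer_rules_ok(spacers, fc):
            return spacers
    return None


def _assemble(unit_seqs: list[str], spacers: list[str]) -> tuple[str, list[int]]:
    parts = []
    starts = []
    pos = 0
    for i, u in enumerate(unit_seqs):
        starts.append(pos)
        parts.append(u)
        pos += len(u)
        if i < len(spacers):
            parts.append(spacers[i])
            pos += len(spacers[i])
    return "".join(parts), starts


def _unit_only_at_starts(seq: str, u: str, starts: list[int]) -> bool:
    found = []
    i = seq.find(u)
    while i != -1:
        found.append(i)
        i = seq.find(u, i + 1)
    return found == starts


def _build_cassette(rng: np.random.Generator, cfg: SimConfig,
                    fc: FilterConfig, params: ScanParams,
                    n_units: int | None = None,
                    dr_len: int | None = None,
                    verify_scan: bool = True) -> _Implant:
    for _ in range(500):
        length = dr_len or int(rng.integers(cfg.dr_len_range[0],
                                            cfg.dr_len_range[1] + 1))
        n = n_units or int(rng.integers(cfg.unit_count_range[0],
                                        cfg.unit_count_range[1] + 1))
        u = _rand_seq(rng, length, cfg.gc_background)
        if not _passes_dr_rules(u, fc):
            continue
        spacers = _draw_spacers(rng, cfg, length, n - 1,
                                cfg.spacer_frac_range, fc)
        if spacers is None:
            continue
        units = [u] * n
        if cfg.unit_mutation_rate > 0:
            units = [
                mutate_sequence(
                    u,
                    int(rng.binomial(length, cfg.unit_mutation_rate)),
                    rng,
                )
                for _ in range(n)
            ]
        seq, starts = _assemble(units, spacers)
        if cfg.unit_mutation_rate == 0 and not _unit_only_at_starts(seq, u, starts):
            continue
        if detect_tandem(seq).is_tandem:
            continue
        left_forbid = spacers[0][-1]
        right_forbid = spacers[-1][0]
        if verify_scan and cfg.unit_mutation_rate == 0:
            cands, margin = _scan_implant(seq, rng, cfg.gc_background, params,
                                          left_forbid, right_forbid)
            expected = [s + margin for s in starts]
            if len(cands) != 1 or [iv.start for iv in cands[0].units] != expected:
                continue
        return _Implant(
            seq, "cassette",
            {"dr_length": length, "n_units": n, "unit_starts": starts,
             "dr_sequence": u, "spacers": spacers},
            left_forbid, right_forbid,
        )
    raise RuntimeError("could not generate a conforming cassette")


def _build_tandem_decoy(rng: np.random.Generator, cfg: SimConfig,
                        fc: FilterConfig, params: ScanParams) -> _Implant:
    for _ in range(500):
        length = int(rng.integers(14, 25))
        u = _rand_seq(rng, length, cfg.gc_background)
        if not _passes_dr_rules(u, fc):
            continue
        # substitutions every 10th base fragment shared runs below the
        # detector's minimum repeat length, so the spacer never seeds
        positions = list(range(9, length - 1, 10))
        s = mutate_sequence(u, len(positions), rng, positions)
        # spacer IS the lightly mutated middle copy: a 3-copy tandem whose
        # lone spacer is nonetheless a complex sequence
        seq = u + s + u
        starts = [0, 2 * length]
        if not _unit_only_at_starts(seq, u, starts):
            continue
        if not _spacer_rules_ok([s], fc):
            continue
        if not detect_tandem(seq).is_tandem:
            continue
        cands, margin = _scan_implant(seq, rng, cfg.gc_background, params,
                                      s[-1], s[0])
        expected = [m + margin for m in starts]
        if len(cands) != 1 or [iv.start for iv in cands[0].units] != expected:
            continue
        return _Implant(
            seq, "tandem_decoy",
            {"dr_length": length, "n_units": 2, "unit_starts": starts,
             "dr_sequence": u, "designated_rule": "tandem"},
            s[-1], s[0],
        )
    raise RuntimeError("could not generate a tandem decoy")


def _build_lowcomplexity_decoy(rng: np.random.Generator, cfg: SimConfig,
                               fc: FilterConfig, params: ScanParams) -> _Implant:
    length = 12
    for _ in range(500):
        t = _rand_seq(rng, 3, 0.5)
        gc = complexity.gc_content(t)
        if gc in (0.0, 100.0) or len(set(t)) == 1:
            continue
        u = (t * 5)[:length]
        if complexity.dust_score(u) < fc.dust_max:
            continue
        n = 3
        spacers = _draw_spacers(rng, cfg, length, n - 1, (1.2, 2.0), fc)
        if spacers is None:
            continue
        seq, starts = _assemble([u] * n, spacers)
        if not _unit_only_at_starts(seq, u, starts):
            continue
        if detect_tandem(seq).is_tandem:
            continue
        cands, margin = _scan_implant(seq, rng, cfg.gc_background, params,
                                      spacers[0][-1], spacers[-1][0])
        if not any(
            c.dr_consensus == u
            and [iv.start for iv in c.units] == [s + margin for s in starts]
            for c in cands
        ):
            continue
        return _Implant(
            seq, "lowcomplexity_decoy",
            {"dr_length": length, "n_units": n, "unit_starts": starts,
             "dr_sequence": u, "designated_rule": "dust"},
            spacers[0][-1], spacers[-1][0],
        )
    raise RuntimeError("could not generate a low-complexity decoy")


def _build_gc_decoy(rng: np.random.Generator, cfg: SimConfig,
                    fc: FilterConfig, params: ScanParams) -> _Implant:
    length = 10
    for _ in range(2000):
        u = "".join(rng.choice(["A", "T"], size=length))
        d = complexity.dust_score(u)
        t = complexity.trifonov_complexity(u)
        if not (d < fc.dust_max and t > fc.trifonov_min
                and d * length < fc.dust_times_len_max
                and t / length > fc.trifonov_over_len_min):
            continue
        n = 3
        spacers = _draw_spacers(rng, cfg, length, n - 1, (0.8, 2.0), fc)
        if spacers is None:
            continue
        seq, starts = _assemble([u] * n, spacers)
        if not _unit_only_at_starts(seq, u, starts):
            continue
        if detect_tandem(seq).is_tandem:
            continue
        cands, margin = _scan_implant(seq, rng, cfg.gc_background, params,
                                      spacers[0][-1], spacers[-1][0])
        if not any(
            c.dr_consensus == u
            and [iv.start for iv in c.units] == [s + margin for s in starts]
            for c in cands
        ):
            continue
        return _Implant(
            seq, "gc_decoy",
            {"dr_length": length, "n_units": n, "unit_starts": starts,
             "dr_sequence": u, "designated_rule": "gc"},
            spacers[0][-1], spacers[-1][0],
        )
    raise RuntimeError("could not generate a GC decoy")


def _build_highcopy_decoy(rng: np.random.Generator, cfg: SimConfig,
                          fc: FilterConfig, params: ScanParams
                          ) -> tuple[_Implant, str]:
    """A well-formed two-unit cassette whose lone spacer will be scattered
    beyond the copy-number cutoff; the spacer is shorter than the minimum
    repeat length so its scattered copies never seed the detector."""
    length = 14
    spacer_len = 9
    for _ in range(500):
        u = _rand_seq(rng, length, cfg.gc_background)
        if not _passes_dr_rules(u, fc):
            continue
        s = _rand_seq(rng, spacer_len, cfg.gc_background)
        if not _spacer_rules_ok([s], fc):
            continue
        seq, starts = _assemble([u, u], [s])
        if not _unit_only_at_starts(seq, u, starts):
            continue
        if detect_tandem(seq).is_tandem:
            continue
        cands, margin = _scan_implant(seq, rng, cfg.gc_background, params,
                                      s[-1], s[0])
        expected = [p + margin for p in starts]
        if len(cands) != 1 or [iv.start for iv in cands[0].units] != expected:
            continue
        imp = _Implant(
            seq, "highcopy_decoy",
            {"dr_length": length, "n_units": 2, "unit_starts": starts,
             "dr_sequence": u, "designated_rule": "spacer_copy"},
            s[-1], s[0],
        )
        return imp, s
    raise RuntimeError("could not generate a high-copy decoy")


def _build_mge_element(rng: np.random.Generator, cfg: SimConfig,
                       params: ScanParams, dr: str) -> str:
    """A random element carrying one exact copy of a cassette repeat unit;
    re-drawn until the element itself assembles into no candidate."""
    for _ in range(200):
        elem_len = int(rng.integers(200, 301))
        pos = int(rng.integers(40, elem_len - 40 - len(dr)))
        body = _rand_seq(rng, elem_len, cfg.gc_background)
        elem = body[:pos] + dr + body[pos + len(dr) :]
        if elem.count(dr) != 1:
            continue
        cands, _ = _scan_implant(elem, rng, cfg.gc_background, params, "", "")
        if cands:
            continue
        return elem
    raise RuntimeError("could not generate an MGE-like element")


def _hidden_copy_positions(rng: np.random.Generator, unit_starts: list[int],
                           dr_len: int, total_len: int,
                           n_subs: int) -> list[int]:
    """Place substitutions inside repeat units so that every pair of units
    shares no exact run of detectable length: greedily cut the longest
    shared run over all unit pairs."""
    cuts: dict[int, set[int]] = {i: set() for i in range(len(unit_starts))}
    positions: list[int] = []
    for _ in range(n_subs):
        best = None   # (run_len, unit_idx, cut_offset)
        for i in range(len(unit_starts)):
            for j in range(i + 1, len(unit_starts)):
                pair_cuts = sorted(cuts[i] | cuts[j])
                prev = -1
                for c in pair_cuts + [dr_len]:
                    run = c - prev - 1
                    if best is None or run > best[0]:
                        best = (run, j, prev + 1 + run // 2)
                    prev = c
        if best is None or best[0] < 1:
            # no pairs left to cut; spend remaining subs randomly in units
            unit = int(rng.integers(0, len(unit_starts)))
            off = int(rng.integers(0, dr_len))
            best = (0, unit, off)
        _, unit, off = best
        off = min(max(off, 0), dr_len - 1)
        if off in cuts[unit]:
            off = int(rng.integers(0, dr_len))
        cuts[unit].add(off)
        positions.append(unit_starts[unit] + off)
    # de-duplicate while keeping count
    uniq = sorted(set(positions))
    while len(uniq) < n_subs:
        p = int(rng.integers(0, total_len))
        if p not in uniq:
            uniq.append(p)
    return sorted(uniq[:n_subs])


def _build_hidden_copy(rng: np.random.Generator, cfg: SimConfig,
                       params: ScanParams, parent: _Implant,
                       parent_id: str) -> _Implant:
    meta = parent.meta
    for _ in range(100):
        positions = _hidden_copy_positions(
            rng, meta["unit_starts"], meta["dr_length"], len(parent.seq),
            cfg.hidden_copy_subs,
        )
        mutated = mutate_sequence(parent.seq, cfg.hidden_copy_subs, rng,
                                  positions)
        cands, _ = _scan_implant(mutated, rng, cfg.gc_background, params,
                                 "", "")
        if cands:
            continue
        return _Implant(
            mutated, "hidden_copy",
            {"parent_id": parent_id, "mutation_count": cfg.hidden_copy_subs,
             "dr_length": meta["dr_length"], "n_units": meta["n_units"]},
        )
    raise RuntimeError(
        "could not generate an undetectable hidden copy; "
        "parent has too many units for the substitution budget"
    )


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

_VERIFIED_KINDS = ("cassette", "tandem_decoy", "lowcomplexity_decoy",
                   "gc_decoy", "highcopy_decoy")


def _placement_clean(genome: str, truth: list[TruthRecord],
                     params: ScanParams, check_cassette_units: bool) -> bool:
    """Check, against the real genomic background, that every implant is
    recovered as exactly its planted unit structure: a chance repeat in the
    flanking background can otherwise extend or distort a candidate."""
    pad = params.max_span // 2 + params.max_dr_len
    for t in truth:
        if t.kind not in _VERIFIED_KINDS:
            continue
        if t.kind == "cassette" and not check_cassette_units:
            continue
        ws = max(0, t.interval.start - pad)
        we = min(len(genome), t.interval.end + pad)
        window = genome[ws:we]
        seeds = find_maximal_repeats(window, params, t.interval.chrom, ws)
        cands = assemble_cassettes(seeds, window, params, t.interval.chrom, ws)
        overlapping = [c for c in cands if c.interval.overlaps(t.interval)]
        if len(overlapping) != 1:
            return False
        if tuple(u.start for u in overlapping[0].units) != t.unit_starts:
            return False
    return True


def simulate_genome(config: SimConfig | None = None,
                    filter_config: FilterConfig | None = None,
                    scan_params: ScanParams | None = None
                    ) -> tuple[list[GenomeSequence], list[TruthRecord]]:
    """Build the synthetic genome and its ground-truth table."""
    cfg = config or SimConfig()
    fc = filter_config or FilterConfig()
    params = scan_params or ScanParams()
    rng = np.random.default_rng(cfg.seed)
    for _ in range(30):
        genome, truth = _simulate_once(cfg, fc, params, rng)
        if _placement_clean(genome[0].seq, truth, params,
                            cfg.unit_mutation_rate == 0):
            return genome, truth
    raise RuntimeError("could not place implants on a clean background")


def _simulate_once(cfg: SimConfig, fc: FilterConfig, params: ScanParams,
                   rng: np.random.Generator
                   ) -> tuple[list[GenomeSequence], list[TruthRecord]]:
    implants: list[_Implant] = []
    counters: dict[str, int] = {}

    def _next_id(kind: str) -> str:
        counters[kind] = counters.get(kind, 0) + 1
        return f"{kind}_{counters[kind]}"

    cassettes: list[tuple[str, _Implant]] = []
    for _ in range(cfg.n_cassettes):
        imp = _build_cassette(rng, cfg, fc, params)
        imp.meta["implant_id"] = _next_id("cassette")
        cassettes.append((imp.meta["implant_id"], imp))
        implants.append(imp)
    for _ in range(cfg.n_tandem_decoys):
        imp = _build_tandem_decoy(rng, cfg, fc, params)
        imp.meta["implant_id"] = _next_id("tandem_decoy")
        implants.append(imp)
    for _ in range(cfg.n_lowcomplexity_decoys):
        imp = _build_lowcomplexity_decoy(rng, cfg, fc, params)
        imp.meta["implant_id"] = _next_id("lowcomplexity_decoy")
        implants.append(imp)
    for _ in range(cfg.n_gc_decoys):
        imp = _build_gc_decoy(rng, cfg, fc, params)
        imp.meta["implant_id"] = _next_id("gc_decoy")
        implants.append(imp)
    for _ in range(cfg.n_highcopy_decoys):
        imp, spacer = _build_highcopy_decoy(rng, cfg, fc, params)
        imp.meta["implant_id"] = _next_id("highcopy_decoy")
        implants.append(imp)
        for _ in range(fc.spacer_copy_max + 10):
            fill = _Implant(spacer, "spacer_fill",
                            {"parent_id": imp.meta["implant_id"]})
            fill.meta["implant_id"] = _next_id("spacer_fill")
            implants.append(fill)
    for _ in range(cfg.n_mge_like):
        if not cassettes:
            break
        parent_id, parent = cassettes[int(rng.integers(0, len(cassettes)))]
        elem = _build_mge_element(rng, cfg, params, parent.meta["dr_sequence"])
        for _ in range(cfg.mge_copies):
            imp = _Implant(elem, "mge_like", {"parent_id": parent_id})
            imp.meta["implant_id"] = _next_id("mge_like")
            implants.append(imp)
    if cfg.n_hidden_copies > 0:
        for parent_id, parent in cassettes:
            for _ in range(cfg.n_hidden_copies):
                imp = _build_hidden_copy(rng, cfg, params, parent, parent_id)
                imp.meta["implant_id"] = _next_id("hidden_copy")
                implants.append(imp)

    # ---- placement -------------------------------------------------------
    order = rng.permutation(len(implants))
    implants = [implants[i] for i in order]
    total = sum(len(i.seq) for i in implants)
    n_gaps = len(implants) + 1
    fixed = total + n_gaps * _MIN_SEPARATION
    extra = cfg.genome_length - fixed
    if extra < 0:
        raise ValueError(
            f"infeasible packing: implants need {fixed} bp, genome is "
            f"{cfg.genome_length} bp"
        )
    extras = rng.multinomial(extra, [1 / n_gaps] * n_gaps) if extra else [0] * n_gaps

    parts: list[str] = []
    truth: list[TruthRecord] = []
    pos = 0
    for idx, imp in enumerate(implants):
        gap_len = _MIN_SEPARATION + int(extras[idx])
        gap = _rand_seq(rng, gap_len, cfg.gc_background)
        if imp.left_forbid and gap[-1] == imp.left_forbid:
            gap = gap[:-1] + _other_base(rng, imp.left_forbid)
        prev = implants[idx - 1] if idx else None
        if prev is not None and prev.right_forbid and gap[0] == prev.right_forbid:
            gap = _other_base(rng, prev.right_forbid) + gap[1:]
        parts.append(gap)
        pos += gap_len
        start = pos
        parts.append(imp.seq)
        pos += len(imp.seq)
        meta = imp.meta
        truth.append(
            TruthRecord(
                implant_id=meta.get("implant_id", f"{imp.kind}_{idx}"),
                kind=imp.kind,
                interval=Interval(cfg.chrom_name, start, pos),
                parent_id=meta.get("parent_id", ""),
                dr_length=meta.get("dr_length", 0),
                n_units=meta.get("n_units", 0),
                mutation_count=meta.get("mutation_count", 0),
                designated_rule=meta.get("designated_rule", ""),
                unit_starts=tuple(start + s for s in meta.get("unit_starts", ())),
                dr_sequence=meta.get("dr_sequence", ""),
            )
        )
    tail_len = _MIN_SEPARATION + int(extras[-1])
    tail = _rand_seq(rng, tail_len, cfg.gc_background)
    last = implants[-1] if implants else None
    if last is not None and last.right_forbid and tail[0] == last.right_forbid:
        tail = _other_base(rng, last.right_forbid) + tail[1:]
    parts.append(tail)
    genome = "".join(parts)
    assert len(genome) == cfg.genome_length
    truth.sort(key=lambda t: t.interval.start)
    return [GenomeSequence(cfg.chrom_name, genome)], truth


def truth_to_frame(truth: Iterable[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truth:
        rows.append(
            {"implant_id": t.implant_id, "kind": t.kind,
             "chrom": t.interval.chrom, "start": t.interval.start,
             "end": t.interval.end, "parent_id": t.parent_id,
             "dr_length": t.dr_length, "n_units": t.n_units,
             "mutation_count": t.mutation_count,
             "designated_rule": t.designated_rule,
             "unit_starts": ",".join(map(str, t.unit_starts)),
             "dr_sequence": t.dr_sequence}
        )
    return pd.DataFrame(rows)
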