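import numpy as np
import pytest

from sirc.repeat_scan import (CandidateCassette, RepeatSeed, ScanParams,
                              assemble_cassettes, build_consensus,
                              find_maximal_repeats, scan_genome)
from sirc.seqcore import GenomeSequence


def brute_force_maximal_pairs(s, min_len):
    """All-pairs enumeration of maximal non-overlapping repeated pairs."""
    n = len(s)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            if i > 0 and s[i - 1] == s[j - 1]:
                continue  # not left-maximal
            length = 0
            while j + length < n and s[i + length] == s[j + length]:
                length += 1
            if length >= min_len and j >= i + length:
                out.add((i, j, length))
    return out


class TestFindMaximalRepeats:
    def test_single_planted_pair(self):
        seeds = find_maximal_repeats("ACGTTTACGT", ScanParams(min_dr_len=4))
        assert [(s.pos_a, s.pos_b, s.length) for s in seeds] == [(0, 6, 4)]

    def test_no_repeats_in_unique_sequence(self, rng):
        # random 50-mer re-drawn until it has no repeated 10-mer
        while True:
            s = "".join(rng.choice(list("ACGT"), size=50))
            kmers = [s[i : i + 10] for i in range(41)]
            if len(set(kmers)) == len(kmers):
                break
        assert find_maximal_repeats(s, ScanParams(min_dr_len=10)) == []

    def test_translation_invariance(self, rng):
        core = "ACGTTTACGTAC"
        params = ScanParams(min_dr_len=4)
        base = find_maximal_repeats(core, params)
        shifted = find_maximal_repeats(core, params, offset=37)
        assert [(s.pos_a + 37, s.pos_b + 37, s.length) for s in base] == [
            (s.pos_a, s.pos_b, s.length) for s in shifted
        ]

    def test_window_shorter_than_two_units(self):
        assert find_maximal_repeats("ACGTACGTACG", ScanParams(min_dr_len=6)) == []

    @pytest.mark.parametrize("min_len", [3, 5])
    def test_matches_brute_force_on_random_windows(self, min_len):
        rng = np.random.default_rng(min_len)
        params = ScanParams(min_dr_len=min_len)
        for _ in range(60):
            s = "".join(rng.choice(list("ACGT"), size=80))
            got = {
                (x.pos_a, x.pos_b, x.length)
                for x in find_maximal_repeats(s, params)
            }
            assert got == brute_force_maximal_pairs(s, min_len)

    def test_seed_invariants(self, small_sim):
        g = small_sim["genome"][0]
        seeds = find_maximal_repeats(g.seq[:10_000], ScanParams(), g.name)
        for s in seeds:
            assert s.pos_b >= s.pos_a + s.length
            assert (g.seq[s.pos_a : s.pos_a + s.length]
                    == g.seq[s.pos_b : s.pos_b + s.length])

    def test_determinism(self):
        rng = np.random.default_rng(9)
        s = "".join(rng.choice(list("ACGT"), size=300))
        params = ScanParams(min_dr_len=4)
        assert find_maximal_repeats(s, params) == find_maximal_repeats(s, params)


class TestAssembleCassettes:
    def _plant(self, rng, unit_len=15, n_units=3, gap=20):
        # spacer boundary bases are forced to differ between consecutive
        # units so chance matches never extend the maximal repeat past the
        # planted unit
        unit = "".join(rng.choice(list("ACGT"), size=unit_len))
        parts = []
        for i in range(n_units):
            parts.append(unit)
            if i < n_units - 1:
                s = "".join(rng.choice(list("ACGT"), size=gap))
                parts.append("ACG"[i % 3] + s[1:-1] + "TGC"[i % 3])
        core = "".join(parts)
        pad = "".join(rng.choice(list("ACGT"), size=29)) + "A"
        pad2 = "T" + "".join(rng.choice(list("ACGT"), size=29))
        return pad + core + pad2, unit, [
            30 + i * (unit_len + gap) for i in range(n_units)
        ]

    def test_three_planted_units_one_cassette(self, rng):
        window, unit, starts = self._plant(rng)
        seeds = find_maximal_repeats(window, ScanParams())
        cands = assemble_cassettes(seeds, window, ScanParams())
        with_units = [c for c in cands
                      if [u.start for u in c.units] == starts]
        assert len(with_units) == 1
        c = with_units[0]
        assert c.n_units == 3 and len(c.spacers) == 2
        assert c.dr_consensus == unit

    def test_gap_beyond_spacer_bound_not_chained(self, rng):
        unit = "".join(rng.choice(list("ACGT"), size=15))
        gap = "".join(rng.choice(list("ACGT"), size=200))  # > 3 x 15
        window = unit + gap + unit
        seeds = find_maximal_repeats(window, ScanParams())
        assert assemble_cassettes(seeds, window, ScanParams()) == []

    def test_unit_count_capped_and_flagged(self, rng):
        unit = "".join(rng.choice(list("ACGT"), size=12))
        parts = []
        for i in range(9):
            parts.append(unit)
            if i < 8:
                s = "".join(rng.choice(list("ACGT"), size=10))
                parts.append("ACG"[i % 3] + s[1:-1] + "TGC"[i % 3])
        window = "".join(parts)
        seeds = find_maximal_repeats(window, ScanParams())
        cands = assemble_cassettes(seeds, window, ScanParams())
        assert all(c.n_units <= 8 for c in cands)
        assert any(c.truncated for c in cands)

    def test_empty_input(self):
        assert assemble_cassettes([], "ACGT" * 30, ScanParams()) == []

    def test_degenerate_flank_admitted_by_consensus_rematch(self, rng):
        unit = "".join(rng.choice(list("ACGT"), size=20))
        mutated = list(unit)
        mutated[7] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[7]]
        mutated = "".join(mutated)
        s1 = "".join(rng.choice(list("ACGT"), size=15))
        s2 = "".join(rng.choice(list("ACGT"), size=15))
        window = ("".join(rng.choice(list("ACGT"), size=25))
                  + mutated + s1 + unit + s2 + unit
                  + "".join(rng.choice(list("ACGT"), size=25)))
        seeds = find_maximal_repeats(window, ScanParams())
        cands = assemble_cassettes(seeds, window, ScanParams())
        best = max(cands, key=lambda c: c.n_units)
        assert best.n_units == 3
        assert best.units[0].start == 25


class TestBuildConsensus:
    def test_column_majority(self):
        assert build_consensus(["ACGT", "ACGA", "ACGT"])[0] == "ACGT"

    def test_identity(self):
        cons, ties = build_consensus(["ACGT", "ACGT"])
        assert cons == "ACGT" and ties == ()

    def test_tie_broken_by_base_order_and_flagged(self):
        cons, ties = build_consensus(["AC", "AG"])
        assert cons == "AC" and ties == (1,)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_consensus(["ACG", "ACGT"])


class TestScanGenome:
    def test_recovers_all_planted_cassettes(self, small_sim):
        truth = [t for t in small_sim["truth"] if t.kind == "cassette"]
        cands = small_sim["candidates"]
        for t in truth:
            assert any(
                tuple(u.start for u in c.units) == t.unit_starts
                for c in cands
            ), f"missed {t.implant_id}"

    def test_determinism_byte_identical(self, small_sim):
        again = scan_genome(small_sim["genome"])
        assert again == small_sim["candidates"]

    def test_n_regions_skipped(self):
        g = GenomeSequence("c", "ACGT" * 10 + "N" * 50 + "ACGT" * 10)
        assert scan_genome([g], ScanParams(min_dr_len=10)) == []

    def test_candidate_structure_valid(self, small_sim):
        for c in small_sim["candidates"]:
            assert 2 <= c.n_units <= 8
            assert len(c.spacers) == c.n_units - 1
            lens = {len(u) for u in c.units}
            assert lens == {len(c.dr_consensus)}
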