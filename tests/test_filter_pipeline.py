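import dataclasses

import pytest

from sirc.filter_pipeline import (FilterConfig, filter_cassettes,
                                  reports_to_frame, summarize_cohort)
from sirc.repeat_scan import CandidateCassette
from sirc.seqcore import GenomeSequence, Interval

NON_BINDING = FilterConfig(
    dust_max=float("inf"),
    trifonov_min=-1.0,
    dust_times_len_max=float("inf"),
    trifonov_over_len_min=-1.0,
    gc_exclude=(-1.0, 101.0),
    spacer_trifonov_min=-1.0,
    spacer_trifonov_over_count_min=-1.0,
    spacer_copy_max=10 ** 9,
    tandem_screen=False,
)


def make_candidate(genome_seq, unit_starts, unit_len, chrom="c"):
    units = [Interval(chrom, s, s + unit_len) for s in unit_starts]
    spacers = [Interval(chrom, a.end, b.start) for a, b in zip(units, units[1:])]
    cons = genome_seq[unit_starts[0] : unit_starts[0] + unit_len]
    return CandidateCassette(
        interval=Interval(chrom, units[0].start, units[-1].end),
        units=units, spacers=spacers, dr_consensus=cons,
    )


class TestCascade:
    def test_homopolymer_consensus_fails_dust_first(self, rng):
        bg = "".join(rng.choice(list("ACGT"), size=200))
        seq = "A" * 12 + bg[:20] + "A" * 12
        cand = make_candidate(seq, [0, 32], 12)
        accepted, (report,) = filter_cassettes([cand], {"c": seq})
        assert accepted == []
        assert report.first_failure() == "dust"

    def test_zero_gc_consensus_fails_gc_rule(self, rng):
        # AT-only unit built to pass the complexity rules, so the GC rule is
        # the first to fail
        unit = "AAATATTTAA"
        bg = "".join(rng.choice(list("ACGT"), size=40))
        seq = unit + bg[:15] + unit
        cand = make_candidate(seq, [0, 25], 10)
        accepted, (report,) = filter_cassettes([cand], {"c": seq})
        assert accepted == []
        assert report.first_failure() == "gc"
        assert report.rule("dust").passed

    def test_ground_truth_cohort(self, small_sim):
        """All simulator cassettes accepted, all decoys rejected, and every
        decoy fails its designated rule while passing the rules designated
        to the other decoy classes."""
        truth = small_sim["truth"]
        accepted = small_sim["accepted"]
        cands = small_sim["candidates"]
        reports = small_sim["reports"]
        for t in truth:
            if t.kind != "cassette":
                continue
            assert any(
                tuple(u.start for u in a.units) == t.unit_starts
                for a in accepted
            ), f"cassette {t.implant_id} rejected"
        designated = {"tandem_decoy": "tandem", "lowcomplexity_decoy": "dust",
                      "gc_decoy": "gc", "highcopy_decoy": "spacer_copy"}
        all_rules = set(designated.values())
        for t in truth:
            if t.kind not in designated:
                continue
            assert not any(
                a.interval.overlaps(t.interval) for a in accepted
            ), f"decoy {t.implant_id} accepted"
            matching = [
                r for r, c in zip(reports, cands)
                if c.interval.overlaps(t.interval)
            ]
            assert matching, f"decoy {t.implant_id} never reached the filter"
            rule = designated[t.kind]
            for rep in matching:
                assert not rep.rule(rule).passed
                for other in all_rules - {rule}:
                    assert rep.rule(other).passed, (t.kind, other)

    def test_non_binding_thresholds_accept_everything(self, small_sim):
        accepted, reports = filter_cassettes(
            small_sim["candidates"], small_sim["genome"], NON_BINDING
        )
        assert len(accepted) == len(small_sim["candidates"])
        assert all(r.verdict for r in reports)

    def test_report_completeness(self, small_sim):
        reports = small_sim["reports"]
        cands = small_sim["candidates"]
        assert len(reports) == len(cands)
        n_pass = sum(r.verdict for r in reports)
        assert n_pass == len(small_sim["accepted"])
        # all nine rules measured for every candidate, even failing ones
        assert all(len(r.rules) == 9 for r in reports)
        frame = reports_to_frame(reports)
        assert len(frame) == len(cands)

    @pytest.mark.parametrize(
        "field,values,direction",
        [
            ("dust_max", [1.0, 0.5, 0.33, 0.1, 0.0], "tighten-desc"),
            ("trifonov_min", [0.0, 0.1, 0.3, 0.6, 0.9], "tighten-asc"),
            ("dust_times_len_max", [50.0, 11.0, 2.0, 0.0], "tighten-desc"),
            ("trifonov_over_len_min", [0.0, 0.0028, 0.02, 0.05], "tighten-asc"),
            ("spacer_trifonov_min", [0.0, 0.15, 0.5, 0.9], "tighten-asc"),
            ("spacer_trifonov_over_count_min", [0.0, 0.07, 0.3, 0.9],
             "tighten-asc"),
            ("spacer_copy_max", [10 ** 6, 100, 10, 1], "tighten-desc"),
        ],
    )
    def test_threshold_monotonicity(self, small_sim, field, values, direction):
        counts = []
        for v in values:
            config = dataclasses.replace(FilterConfig(), **{field: v})
            accepted, _ = filter_cassettes(
                small_sim["candidates"], small_sim["genome"], config
            )
            counts.append(len(accepted))
        assert counts == sorted(counts, reverse=True)


class TestSummarizeCohort:
    def test_single_cassette_arithmetic(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=1_000_000))
        unit = seq[100:115]
        cand = make_candidate(seq, [100, 140, 180], 15)
        accepted, _ = filter_cassettes([cand], {"c": seq}, NON_BINDING)
        stats = summarize_cohort(accepted, {"c": seq})
        assert stats["total_bp"] == 95
        assert stats["genome_fraction_percent"] == pytest.approx(0.0095)
        assert stats["dr_length_mode"] == 15

    def test_mode_matches_planted_lengths(self, small_sim):
        truth_lengths = [
            t.dr_length for t in small_sim["truth"] if t.kind == "cassette"
        ]
        # restrict to records matching planted cassettes
        planted = {
            t.unit_starts for t in small_sim["truth"] if t.kind == "cassette"
        }
        recs = [
            a for a in small_sim["accepted"]
            if tuple(u.start for u in a.units) in planted
        ]
        stats = summarize_cohort(recs, small_sim["genome"])
        assert sorted(stats["dr_length_hist"]) == sorted(set(truth_lengths))

    def test_per_mbp_median_matches_independent_binning(self, small_sim):
        import numpy as np

        stats = summarize_cohort(small_sim["accepted"], small_sim["genome"])
        starts = [a.interval.start for a in small_sim["accepted"]]
        length = len(small_sim["gd"]["chr1"])
        nbins = (length + 999_999) // 1_000_000
        counts = [0] * nbins
        for s in starts:
            counts[s // 1_000_000] += 1
        assert stats["per_chromosome"]["chr1"]["counts_per_mbp"] == counts
        assert stats["per_chromosome"]["chr1"]["median_per_mbp"] == float(
            np.median(counts)
        )

    def test_empty_cohort_warns(self, small_sim):
        with pytest.warns(UserWarning):
            assert summarize_cohort([], small_sim["genome"]) == {}
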