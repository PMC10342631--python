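"""The filtration cascade turning candidate cassettes into accepted records.

Nine rules are evaluated, in this fixed order, for every candidate (all of
them are always measured so the report is complete even after an early
failure):

1.  ``dust``                       DUST(consensus) < 0.33
2.  ``trifonov``                   Trifonov(consensus) > 0.1
3.  ``dust_x_len``                 DUST x |consensus| < 11
4.  ``trifonov_over_len``          Trifonov / |consensus| > 0.0028
5.  ``gc``                         GC(consensus) not 0 and not 100 %
6.  ``spacer_trifonov``            Trifonov(merged spacers) > 0.15
7.  ``spacer_trifonov_over_count`` Trifonov(merged spacers)/n_spacers > 0.07
8.  ``spacer_copy``                min spacer genome copy number < 100
9.  ``tandem``                     full-cassette tandem screen negative

"Merged spacers" is the plain concatenation of the spacer sequences in
genomic order.  Inequalities are strict exactly as written: a boundary value
fails.  A candidate is accepted iff every rule passes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import complexity, copynumber, structure
from .seqcore import SircRecord
from .repeat_scan import CandidateCassette

__all__ = [
    "FilterConfig",
    "RuleResult",
    "FilterReport",
    "filter_cassettes",
    "summarize_cohort",
    "reports_to_frame",
]


@dataclass(frozen=True)
class FilterConfig:
    dust_max: float = 0.33
    trifonov_min: float = 0.1
    dust_times_len_max: float = 11.0
    trifonov_over_len_min: float = 0.0028
    gc_exclude: tuple[float, float] = (0.0, 100.0)
    spacer_trifonov_min: float = 0.15
    spacer_trifonov_over_count_min: float = 0.07
    spacer_copy_max: int = 100
    tandem_screen: bool = True
    # tandem screen knobs (native period-scan)
    tandem_min_period: int = 2
    tandem_min_identity: float = 0.8
    tandem_min_cover: float = 0.5


@dataclass(frozen=True)
class RuleResult:
    name: str
    value: float
    threshold: float
    passed: bool


@dataclass
class FilterReport:
    candidate_id: str
    rules: list[RuleResult]
    verdict: bool

    def first_failure(self) -> str | None:
        for r in self.rules:
            if not r.passed:
                return r.name
        return None

    def rule(self, name: str) -> RuleResult:
        for r in self.rules:
            if r.name == name:
                return r
        raise KeyError(name)


def _evaluate(candidate: CandidateCassette, gd: dict[str, str],
              config: FilterConfig) -> FilterReport:
    cons = candidate.dr_consensus
    length = len(cons)
    dust = complexity.dust_score(cons)
    trif = complexity.trifonov_complexity(cons)
    gc = complexity.gc_content(cons)
    merged = "".join(candidate.spacer_sequences(gd))
    sp_trif = complexity.trifonov_complexity(merged) if len(merged) >= 2 else 0.0
    n_spacers = len(candidate.spacers)
    spacer_copies = [
        copynumber.count_exact(gd, s) for s in candidate.spacer_sequences(gd)
    ]
    min_copies = min(spacer_copies) if spacer_copies else 0
    if config.tandem_screen:
        tandem = structure.detect_tandem(
            candidate.sequence(gd),
            min_period=config.tandem_min_period,
            min_identity=config.tandem_min_identity,
            min_cover=config.tandem_min_cover,
        )
        tandem_val = 1.0 if tandem.is_tandem else 0.0
    else:
        tandem_val = 0.0
    rules = [
        RuleResult("dust", dust, config.dust_max, dust < config.dust_max),
        RuleResult("trifonov", trif, config.trifonov_min,
                   trif > config.trifonov_min),
        RuleResult("dust_x_len", dust * length, config.dust_times_len_max,
                   dust * length < config.dust_times_len_max),
        RuleResult("trifonov_over_len", trif / length,
                   config.trifonov_over_len_min,
                   trif / length > config.trifonov_over_len_min),
        RuleResult("gc", gc, float("nan"), gc not in config.gc_exclude),
        RuleResult("spacer_trifonov", sp_trif, config.spacer_trifonov_min,
                   sp_trif > config.spacer_trifonov_min),
        RuleResult("spacer_trifonov_over_count", sp_trif / n_spacers,
                   config.spacer_trifonov_over_count_min,
                   sp_trif / n_spacers > config.spacer_trifonov_over_count_min),
        RuleResult("spacer_copy", float(min_copies), config.spacer_copy_max,
                   min_copies < config.spacer_copy_max),
        RuleResult("tandem", tandem_val, 0.0, tandem_val == 0.0),
    ]
    return FilterReport(candidate.sirc_id, rules, all(r.passed for r in rules))


def filter_cassettes(candidates: Sequence[CandidateCassette], genome,
                     config: FilterConfig | None = None
                     ) -> tuple[list[SircRecord], list[FilterReport]]:
    """Apply the cascade; returns accepted records (with derived features
    attached) and one report per candidate, in input order."""
    if config is None:
        config = FilterConfig()
    gd = copynumber._as_dict(genome)
    accepted: list[SircRecord] = []
    reports: list[FilterReport] = []
    for cand in candidates:
        report = _evaluate(cand, gd, config)
        reports.append(report)
        if not report.verdict:
            continue
        pal = structure.find_palindrome(cand.dr_consensus)
        features = {
            "gc_percent": round(report.rule("gc").value, 3),
            "dust": round(report.rule("dust").value, 5),
            "trifonov": round(report.rule("trifonov").value, 5),
            "spacer_trifonov": round(report.rule("spacer_trifonov").value, 5),
            "min_spacer_copies": int(report.rule("spacer_copy").value),
            "palindrome_arm": pal.max_arm,
            "palindrome_class": pal.arm_class,
            "dr_copies": copynumber.count_exact(gd, cand.dr_consensus),
        }
        accepted.append(
            SircRecord(
                interval=cand.interval,
                units=list(cand.units),
                spacers=list(cand.spacers),
                dr_consensus=cand.dr_consensus,
                features=features,
                sirc_id=cand.sirc_id,
            )
        )
    return accepted, reports


def reports_to_frame(reports: Sequence[FilterReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        row: dict[str, object] = {
            "candidate_id": rep.candidate_id,
            "verdict": "pass" if rep.verdict else "fail",
            "first_failure": rep.first_failure() or "",
        }
        for r in rep.rules:
            row[f"{r.name}_value"] = r.value
            row[f"{r.name}_pass"] = r.passed
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort(accepted: Sequence[SircRecord], genome) -> dict:
    """Cohort statistics: DR-length histogram and mode, GC distribution,
    total cassette bp and genome fraction, per-chromosome counts per 1-Mbp
    bin with their median, palindrome class counts."""
    gd = copynumber._as_dict(genome)
    genome_size = sum(len(s) for s in gd.values())
    if not accepted:
        import warnings

        warnings.warn("empty cohort: nothing to summarize")
        return {}
    dr_lengths = [len(r.dr_consensus) for r in accepted]
    hist = Counter(dr_lengths)
    mode = max(hist.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    gcs = [float(r.features.get("gc_percent", float("nan"))) for r in accepted]
    total_bp = sum(len(r.interval) for r in accepted)
    per_chrom: dict[str, dict] = {}
    for chrom, seq in gd.items():
        nbins = max(1, -(-len(seq) // 1_000_000))
        counts = [0] * nbins
        for r in accepted:
            if r.interval.chrom == chrom:
                counts[r.interval.start // 1_000_000] += 1
        per_chrom[chrom] = {
            "counts_per_mbp": counts,
            "median_per_mbp": float(np.median(counts)),
        }
    pal_classes = Counter(
        str(r.features.get("palindrome_class", "unknown")) for r in accepted
    )
    return {
        "n_cassettes": len(accepted),
        "dr_length_hist": dict(sorted(hist.items())),
        "dr_length_mode": mode,
        "gc_mean": float(np.mean(gcs)),
        "gc_median": float(np.median(gcs)),
        "total_bp": total_bp,
        "genome_fraction_percent": 100.0 * total_bp / genome_size,
        "per_chromosome": per_chrom,
        "palindrome_classes": dict(pal_classes),
    }
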