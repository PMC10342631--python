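"""Workflow orchestration: simulate -> detect -> filter -> characterize.

``PipelineConfig`` bundles every stage's parameters and round-trips through
a single YAML file, so one config plus one seed reproduces a whole run
byte-for-byte.  The stage functions here are the programmatic interface; the
``sirc`` command-line tool in :mod:`sirc.cli` is a thin wrapper over them.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import annotate_enrich, copynumber, filter_pipeline, repeat_scan, seqcore
from .filter_pipeline import FilterConfig
from .repeat_scan import CandidateCassette, ScanParams
from .seqcore import AnnotationInterval, GenomeSequence, SircRecord
from .synthetic_data import SimConfig, simulate_genome, truth_to_frame

logger = logging.getLogger("sirc")

__all__ = [
    "PipelineConfig",
    "run_simulate",
    "run_detect",
    "run_filter",
    "run_characterize",
]


@dataclass
class PipelineConfig:
    scan: ScanParams = field(default_factory=ScanParams)
    filter: FilterConfig = field(default_factory=FilterConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    enrichment_shuffles: int = 1000
    cre_q_max: float = 0.01
    hidden_copy_mismatches: int = 5
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "scan": dataclasses.asdict(self.scan),
            "filter": dataclasses.asdict(self.filter),
            "sim": dataclasses.asdict(self.sim),
            "enrichment_shuffles": self.enrichment_shuffles,
            "cre_q_max": self.cre_q_max,
            "hidden_copy_mismatches": self.hidden_copy_mismatches,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        try:
            kwargs = {}
            if "scan" in doc:
                kwargs["scan"] = ScanParams(**doc["scan"])
            if "filter" in doc:
                fd = dict(doc["filter"])
                if "gc_exclude" in fd:
                    fd["gc_exclude"] = tuple(fd["gc_exclude"])
                kwargs["filter"] = FilterConfig(**fd)
            if "sim" in doc:
                sd = dict(doc["sim"])
                for key in ("dr_len_range", "unit_count_range",
                            "spacer_frac_range"):
                    if key in sd:
                        sd[key] = tuple(sd[key])
                kwargs["sim"] = SimConfig(**sd)
            for key in ("enrichment_shuffles", "cre_q_max",
                        "hidden_copy_mismatches", "seed"):
                if key in doc:
                    kwargs[key] = doc[key]
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid config {path}: {exc}") from exc


def run_simulate(config: PipelineConfig, out_prefix: str | Path
                 ) -> tuple[list[GenomeSequence], "object"]:
    sim = dataclasses.replace(config.sim, seed=config.seed)
    genome, truth = simulate_genome(sim, config.filter, config.scan)
    out_prefix = Path(out_prefix)
    seqcore.write_genome(genome, out_prefix.with_suffix(".fasta"))
    truth_to_frame(truth).to_csv(
        out_prefix.with_suffix(".truth.tsv"), sep="\t", index=False
    )
    logger.info("simulated %d bp genome with %d implants",
                sum(len(g) for g in genome), len(truth))
    return genome, truth


def run_detect(genome: list[GenomeSequence],
               config: PipelineConfig) -> list[CandidateCassette]:
    def _progress(chrom: str, pos: int) -> None:
        if pos % 1_000_000 < config.scan.window:
            logger.info("scanning %s @ %d bp", chrom, pos)

    candidates = repeat_scan.scan_genome(genome, config.scan, _progress)
    logger.info("detected %d candidate cassettes", len(candidates))
    return candidates


def run_filter(candidates: Sequence[CandidateCassette],
               genome: list[GenomeSequence],
               config: PipelineConfig):
    accepted, reports = filter_pipeline.filter_cassettes(
        candidates, genome, config.filter
    )
    logger.info("filter cascade: %d of %d candidates accepted",
                len(accepted), len(candidates))
    return accepted, reports


def run_characterize(accepted: Sequence[SircRecord],
                     genome: list[GenomeSequence],
                     config: PipelineConfig,
                     annotations: Sequence[AnnotationInterval] | None = None,
                     motifs=None) -> dict:
    """Cohort summary plus, when inputs are supplied, positional enrichment,
    DR census and CRE scan tables."""
    out: dict = {
        "cohort": filter_pipeline.summarize_cohort(accepted, genome),
    }
    out["hidden_copies"] = {
        rec.sirc_id: copynumber.hidden_copies(
            genome, rec, k=config.hidden_copy_mismatches
        )
        for rec in accepted
    }
    if annotations:
        universe = {g.name: len(g) for g in genome}
        out["enrichment"] = annotate_enrich.positional_enrichment(
            [r.interval for r in accepted], annotations, universe,
            n_shuffles=config.enrichment_shuffles, seed=config.seed,
        )
        out["dr_census"] = copynumber.dr_census(
            genome,
            {r.sirc_id: r.dr_consensus for r in accepted},
            annotations,
        )
    else:
        logger.info("no annotations supplied; enrichment and census skipped")
    if motifs:
        out["cre"] = annotate_enrich.scan_cres(
            list(accepted), motifs, genome, q_max=config.cre_q_max
        )
    return out
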