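import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sirc.filter_pipeline import filter_cassettes
from sirc.repeat_scan import scan_genome
from sirc.synthetic_data import SimConfig, simulate_genome

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A 200-kbp genome with every implant kind, scanned and filtered once
    for the whole session."""
    cfg = SimConfig(
        genome_length=200_000,
        n_cassettes=6,
        n_tandem_decoys=3,
        n_lowcomplexity_decoys=3,
        n_gc_decoys=2,
        n_highcopy_decoys=2,
        n_mge_like=2,
        seed=42,
    )
    genome, truth = simulate_genome(cfg)
    candidates = scan_genome(genome)
    accepted, reports = filter_cassettes(candidates, genome)
    return {
        "config": cfg,
        "genome": genome,
        "gd": {g.name: g.seq for g in genome},
        "truth": truth,
        "candidates": candidates,
        "accepted": accepted,
        "reports": reports,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
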