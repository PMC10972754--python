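import pytest

from baitrank.pipeline import run_pipeline
from baitrank.simulate import SimConfig

#: compact study conditions for fast CLI / IO round-trip tests
SMALL_SIM = dict(
    n_scaffolds=4,
    n_genes=300,
    n_tissues=6,
    replicates_per_tissue=3,
    n_pathway_genes=8,
    n_decoy_coexpr=2,
    n_decoy_clustered=2,
    planted_cluster_sizes=(4, 4),
    n_characterized=2,
    seed=11,
)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run at the default study conditions (seed 1)."""
    outdir = tmp_path_factory.mktemp("default_run")
    return run_pipeline({"simulate": True, "seed": 1}, outdir)


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=1)


@pytest.fixture()
def small_config():
    return SimConfig(**SMALL_SIM)
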