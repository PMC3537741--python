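from __future__ import annotations

import pytest

from gliafam.pipeline import PipelineConfig, run_pipeline
from gliafam.simulate import GroupEvent, SimulationConfig, reference_profile, simulate_family


@pytest.fixture(scope="session")
def profile909():
    return reference_profile(909)


@pytest.fixture(scope="session")
def default_family():
    """One default simulated family (6 groups, 8 genomes) with its truth."""
    records, truth = simulate_family(SimulationConfig(seed=42))
    return records, truth


def small_sim_config(seed: int) -> SimulationConfig:
    """A reduced family on a 4-genome tree for fast pipeline tests."""
    f = frozenset
    tips = f("CDMS")
    return SimulationConfig(
        seed=seed,
        genome_tree="((C:0.02,M:0.02):0.012,(D:0.022,S:0.022):0.012);",
        group_model=[
            GroupEvent(tips, 1, "gain"),
            GroupEvent(f("C"), 1, "loss"),
            GroupEvent(f("M"), 1, "pseudogenisation"),
            GroupEvent(f("DS"), 2, "gain"),
            GroupEvent(tips, 6, "gain"),
        ],
        n_genes_per_group_per_genome=2,
        clone_reads_per_gene=2,
        n_outgroups=2,
    )


@pytest.fixture(scope="session")
def pipeline_result():
    """Full pipeline over the default family; shared by end-to-end tests."""
    cfg = PipelineConfig(seed=11, tree_bootstrap=300, n_bootstrap=500)
    return run_pipeline(cfg)
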