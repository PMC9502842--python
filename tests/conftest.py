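"""Shared fixtures: calibrated profile sets and one full-scale synthetic run.

The expensive objects (profile calibration, the 200-contig end-to-end
simulation) are session-scoped so the whole suite pays for them once.
"""

import pytest


@pytest.fixture(scope="session")
def group_profiles():
    from vinascan.synthetic_data import mcp_group_profiles

    return mcp_group_profiles()


@pytest.fixture(scope="session")
def fam_profiles():
    from vinascan.synthetic_data import family_profiles

    return family_profiles()


@pytest.fixture(scope="session")
def taxonomy():
    from vinascan.synthetic_data import default_taxonomy

    return default_taxonomy()


@pytest.fixture(scope="session")
def full_run():
    """End-to-end pipeline on a seeded 200-contig metagenome (divergence 0.1)."""
    from vinascan.pipeline import PipelineConfig, run
    from vinascan.synthetic_data import SimulationConfig

    cfg = PipelineConfig(
        simulation=SimulationConfig(
            seed=1,
            n_host_contigs=200,
            prophage_probability=0.6,
            divergence=0.1,
            read_count=2000,
            crispr_probability=0.5,
        )
    )
    return run(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """A tiny zero-divergence simulation for exactness checks."""
    from vinascan.synthetic_data import SimulationConfig, generate_metagenome

    cfg = SimulationConfig(
        seed=7,
        n_host_contigs=3,
        prophage_probability=1.0,
        divergence=0.0,
        free_phage_fraction=0.0,
        group_weights={"Vinavirales": 1.0},
    )
    return generate_metagenome(cfg)
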