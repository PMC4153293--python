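import pytest

from dnralink import synthetic_data as syn


@pytest.fixture(scope="session")
def small_pool():
    """Genus-structured pool whose taxa are mutually distinct at 90% identity."""
    return syn.generate_reference_pool(
        12, 3, length=80, seed=3, r_within=0.08, r_between=0.4
    )


@pytest.fixture(scope="session")
def calibration_pool():
    """Pool with tight genera for cutoff calibration."""
    return syn.generate_reference_pool(
        5, 3, length=80, seed=7, r_within=0.05, r_between=0.3
    )


@pytest.fixture(scope="session")
def small_dataset(small_pool, tmp_path_factory):
    """A 3-site, 400-reads-per-site simulated run (fast shared fixture)."""
    out = tmp_path_factory.mktemp("smallsim")
    config = syn.SimulationConfig(n_sites=3, depth_per_site=400, seed=3)
    communities = syn.generate_site_communities(small_pool, config)
    fastq = out / "reads.fastq"
    truth = out / "truth.tsv"
    syn.simulate_reads(communities, small_pool, config, fastq, truth)
    return {
        "pool": small_pool,
        "config": config,
        "communities": communities,
        "fastq": fastq,
        "truth": truth,
    }
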