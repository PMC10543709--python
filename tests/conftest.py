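import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hervantigen.search_db import assemble_database
from hervantigen.synthetic_data import (
    SimConfig,
    generate_hervs,
    generate_mutations,
    generate_proteome,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A scaled-down simulated experiment for fast unit tests."""
    return SimConfig(
        seed=11,
        n_proteins=40,
        protein_len_range=(80, 200),
        n_hervs=10,
        herv_len_range=(500, 1200),
        n_missense=30,
        n_frameshift=5,
        n_target_psms=400,
        n_true_peptides=200,
        n_herv_true_peptides=5,
        n_false_target_psms=150,
        n_decoy_psms=150,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Generated inputs plus per-sample search databases for the small config."""
    proteome = generate_proteome(small_config)
    hervs = generate_hervs(small_config)
    mutations, cds_by_gene = generate_mutations(small_config, proteome)
    dbs = {
        s: assemble_database(
            proteome, mutations, hervs, sample=s, cds_by_gene=cds_by_gene
        )
        for s in ("tumor", "normal")
    }
    return {
        "config": small_config,
        "proteome": proteome,
        "hervs": hervs,
        "mutations": mutations,
        "cds_by_gene": cds_by_gene,
        "dbs": dbs,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
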