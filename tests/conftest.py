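import pytest

from elucycle.config import SimulationConfig
from elucycle.synthetic import generate_evidence_table, generate_ground_truth, generate_rna_table


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(n_genes=120, seed=42, seq_length_median=150)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return generate_ground_truth(small_cfg)


@pytest.fixture(scope="session")
def small_evidence(small_truth, small_cfg):
    return generate_evidence_table(small_truth, small_cfg)


@pytest.fixture(scope="session")
def small_rna(small_truth, small_cfg):
    return generate_rna_table(small_truth, small_cfg)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SimulationConfig(
        n_genes=80, seed=7, noise_cv=0.0, detect_midpoint=float("-inf"),
        seq_length_median=150, contaminant_rate=0.0, decoy_rate=0.0,
        oxidation_rate=0.0, deamidation_rate=0.0, phospho_rate=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_truth(noiseless_cfg):
    return generate_ground_truth(noiseless_cfg)


@pytest.fixture(scope="session")
def noiseless_evidence(noiseless_truth, noiseless_cfg):
    return generate_evidence_table(noiseless_truth, noiseless_cfg)
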