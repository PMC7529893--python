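import pytest

from magekit import degron, synthetic


@pytest.fixture(scope="session")
def noiseless_array():
    """Zero-noise saturation substitution array of the PCF11-like degron."""
    array, truth = synthetic.gen_peptide_array(noise_cv=0.0, seed=7)
    return array, truth


@pytest.fixture(scope="session")
def pcf11_matrix(noiseless_array):
    """Affinity matrix built from the zero-noise array (closed loop)."""
    array, _ = noiseless_array
    records = synthetic.substitution_records(array)
    return degron.build_affinity_matrix(records, degron.PCF11_DEGRON, 59.0)


@pytest.fixture(scope="session")
def consensus_pattern(pcf11_matrix):
    return degron.derive_consensus(pcf11_matrix)
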