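"""Shared synthetic fixtures.

One tiny study (50 cells, depth 30, error 0.005, carrier VAF 0.5) is
generated once per session and reused by the integration-level tests.
"""

import pytest

from scesnv import synthetic


@pytest.fixture(scope="session")
def tiny_reference():
    """(reference, gene_model): 1 chromosome, 10 genes."""
    return synthetic.make_reference(1, 80_000, 10, seed=1)


@pytest.fixture(scope="session")
def tiny_truth(tiny_reference):
    reference, gene_model = tiny_reference
    return synthetic.plant_variants(
        reference, gene_model, n_cells=50, n_germline=12, n_somatic=8,
        carrier_fraction=0.05, seed=2,
    )


@pytest.fixture(scope="session")
def tiny_reads(tiny_reference, tiny_truth):
    reference, gene_model = tiny_reference
    config = synthetic.SimConfig(n_cells=50, mean_depth=30.0,
                                 error_rate=0.005, seed=3)
    return synthetic.simulate_reads(reference, gene_model, tiny_truth, config)
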