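import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def std_code():
    from opalcode import standard_code

    return standard_code()


@pytest.fixture(scope="session")
def gly_code():
    from opalcode import make_variant_code, standard_code

    return make_variant_code(standard_code(), "TGA", "G")


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted UGA->Gly dataset reused across tests."""
    from opalcode import generate_dataset

    return generate_dataset(n_genes=20, mean_gene_aa=120, n_true_peptides=200, seed=11)
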