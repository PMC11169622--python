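import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def tiny_records():
    from idrbind.records import ProteinRecord

    return [
        ProteinRecord("P1", "MKV", np.array([0, 1, 1]), np.array([0, 0, 1])),
        ProteinRecord("P2", "ACDEF", np.array([1, 1, 1, 0, 0]),
                      np.array([0, 1, 0, 0, 0])),
        ProteinRecord("N1", "GHIKL", np.array([0, 0, 1, 1, 1]),
                      np.zeros(5, dtype=int)),
    ]


@pytest.fixture(scope="session")
def small_corpus():
    """A small synthetic corpus with planted signal, shared across tests."""
    from idrbind import synthetic

    config = synthetic.SyntheticConfig(
        n_proteins=40, length_median=120, length_sigma=0.4, min_length=40,
        max_length=400, m=16, k_informative=4, effect_size=3.0, seed=11,
    )
    records = synthetic.generate_proteins(config)
    embeddings = synthetic.generate_embeddings(records, config)
    return config, records, embeddings
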