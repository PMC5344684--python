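import pytest

from reprosist import synthetic_data as sim


@pytest.fixture(scope="session")
def small_annotation():
    return sim.make_annotation(sim.SimConfig(n_genes=30, n_resistant=5, seed=3))


@pytest.fixture(scope="session")
def small_experiment():
    cfg = sim.SimConfig(n_genes=300, n_resistant=30, seed=1)
    counts, meta, truth = sim.simulate_nt_counts(cfg)
    return cfg, counts, meta, truth
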