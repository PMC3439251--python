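import numpy as np
import pytest

from stabnet import bn, pipeline, simulate


@pytest.fixture(scope="session")
def ground_truth():
    return simulate.default_ground_truth()


@pytest.fixture(scope="session")
def small_config():
    return simulate.FixtureConfig(
        n_stable=120,
        n_unstable=130,
        gpsp_counts=(30, 90, 30),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate.simulate_dataset(small_config, seed=42)


@pytest.fixture(scope="session")
def small_stability_data(small_dataset):
    ds = small_dataset
    return pipeline.StabilityData(ds.sequences, ds.annotations, ds.labels, ds.motif_windows)


@pytest.fixture()
def tiny_spec():
    """A 6-node network small enough for per-assignment oracles."""
    nodes = (
        bn.Node("a", "cpt"),
        bn.Node("b", "cpt", ("a",)),
        bn.Node("c", "noisy_or", ("a", "b")),
        bn.Node("d", "cpt", ("c",)),
        bn.Node("stability", "cpt", ("b", "c")),
        bn.Node("x", "gaussian", ("stability",)),
    )
    return bn.NetworkSpec(nodes, variant="bn")


def random_tiny_params(spec, rng):
    params = {}
    for node in spec.discrete_nodes:
        k = len(node.parents)
        if node.kind == "cpt":
            t = rng.uniform(0.05, 0.95, size=(2,) * k)
            params[node.name] = bn.CptParams(np.stack([1 - t, t], axis=-1))
        else:
            params[node.name] = bn.NoisyOrParams(
                q=rng.uniform(0.1, 0.95, size=k), c0=float(rng.uniform(0.01, 0.3))
            )
    for node in spec.continuous_nodes:
        params[node.name] = bn.GaussianTable(
            mean=rng.normal(0, 1, 2), var=rng.uniform(0.5, 2, 2)
        )
    return params
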