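import numpy as np
import pytest

from taskbrain import (
    SyntheticConnectomeSpec,
    build_embedding,
    default_module_specs,
    synthesize_connectome,
)


@pytest.fixture(scope="session")
def module_specs():
    return default_module_specs()


@pytest.fixture(scope="session")
def small_connectome(module_specs):
    """96-node synthetic connectome with nodes pinned at the module targets."""
    anchors = [s.target_talairach for s in module_specs]
    return synthesize_connectome(
        SyntheticConnectomeSpec(n_nodes=96, density=0.08, seed=7, anchor_points=anchors)
    )


@pytest.fixture()
def hybrid(small_connectome, module_specs):
    return build_embedding(
        small_connectome,
        module_specs,
        G=0.15,
        rng=np.random.default_rng(5),
        on_collision="next-nearest",
    )
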