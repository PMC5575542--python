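import numpy as np
import pytest

from paleoenrich.containers import ProteinAlignment
from paleoenrich.simulate import SimulationConfig, gen_fixture_bundle
from paleoenrich.substitution import build_model
from paleoenrich.trees import parse_newick


@pytest.fixture(scope="session")
def wag_g4():
    return build_model("WAG", alpha=1.0, K=4)


@pytest.fixture(scope="session")
def poisson():
    return build_model("Poisson", alpha=1.0, K=1)


@pytest.fixture()
def three_leaf_alignment():
    return ProteinAlignment({"t1": "AK-", "t2": "ARC", "t3": "GKC"})


@pytest.fixture()
def three_leaf_tree():
    return parse_newick("((t1:0.12,t2:0.3):0.2,t3:0.4);")


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """One deterministic fixture bundle shared across structural tests."""
    out = tmp_path_factory.mktemp("bundle")
    config = SimulationConfig(n_leaves=8, seq_length=60, seed=5)
    manifest = gen_fixture_bundle(config, out)
    manifest["dir"] = out
    return manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(20231105)
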