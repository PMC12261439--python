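import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles imports

from beaver import FragmentIndex, build_graph, connected_components
from beaver.simulate import make_end_to_end_fixture


@pytest.fixture(scope="session")
def tiny_fixture():
    return make_end_to_end_fixture("tiny", seed=7)


@pytest.fixture(scope="session")
def small_fixture():
    return make_end_to_end_fixture("small", seed=7)


@pytest.fixture(scope="session")
def small_clean_fixture():
    """Small fixture with neither dropout nor decoys (planted chains
    fully reconstructible)."""
    return make_end_to_end_fixture("small", seed=7, dropout_prob=0.0,
                                   decoy_rate=0.0)


@pytest.fixture(scope="session")
def small_graph(small_fixture):
    graph = build_graph(small_fixture.assemblies)
    return graph, connected_components(graph), FragmentIndex(
        small_fixture.assemblies
    )
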