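import numpy as np
import pytest

from vetowalk import (
    GeneratorConfig,
    MarkovChain,
    build_complete_graph_chain,
    build_line_chain,
    generate_trials_reversed,
)


@pytest.fixture(scope="session")
def line1():
    return build_line_chain(1)


@pytest.fixture(scope="session")
def line5():
    return build_line_chain(5)


@pytest.fixture(scope="session")
def line10():
    return build_line_chain(10)


@pytest.fixture(scope="session")
def complete5():
    return build_complete_graph_chain(5)


@pytest.fixture(scope="session")
def custom2():
    # reversible 2-state chain with stationary (0.75, 0.25)
    return MarkovChain(np.array([[0.9, 0.1], [0.3, 0.7]]))


@pytest.fixture(scope="session")
def nonreversible3():
    return MarkovChain(
        np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.4, 0.1, 0.5]])
    )


@pytest.fixture(scope="session")
def small_reversed_line5(line5):
    """A modest reversed-mode TrialSet shared by classification tests."""
    cfg = GeneratorConfig(chain=line5, N=20, M=10, k=20, p_switch=0.2, seed=11)
    return generate_trials_reversed(cfg)
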