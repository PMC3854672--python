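import warnings

import pytest

from crwalign.config import Config
from crwalign.descriptor import build_descriptor
from crwalign.fixtures import figure1_fixture, figure3_fixture, synth_template
from crwalign.stats import build_taxon_statistics

# the statistics modules warn on degenerate columns by design; tests that
# assert on warnings re-enable them locally
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def figure1():
    """The worked-example template: 10 sequences, 3 taxa, 34 columns."""
    alignment, taxonomy = figure1_fixture()
    config = Config(block_size=5, min_sequences=3)
    stats = build_taxon_statistics(alignment, taxonomy, config)
    return alignment, taxonomy, config, stats


@pytest.fixture(scope="session")
def figure3():
    """The structured toy template: 7 sequences, 3 nodes, one hairpin."""
    alignment, taxonomy = figure3_fixture()
    descriptor = build_descriptor(alignment, taxonomy, min_sequences=2)
    return alignment, taxonomy, descriptor


@pytest.fixture(scope="session")
def synth200():
    """A compact synthetic template (2 structural units, 200 columns)."""
    alignment, taxonomy, pairs, truth = synth_template(
        3, 10, 200, "default", 0.05, 0.02, seed=7
    )
    descriptor = build_descriptor(alignment, taxonomy, min_sequences=5)
    return alignment, taxonomy, pairs, truth, descriptor


@pytest.fixture(scope="session")
def synth600():
    """The study-scale synthetic template (6 units, 600 columns, seed 1)."""
    return synth_template(3, 10, 600, "default", 0.05, 0.02, seed=1)
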