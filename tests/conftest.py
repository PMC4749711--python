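import numpy as np
import pytest

from spacertyper import NucleotideSequence
from spacertyper.synth import PanelConfig, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A small but complete panel (5 templates + 4 isolates)."""
    cfg = PanelConfig(n_references=5, n_isolates=4, seed=7)
    seqs, truths = generate_panel(cfg)
    return cfg, seqs, truths


@pytest.fixture(scope="session")
def default_panel():
    """The study-scale default panel (14 + 23, seed 42)."""
    cfg = PanelConfig(seed=42)
    seqs, truths = generate_panel(cfg)
    return cfg, seqs, truths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n, seq_id="s"):
    return NucleotideSequence(seq_id, "".join(rng.choice(list("ACGT"), size=n)))
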