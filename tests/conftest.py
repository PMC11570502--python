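import numpy as np
import pytest

from callgram import synth


@pytest.fixture(scope="session")
def default_config():
    return synth.GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def small_corpus():
    """A reduced corpus (fast): playback trials only, ~20 per stimulus."""
    cfg = synth.GeneratorConfig(seed=7)
    layout = [("leopard", "playback", 20), ("eagle", "playback", 20),
              ("tree", "playback", 20), ("chimpanzee", "playback", 5)]
    trials, calls = synth.generate_corpus(cfg, layout)
    return cfg, trials, calls


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def label_from_truth(calls):
    """Copy ground-truth symbols into assigned_type (bypasses clustering)."""
    for c in calls:
        c.assigned_type = c.true_type
    return calls
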