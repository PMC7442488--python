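"""Shared fixtures.

Training-based fixtures are session-scoped (a quasi-natural training run of
the full-size network takes tens of seconds) and deterministic: every
stochastic stage takes an explicit seed.
"""

from __future__ import annotations

import pytest

import pecircuit as pz
from pecircuit import analysis, protocols, theory

# reduced network used for training-heavy qualitative tests; in-degrees of
# every pathway stay >= 1 at these sizes
SMALL_SIZES = pz.PopulationSizes(35, 8, 8, 8)


@pytest.fixture(scope="session")
def default_config():
    return pz.InputConfiguration()


@pytest.fixture(scope="session")
def nonplastic_net(default_config):
    """Non-plastic default network with solved background drives."""
    ws = pz.default_nonplastic_weights(default_config, rng_seed=1)
    background = theory.background_for_weights(ws).as_drives(ws.sizes)
    return ws, background


@pytest.fixture(scope="session")
def trained_default(default_config):
    """Full-size default network after quasi-natural training (backprop
    rules); shared by the emergence, balance-recovery and sweep tests."""
    ws = pz.default_plastic_weights(default_config, rng_seed=1)
    seq = protocols.generate_training_sequence("QT", n_stimuli=3000, rng_seed=11)
    return pz.train(ws, default_config, seq)


def train_small(input_config, paradigm="QT", conn_seed=1, stim_seed=21,
                n_stimuli=2500, config=None, plastic_pe=False):
    """Train a reduced-size network; helper for the qualitative suite."""
    ws = pz.default_plastic_weights(input_config, SMALL_SIZES,
                                    rng_seed=conn_seed, plastic_pe=plastic_pe)
    seq = protocols.generate_training_sequence(paradigm, n_stimuli,
                                               rng_seed=stim_seed)
    return pz.train(ws, input_config, seq, config)


def triplet_of(result, input_config, dt=0.5, **kw):
    return analysis.run_triplet(result.weights, input_config, dt=dt, **kw)
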