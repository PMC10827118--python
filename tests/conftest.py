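import numpy as np
import pytest

from mtsl import task
from mtsl.gru import TrainingConfig, train_participant


@pytest.fixture(scope="session")
def layout():
    return task.make_layout(7)


@pytest.fixture(scope="session")
def participant():
    return task.make_participant(seed=11, group_index=3)


@pytest.fixture(scope="session")
def trained_instances():
    """Three small trained instances with early/late checkpoints.

    Shared across unit tests that need a learner with some structure;
    full-scale study conditions live in the acceptance tests.
    """
    out = []
    for i in range(3):
        p = task.make_participant(seed=100 + i, group_index=i)
        cfg = TrainingConfig(
            n_rounds=240, checkpoint_rounds=(0, 20, 48, 240), init_seed=200 + i
        )
        ckpts = {c.rounds_seen: c for c in train_participant(cfg, p, 300 + i)}
        out.append((p, ckpts))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
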