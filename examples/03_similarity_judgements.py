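"""Simulate two-alternative similarity judgements between games.

The trained network's context embeddings (hidden state after switching on
a single game-identity unit) are compared with correlation distances; a
temperature-1 softmax over the two options' distances to the comparison
game gives the choice probability, sampled 10 times per trial.

Accuracy above 0.5 on a trial type means the relevant rule is reflected
in the learned context representations.  Type g records the proportion of
high-level-matching choices: below 0.5 indicates a low-level bias.
"""

import numpy as np

from mtsl import TrainingConfig, make_participant, train_participant
from mtsl.similarity import (
    accuracy_by_type,
    generate_similarity_trials,
    simulate_judgements,
)

participant = make_participant(seed=3, group_index=5)
config = TrainingConfig(n_rounds=240, checkpoint_rounds=(240,), init_seed=4)
ckpt = train_participant(config, participant, stream_seed=5)[-1]

rng = np.random.default_rng(6)
trials = generate_similarity_trials(participant.assignment, rng)
judgements = simulate_judgements(ckpt.params, trials, rng, n_samples=10)
labels = {
    "a": "attention check (one option is the comparison itself)",
    "b": "same rules vs both rules differ",
    "c": "same rules vs low-level rule differs",
    "d": "same rules vs high-level rule differs",
    "e": "both differ vs only high differs (low-level diagnostic)",
    "f": "both differ vs only low differs (high-level diagnostic)",
    "g": "low-level match vs high-level match (bias, not accuracy)",
}
for ttype, acc in accuracy_by_type(judgements).items():
    print(f"type {ttype}: {acc:.3f}  {labels[ttype]}")
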