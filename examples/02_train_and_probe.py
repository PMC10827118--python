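"""Train one learner and measure its timescale-sensitivity indices.

The GRU (17 inputs -> 150 gated recurrent units -> 9 outputs) is trained
to predict the next target location, one RMSprop step per round of the 8
games.  Frozen checkpoints are then probed: noise (sigma = 1.0) corrupts
the input step before a probed trial and the model's forced choice among
the 8 peripheral locations is scored against the game's own rules.

Sensitivity indices are proportion differences: 0 at chance, 1 at
ceiling.  Low-level sensitivity grows faster than high-level sensitivity,
the study's key asymmetry.
"""

import numpy as np

from mtsl import NoiseSpec, TrainingConfig, evaluate_checkpoint
from mtsl import make_participant, train_participant

participant = make_participant(seed=42, group_index=2)
config = TrainingConfig(n_rounds=240, checkpoint_rounds=(0, 48, 240),
                        init_seed=7)
checkpoints = train_participant(config, participant, stream_seed=8)

rng = np.random.default_rng(9)
print("rounds  low-level  high-level(earliest)")
for ckpt in checkpoints:
    res = evaluate_checkpoint(
        ckpt.params, participant, n_eval_rounds=100,
        noise=NoiseSpec(sigma=1.0, n_injections=10), rng=rng,
    )
    print(f"{ckpt.rounds_seen:6d}  {res.low_level:9.3f}"
          f"  {res.high_level_earliest:10.3f}")
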