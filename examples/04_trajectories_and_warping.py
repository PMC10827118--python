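"""Representational trajectories: distance structure, MDS plot, warping.

Hidden states are recorded during clean gameplay, averaged per (game,
trial) over many rounds, and compared with correlation distances.  The
warping contrast asks whether games differing in the low-level rule are
further apart in activation space than games differing in the high-level
rule; a positive value mirrors the stronger low-level imprint seen in the
similarity judgements.  The MDS figure shows each game's 27-trial
trajectory in a shared 2-D embedding.
"""

import numpy as np

from mtsl import TrainingConfig, make_participant, train_participant
from mtsl.experiment import plot_trajectories
from mtsl.representation import average_trajectories, warping_statistic

participant = make_participant(seed=12, group_index=9)
config = TrainingConfig(n_rounds=240, checkpoint_rounds=(48, 240),
                        init_seed=13)
early, late = train_participant(config, participant, stream_seed=14)

rng = np.random.default_rng(15)
for ckpt in (early, late):
    tensor = average_trajectories(ckpt.params, participant, 50, rng)
    stat = warping_statistic(tensor, participant.assignment)
    print(f"after {ckpt.rounds_seen:3d} rounds: warping contrast = {stat:+.3f}")
    if ckpt.rounds_seen == config.n_rounds:
        plot_trajectories(
            tensor, participant.assignment, "trajectories_late.png", seed=0
        )
        print("late-training MDS trajectory plot -> trajectories_late.png")
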