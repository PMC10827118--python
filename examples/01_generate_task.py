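"""Build one simulated participant's task materials and inspect a game.

Each participant gets a randomized board layout (8 peripheral locations
split into two 4-location sets, each carrying two ordered pairs) and one
of 16 counterbalance lists assigning the 8 games to the 2x2 crossing of
high-level (which set appears in which half) and low-level (which second
location completes each pair) order rules.
"""

import numpy as np

from mtsl import make_participant, generate_game_sequence

participant = make_participant(seed=0, group_index=0)

print("location sets:", sorted(participant.layout.set_a),
      sorted(participant.layout.set_b))
print("pairs under L1:", participant.layout.pairs_l1)
print("pairs under L2:", participant.layout.pairs_l2)
print()
print("game -> condition:",
      {g: c.label for g, c in participant.assignment.items()})
print()

rng = np.random.default_rng(1)
seq = generate_game_sequence(participant.games[0], rng)
print(f"game 0 ({seq.game.condition.label}), 27 trials "
      "(trial, location, role, half):")
for t in seq.trials:
    print(f"  {t.index + 1:2d}  loc {t.location}  {t.role.value:15s} "
          f"{t.half.value}")
# Every pair presentation is (center, first, second); the three mid-game
# centers mark the event boundary between the two location-set halves.
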