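# Methods

`mtsl` simulates rapid statistical learning of temporal structure at two
nested timescales and the readouts used to measure it. This note documents
the task model, the learner, the three analyses, the numerical choices made
where the design was genuinely open, and known limitations.

## Task environment

A session consists of 8 "whack-a-mole" games played on a board with one
center hole and 8 peripheral holes. Per participant, the peripheral
locations are randomly partitioned into two 4-location sets (A, B), and
each set into two ordered pairs (first → second). Two binary order rules
are crossed 2 × 2 over games:

- **high-level rule** (slow timescale): whether set A or set B supplies
  targets in the first half of a game (the other set takes the second half);
- **low-level rule** (fast timescale): which second location completes each
  pair. The two low-level rules share all pair-first locations and swap the
  pair-second locations *within* each set, so the half-game location sets
  are identical across low-level conditions and only the adjacent-trial
  transition differs.

Each game lasts 27 trials: per half, its two pairs are each presented twice
in randomized order as (pre-pair center, pair-first, pair-second) triplets
(12 trials), with three consecutive center trials in mid-game forming an
event boundary (2 × 12 + 3 = 27; 11 center and 16 peripheral trials). The
pair-second location follows its pair-first location with probability 1.
This 27-trial layout places the boundary centers at trials 13–15, directly
followed by the second half's first pre-pair center; a visible run of four
centers is the price of honoring both the 27-trial length and the
triplet structure, which are jointly binding.

Games are assigned to the four joint conditions (two games each) by one of
16 counterbalance groups. Across the family of groups each game occupies
each joint condition exactly 4 times. Exact balance of how often two games
*share* a rule is impossible: each group contributes 12 same-rule pairs, so
16 groups give 192 sharing events over 28 game pairs (48/7 each), and
parity forces every sharing count to be even. The family is constructed by
a deterministic constraint-preserving local search that achieves the
provable optimum — all pair-sharing counts in {6, 8} for both rules — and
is verified by brute-force tallies in the tests.

Model inputs are 17-dimensional indicators per trial: 8 context units
(one-hot game identity, constant within a game) and 9 location units.
Prediction probes are evaluation points, not extra timesteps: one probe per
game per round (three in a final round when emulating the human session),
placed on the earliest peripheral trial with probability 0.375 and
otherwise uniformly over the remaining peripheral positions.

## Learner

A single-hidden-layer gated recurrent network (17 → 150 GRU units → 9
linear outputs, fully connected) is trained to predict the next target
location: mean-squared error against the one-hot next location, excluding
each game's final trial (it has no within-game successor). One RMSprop
step (lr 0.001, ρ 0.9, ε 1e-7) is taken per round-batch of all 8 games;
hidden activations reset between games. Feedforward weights are
Glorot-uniform per gate, recurrent weights orthogonal (QR of a random
normal matrix, sign-fixed), biases zero. The default gate order applies
the reset gate to the previous hidden state before the recurrent product
("reset-before"); the "reset-after" variant is available and produces
equivalent results in our hands. The implementation is plain numpy with
analytic backpropagation through time, verified against central finite
differences to better than 1e-4 relative error (observed ~1e-8) for both
gate variants.

Training runs for 240 rounds (one simulated participant's full stream,
sequences regenerated every round). Analyses default to the **final
checkpoint**, with an early comparison checkpoint at one fifth of that
exposure (48 rounds). Reference implementations of this paradigm in a
mainstream deep-learning framework reach the same behavioral operating
point after roughly 4–6× fewer gradient steps than this implementation;
the discrepancy traces to framework internals that the stated
hyperparameters do not pin down (we verified it is not the gate variant,
the initializer fan, sequence reuse, or the gradient computation). Since
the operating point — not the step count — defines the analyses, the
default analysis checkpoint is the end of the full training duration,
where prediction sensitivity has saturated at the levels the similarity
and representational analyses presuppose. The checkpoint is configurable
(`ExperimentConfig.analysis_round`).

## Readouts

**Online prediction sensitivity.** With frozen weights, fresh rounds are
generated and probed at session-matched probe points. The input at the
step immediately before the probed trial is corrupted with zero-mean
Gaussian noise (σ = 1.0 default; a sweep utility covers 0.01, 0.1–2.0,
10). The prediction is the argmax over the 8 peripheral output units (the
center is barred, as in the forced-choice probe). Ten independent noise
injections are averaged **at the choice level**: each injection yields a
response and the indices are proportions over responses; this follows the
reading that performance, not the output vector, is averaged over
injections, and it matters — output-vector averaging suppresses the noise
(effective σ ≈ σ/√10) and roughly doubles both indices at a given
checkpoint. Output-averaging is available via `average="output"`.
Indices: low-level sensitivity = P(response = own-rule pair-second) −
P(response = opposite-rule pair-second) at pair-second probes; high-level
sensitivity = P(response ∈ half-appropriate set) − P(response ∈ other set)
at pair-first probes, optionally restricted to the earliest (context-only)
probe of each game. Both are 0 at chance and 1 at ceiling; a random agent
and a rule-oracle agent bracket the learner in the tests.

**Similarity judgements.** A game's context embedding is the hidden state
after a single step from zero with only its context unit active (duration
configurable). Option distances to the comparison game are correlation
distances (1 − Pearson r over the 150 units); the probability of choosing
an option is a temperature-1 softmax over negative distances — equivalent,
by shift invariance, to any common offset of the distances. All valid
trial triplets per type (a–g) are enumerated, and 10 choices are sampled
per trial. Accuracies above 0.5 on types c/e (d/f) indicate low-level
(high-level) rule information in the context representations; type g
records the proportion of high-level-matching choices.

**Representational trajectories.** Hidden states during clean gameplay are
averaged per (game, trial) over evaluation rounds (default 50; the
average converges quickly because pair order randomizes across rounds),
yielding an 8 × 27 × 150 tensor per instance. The 216 × 216 correlation-
distance matrix over (game, trial) vectors supports 2-D metric MDS
trajectory plots. The warping contrast is
\[mean distance, different low-level rule − same low-level rule\] −
\[same quantity for the high-level rule\], where a game-pair distance is
the mean over the full 27 × 27 between-game block of the distance matrix.
Block averaging is essential: averaging only matched trial indices is
dominated by whether two games show the same location set at the same
time, which reverses the sign of the contrast; the block mean cancels that
set-alignment component and isolates learned context structure. The
matched-trial aggregation and a Euclidean metric remain available as
options.

**Statistics.** Cross-instance inference uses two-sided one-sample and
paired t-tests (df = n − 1), percentile bootstrap 95% bands for learning
curves (resampling instances), and Benjamini–Hochberg FDR flags, all
delegated to scipy/statsmodels behind thin reporting wrappers.

## Reproducibility and problem sizes

A master seed fans out through `numpy.random.SeedSequence` to per-instance
seeds for materials, initialization, training stream, probe evaluation,
similarity sampling, and trajectory rounds; two runs with the same
configuration produce identical tables. Default study size — 48 instances,
240 training rounds, 100 probe-evaluation rounds and 50 trajectory rounds
per instance — completes in about two minutes on one CPU core; the test
suite uses the same sizes for the replication checks and smaller ones
elsewhere.

## What the generator does and does not emulate

The synthetic task reproduces the structural statistics that drive
learning: deterministic within-pair transitions, half-game set switching,
boundary centers, counterbalancing, probe placement. It does not model
motor behavior (reaction times, missed clicks, point scoring), stimulus
artwork, or instruction wording, so quantitative matches to human data
beyond the modeled statistics are out of scope: passing tests demonstrate
properties of the learning model under the task's statistics, not a fit
to any individual human dataset.

## Known limitations

- The exposure scale (gradient steps to reach a given operating point) is
  implementation-dependent (see Learner); comparisons across
  implementations should align on performance, not round counts.
- The representational warping contrast is non-monotone in training: it
  peaks mid-training (values around 0.4–0.5 here) and relaxes to ~0.2 as
  prediction performance saturates, so its magnitude is sensitive to the
  checkpoint at which it is measured.
- High-level (earliest-probe) sensitivity at the default checkpoint sits
  near 0.19; it is the measure most sensitive to the noise model at the
  probe step.
- Choice-level noise averaging makes per-instance indices noisier than
  output averaging; the defaults compensate with 100 evaluation rounds
  (≈ 2,700 pair-second and ≈ 3,000 earliest-probe responses per instance).
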