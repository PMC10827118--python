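"""Frozen-weight prediction probes and timescale-sensitivity indices.

At a probe point the learner predicts the upcoming target location among
the 8 peripheral positions (the center is excluded from the choice, as in
a forced-choice probe).  Gaussian noise is added to all 17 input units at
the step immediately preceding the probed trial.  Performance is averaged
over independent noise injections at the choice level by default: every
injection yields its own argmax response and the sensitivity indices are
proportions over all responses.  Averaging the output vectors before the
argmax is available as an alternative (lower-variance) mode.

Two indices summarize what has been learned, each a proportion difference
in [-1, 1] (0 at chance):

* **low-level sensitivity** — at pair-second probes, P(response is the
  pair's second location under the game's own low-level rule) minus
  P(response is the second location under the opposite rule);
* **high-level sensitivity** — at pair-first probes, P(response in the
  half-appropriate 4-location set) minus P(response in the other set);
  the *earliest-probe* variant keeps only the first peripheral trial of
  each game, where only context and set knowledge can help.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import task
from .gru import GRUParams, forward_sequence, gru_step, readout
from .task import Half, Participant, Role, TrialSequence

DEFAULT_SIGMA = 1.0
DEFAULT_N_INJECTIONS = 10
DEFAULT_AVERAGE = "choice"
NOISE_SWEEP_SIGMAS = (0.01, 10.0) + tuple(np.round(np.arange(0.1, 2.01, 0.1), 1))


@dataclass(frozen=True)
class NoiseSpec:
    """Zero-mean Gaussian input corruption applied at the pre-probe step."""

    sigma: float = DEFAULT_SIGMA
    n_injections: int = DEFAULT_N_INJECTIONS

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n_injections < 1:
            raise ValueError("n_injections must be >= 1")


@dataclass(frozen=True)
class SensitivityResult:
    low_level: float
    high_level_all: float
    high_level_earliest: float
    n_low_probes: int
    n_high_probes: int
    n_earliest_probes: int
    rounds_seen: int | None = None
    instance: int | None = None


def predict_at_probe(
    params: GRUParams,
    sequence: TrialSequence,
    probe_index: int,
    noise: NoiseSpec,
    rng: np.random.Generator,
    variant: str = "reset_before",
    average: str = "output",
) -> int:
    """Predicted peripheral location (1..8) for the trial at ``probe_index``.

    The clean sequence is run up to the step before the probed trial, the
    input at that final pre-probe step is corrupted with fresh noise per
    injection, and the resulting output vectors are averaged ("output",
    default) or the per-injection argmax choices are tallied ("choice").
    """
    trial = sequence.trials[probe_index]
    if trial.location == 0 or trial.role in (
        Role.PREPAIR_CENTER,
        Role.BOUNDARY_CENTER,
    ):
        raise ValueError("probes target peripheral trials only")
    x = task.encode_sequence(sequence)
    h_prev = np.zeros(params.n_hidden)
    if probe_index >= 2:
        hs, _ = forward_sequence(params, x[: probe_index - 1], variant)
        h_prev = hs[-1]
    x_pre = x[probe_index - 1]
    noisy = x_pre + rng.normal(0.0, noise.sigma, (noise.n_injections, 17))
    h = gru_step(
        params,
        np.broadcast_to(h_prev, (noise.n_injections, params.n_hidden)),
        noisy,
        variant,
    )
    outs = readout(params, h)
    return _choose_peripheral(outs, average)


def _choose_peripheral(outs: np.ndarray, average: str = "output") -> int:
    """Forced choice over the 8 peripheral output units."""
    peripheral = outs[..., 1:9]
    if average == "output":
        mean = peripheral.mean(axis=0) if peripheral.ndim == 2 else peripheral
        return int(np.argmax(mean)) + 1
    if average == "choice":
        votes = np.argmax(peripheral, axis=-1)
        counts = np.bincount(votes, minlength=8)
        return int(np.argmax(counts)) + 1
    raise ValueError(f"unknown averaging mode: {average}")


def probe_responses(
    params: GRUParams,
    participant: Participant,
    n_rounds: int,
    noise: NoiseSpec,
    rng: np.random.Generator,
    variant: str = "reset_before",
    average: str = DEFAULT_AVERAGE,
    final_round_probes: int = 1,
) -> pd.DataFrame:
    """Probe the frozen network over fresh rounds of the participant's games.

    Each round regenerates randomized sequences; probe positions follow the
    session schedule (earliest-trial bias 0.375).  In the default
    choice-level mode every injection contributes one response row; in
    "output" mode the injection-averaged output yields one row per probe.
    Vectorized over the 8 games of a round and over injections.
    """
    schedule = task.schedule_probes(
        n_rounds, rng, final_round_probes=final_round_probes
    )
    records: list[dict] = []
    for r in range(n_rounds):
        seqs = task.generate_round(participant, rng, shuffle_games=False)
        x = task.encode_games(seqs)  # (8, 27, 17)
        hs, _ = forward_sequence(params, x, variant)
        probe_jobs = []  # (game_slot, probe_index)
        for g in range(task.N_GAMES):
            for idx in schedule.probes[(r, g)]:
                probe_jobs.append((g, idx))
        n_jobs = len(probe_jobs)
        k = noise.n_injections
        h_prev = np.zeros((n_jobs, k, params.n_hidden))
        x_pre = np.zeros((n_jobs, k, 17))
        for j, (g, idx) in enumerate(probe_jobs):
            if idx >= 2:
                h_prev[j] = hs[g, idx - 2]
            x_pre[j] = x[g, idx - 1]
        noisy = x_pre + rng.normal(0.0, noise.sigma, x_pre.shape)
        h = gru_step(
            params,
            h_prev.reshape(-1, params.n_hidden),
            noisy.reshape(-1, 17),
            variant,
        )
        outs = readout(params, h).reshape(n_jobs, k, -1)
        for j, (g, idx) in enumerate(probe_jobs):
            seq = seqs[g]
            trial = seq.trials[idx]
            game = seq.game
            if average == "choice":
                responses = [
                    _choose_peripheral(outs[j, inj]) for inj in range(k)
                ]
            else:
                responses = [_choose_peripheral(outs[j], average)]
            layout = game.layout
            if trial.role == Role.PAIR_SECOND:
                first_loc = seq.trials[idx - 1].location
                own = layout.pair_dict(game.condition.low_rule)[first_loc]
                opp = layout.pair_dict(1 - game.condition.low_rule)[first_loc]
            else:
                own = opp = np.nan
            correct_set = layout.half_set(game.condition.high_rule, trial.half)
            for response in responses:
                records.append(
                    {
                        "round": r,
                        "game_id": game.game_id,
                        "high_rule": game.condition.high_rule,
                        "low_rule": game.condition.low_rule,
                        "trial_index": idx,
                        "role": trial.role.value,
                        "is_earliest": idx == task.EARLIEST_PERIPHERAL_IDX,
                        "response": response,
                        "target": trial.location,
                        "own_second": own,
                        "opposite_second": opp,
                        "in_correct_set": response in correct_set,
                    }
                )
    return pd.DataFrame.from_records(records)


def low_level_sensitivity(responses: pd.DataFrame) -> float:
    """Own-rule minus opposite-rule response proportion at pair-second
    probes."""
    sub = responses[responses["role"] == Role.PAIR_SECOND.value]
    if len(sub) == 0:
        raise ValueError("no pair-second probe responses")
    own = (sub["response"] == sub["own_second"]).mean()
    opp = (sub["response"] == sub["opposite_second"]).mean()
    return float(own - opp)


def high_level_sensitivity(
    responses: pd.DataFrame, earliest_only: bool = False
) -> float:
    """Correct-set minus incorrect-set response proportion at pair-first
    probes (equivalently 2 * P(correct set) - 1)."""
    sub = responses[responses["role"] == Role.PAIR_FIRST.value]
    if earliest_only:
        sub = sub[sub["is_earliest"]]
    if len(sub) == 0:
        raise ValueError("no eligible pair-first probe responses")
    p_correct = sub["in_correct_set"].mean()
    return float(2.0 * p_correct - 1.0)


def sensitivities_from_responses(
    responses: pd.DataFrame,
    rounds_seen: int | None = None,
    instance: int | None = None,
) -> SensitivityResult:
    first = responses["role"] == Role.PAIR_FIRST.value
    second = responses["role"] == Role.PAIR_SECOND.value
    return SensitivityResult(
        low_level=low_level_sensitivity(responses),
        high_level_all=high_level_sensitivity(responses),
        high_level_earliest=high_level_sensitivity(responses, True),
        n_low_probes=int(second.sum()),
        n_high_probes=int(first.sum()),
        n_earliest_probes=int((first & responses["is_earliest"]).sum()),
        rounds_seen=rounds_seen,
        instance=instance,
    )


def evaluate_checkpoint(
    params: GRUParams,
    participant: Participant,
    n_eval_rounds: int,
    noise: NoiseSpec,
    rng: np.random.Generator,
    variant: str = "reset_before",
    rounds_seen: int | None = None,
    instance: int | None = None,
    return_responses: bool = False,
    average: str = DEFAULT_AVERAGE,
):
    """Sensitivity indices for one frozen checkpoint over fresh rounds."""
    responses = probe_responses(
        params, participant, n_eval_rounds, noise, rng, variant, average
    )
    result = sensitivities_from_responses(responses, rounds_seen, instance)
    if return_responses:
        return result, responses
    return result


def noise_sweep(
    params: GRUParams,
    participant: Participant,
    rng: np.random.Generator,
    sigmas=NOISE_SWEEP_SIGMAS,
    n_eval_rounds: int = 100,
    n_injections: int = DEFAULT_N_INJECTIONS,
    variant: str = "reset_before",
    average: str = DEFAULT_AVERAGE,
) -> pd.DataFrame:
    """Sensitivity indices across input-noise levels, one row per sigma."""
    rows = []
    for sigma in sigmas:
        res = evaluate_checkpoint(
            params,
            participant,
            n_eval_rounds,
            NoiseSpec(sigma=sigma, n_injections=n_injections),
            rng,
            variant,
            average=average,
        )
        rows.append(
            {
                "sigma": sigma,
                "low_level": res.low_level,
                "high_level_all": res.high_level_all,
                "high_level_earliest": res.high_level_earliest,
            }
        )
    return pd.DataFrame(rows)
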