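"""Simulated two-alternative similarity judgements between games.

A comparison game is shown with two option games; the "more similar"
option is chosen stochastically through a temperature-1 softmax over the
negative correlation distances between *context embeddings* — hidden
states elicited by activating only a game's context unit for a single
step from a zero hidden state.

Trial types (the designated correct option in parentheses):

a. attention check — one option *is* the comparison game
b. same-rules twin vs. a game differing in both rules (twin)
c. same-rules twin vs. differing only in the low-level rule (twin)
d. same-rules twin vs. differing only in the high-level rule (twin)
e. both-differ vs. only-high-differs (the low-rule-sharing option)
f. both-differ vs. only-low-differs (the high-rule-sharing option)
g. one option matches on the low-level rule, the other on the high-level
   rule; the recorded outcome is the proportion choosing the
   high-level-matching option (a bias measure, not an accuracy)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gru import GRUParams, gru_step, N_INPUT
from .task import N_GAMES, RuleCondition

TRIAL_TYPES = ("a", "b", "c", "d", "e", "f", "g")
# types whose accuracy indexes low-level vs high-level order knowledge
LOW_DIAGNOSTIC = ("c", "e")
HIGH_DIAGNOSTIC = ("d", "f")


@dataclass(frozen=True)
class SimilarityTrial:
    trial_type: str
    comparison: int
    option1: int
    option2: int
    correct_option: int  # 1 or 2; for type g, the high-level-matching option


def context_embedding(
    params: GRUParams, game_id: int, variant: str = "reset_before",
    n_steps: int = 1,
) -> np.ndarray:
    """Hidden state after ``n_steps`` with only the game's context unit on."""
    x = np.zeros(N_INPUT)
    x[game_id] = 1.0
    h = np.zeros(params.n_hidden)
    for _ in range(n_steps):
        h = gru_step(params, h, x, variant)
    return h


def context_embeddings(
    params: GRUParams, variant: str = "reset_before", n_steps: int = 1
) -> np.ndarray:
    return np.stack(
        [context_embedding(params, g, variant, n_steps) for g in range(N_GAMES)]
    )


def game_distance(e1: np.ndarray, e2: np.ndarray) -> float:
    """Correlation distance 1 - r between two embedding vectors."""
    s1, s2 = np.std(e1), np.std(e2)
    if s1 == 0 or s2 == 0:
        raise ValueError("correlation distance undefined for constant vector")
    r = float(np.corrcoef(e1, e2)[0, 1])
    return 1.0 - r


def _relation(c1: RuleCondition, c2: RuleCondition) -> tuple[bool, bool]:
    return (c1.high_rule == c2.high_rule, c1.low_rule == c2.low_rule)


def generate_similarity_trials(
    condition_map: dict[int, RuleCondition],
    rng: np.random.Generator | None = None,
) -> list[SimilarityTrial]:
    """Enumerate all valid (comparison, option1, option2) triplets per type.

    Option order is randomized when an rng is given (the choice model is
    order-symmetric, so enumeration order carries no information).
    """
    games = sorted(condition_map)
    trials: list[SimilarityTrial] = []

    def add(ttype: str, comp: int, correct: int, foil: int) -> None:
        if rng is not None and rng.random() < 0.5:
            trials.append(SimilarityTrial(ttype, comp, foil, correct, 2))
        else:
            trials.append(SimilarityTrial(ttype, comp, correct, foil, 1))

    for comp in games:
        cc = condition_map[comp]
        others = [g for g in games if g != comp]
        twins = [g for g in others if _relation(cc, condition_map[g]) == (True, True)]
        low_diff = [g for g in others if _relation(cc, condition_map[g]) == (True, False)]
        high_diff = [g for g in others if _relation(cc, condition_map[g]) == (False, True)]
        both_diff = [g for g in others if _relation(cc, condition_map[g]) == (False, False)]
        for other in others:
            add("a", comp, comp, other)
        for twin in twins:
            for foil in both_diff:
                add("b", comp, twin, foil)
            for foil in low_diff:
                add("c", comp, twin, foil)
            for foil in high_diff:
                add("d", comp, twin, foil)
        for correct in high_diff:  # shares the low-level rule
            for foil in both_diff:
                add("e", comp, correct, foil)
        for correct in low_diff:  # shares the high-level rule
            for foil in both_diff:
                add("f", comp, correct, foil)
        # type g: option matching on high level (= low_diff games) vs
        # option matching on low level (= high_diff games); "correct"
        # records the high-level-matching option.
        for high_match in low_diff:
            for low_match in high_diff:
                add("g", comp, high_match, low_match)
    return trials


def choice_probability(
    d_correct: float, d_foil: float, temperature: float = 1.0
) -> float:
    """Softmax over negative distances; invariant to shifting both
    distances by a constant."""
    a = -np.asarray([d_correct, d_foil]) / temperature
    a -= a.max()
    e = np.exp(a)
    return float(e[0] / e.sum())


def simulate_judgements(
    params: GRUParams,
    trials: list[SimilarityTrial],
    rng: np.random.Generator,
    n_samples: int = 10,
    temperature: float = 1.0,
    variant: str = "reset_before",
    analytic: bool = False,
) -> pd.DataFrame:
    """Per-trial choice accuracy, averaged over ``n_samples`` sampled
    choices (or the analytic expectation when ``analytic``)."""
    emb = context_embeddings(params, variant)
    rows = []
    for trial in trials:
        d1 = 0.0 if trial.option1 == trial.comparison else game_distance(
            emb[trial.comparison], emb[trial.option1]
        )
        d2 = 0.0 if trial.option2 == trial.comparison else game_distance(
            emb[trial.comparison], emb[trial.option2]
        )
        if trial.correct_option == 1:
            p_correct = choice_probability(d1, d2, temperature)
        else:
            p_correct = choice_probability(d2, d1, temperature)
        if analytic:
            acc = p_correct
        else:
            acc = float(np.mean(rng.random(n_samples) < p_correct))
        rows.append(
            {
                "trial_type": trial.trial_type,
                "comparison": trial.comparison,
                "p_correct": p_correct,
                "accuracy": acc,
            }
        )
    return pd.DataFrame(rows)


def accuracy_by_type(judgements: pd.DataFrame) -> pd.Series:
    """Mean accuracy per trial type (for type g: the high-level-choice
    proportion)."""
    return judgements.groupby("trial_type")["accuracy"].mean()


def low_high_diagnostic_difference(by_type: pd.Series) -> float:
    """Mean accuracy over low-diagnostic types (c, e) minus mean over
    high-diagnostic types (d, f)."""
    low = np.mean([by_type[t] for t in LOW_DIAGNOSTIC])
    high = np.mean([by_type[t] for t in HIGH_DIAGNOSTIC])
    return float(low - high)
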