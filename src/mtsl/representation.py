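"""Hidden-representation trajectory analysis.

Hidden states are recorded during noise-free gameplay, averaged per
(game, trial) over many evaluation rounds, and compared with correlation
distances: a 216 x 216 representational distance matrix over the
8 games x 27 trials, its 2-D multidimensional-scaling embedding, and a
warping contrast asking whether games differing in the low-level rule are
further apart in activation space than games differing in the high-level
rule.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from . import task
from .gru import GRUParams, forward_sequence
from .task import Participant, RuleCondition, N_GAMES, TRIALS_PER_GAME


def average_trajectories(
    params: GRUParams,
    participant: Participant,
    n_rounds: int,
    rng: np.random.Generator,
    variant: str = "reset_before",
) -> np.ndarray:
    """Mean hidden vector per (game, trial): an (8, 27, n_hidden) tensor.

    Sequences are regenerated per round (randomized pair order), so the
    average reflects each game's stable structure rather than any single
    realization; inputs are clean (no probe noise).
    """
    total = np.zeros((N_GAMES, TRIALS_PER_GAME, params.n_hidden))
    for _ in range(n_rounds):
        seqs = task.generate_round(participant, rng, shuffle_games=False)
        x = task.encode_games(seqs)
        hs, _ = forward_sequence(params, x, variant)
        for slot, seq in enumerate(seqs):
            total[seq.game.game_id] += hs[slot]
    return total / n_rounds


def trajectory_rdm(tensor: np.ndarray, metric: str = "correlation") -> np.ndarray:
    """Pairwise distance matrix over all (game, trial) mean vectors.

    Rows are ordered game-major: index = game * 27 + trial.
    """
    flat = tensor.reshape(-1, tensor.shape[-1])
    d = squareform(pdist(flat, metric=metric))
    np.fill_diagonal(d, 0.0)
    return d


def mds_embed(
    matrix: np.ndarray, seed: int = 0, n_components: int = 2
) -> np.ndarray:
    """Metric MDS coordinates of a precomputed distance matrix."""
    import inspect

    kwargs = dict(
        n_components=n_components,
        random_state=seed,
        normalized_stress=False,
        n_init=4,
    )
    params = inspect.signature(MDS.__init__).parameters
    if "metric_mds" in params:  # scikit-learn >= 1.9 naming
        kwargs.update(metric="precomputed", metric_mds=True, init="random")
    else:
        kwargs.update(dissimilarity="precomputed", metric=True)
    return MDS(**kwargs).fit_transform(matrix)


def game_pair_distances(
    tensor: np.ndarray,
    metric: str = "correlation",
    aggregation: str = "all_trials",
) -> np.ndarray:
    """Game-pair distance matrix derived from the (game, trial) vectors.

    ``aggregation="all_trials"`` (default) takes the mean over the full
    27 x 27 between-game block of the trial-level distance matrix, i.e.
    all pairs of trial indices; ``"matched_trials"`` averages only the
    distances at matched trial indices.  The block mean cancels the
    half-to-set alignment between games, isolating learned context
    structure; the matched-trial mean is dominated by whether the two
    games show the same location set at the same time.
    """
    n_games, n_trials, _ = tensor.shape
    d = np.zeros((n_games, n_games))
    rdm = trajectory_rdm(tensor, metric=metric)
    for i, j in combinations(range(n_games), 2):
        block = rdm[
            i * n_trials : (i + 1) * n_trials,
            j * n_trials : (j + 1) * n_trials,
        ]
        if aggregation == "all_trials":
            value = float(block.mean())
        elif aggregation == "matched_trials":
            value = float(np.diagonal(block).mean())
        else:
            raise ValueError(f"unknown aggregation: {aggregation}")
        d[i, j] = d[j, i] = value
    return d


def warping_statistic(
    tensor: np.ndarray,
    condition_map: dict[int, RuleCondition],
    metric: str = "correlation",
    aggregation: str = "all_trials",
) -> float:
    """Low-level vs high-level representational warping contrast.

    [mean game-pair distance for pairs *differing* in the low-level rule
    minus pairs *sharing* it] minus [the same quantity for the high-level
    rule].  Positive values mean the low-level rule warps the hidden
    representation more than the high-level rule.
    """
    d = game_pair_distances(tensor, metric, aggregation)
    diff_low, same_low, diff_high, same_high = [], [], [], []
    for i, j in combinations(sorted(condition_map), 2):
        ci, cj = condition_map[i], condition_map[j]
        (diff_low, same_low)[ci.low_rule == cj.low_rule].append(d[i, j])
        (diff_high, same_high)[ci.high_rule == cj.high_rule].append(d[i, j])
    low_effect = np.mean(diff_low) - np.mean(same_low)
    high_effect = np.mean(diff_high) - np.mean(same_high)
    return float(low_effect - high_effect)
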