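"""Synthetic task environment: nested-timescale "whack-a-mole" games.

A session consists of 8 games played on a board with 9 locations (one
center, 8 peripheral).  Each game follows two order rules at different
timescales:

* a *high-level* (slow) rule determining which 4-location set supplies
  targets in the first vs. second half of the game, and
* a *low-level* (fast) rule determining which second location
  deterministically follows each pair-first location.

Games are crossed in a 2x2 design (two games per joint condition) and
assigned to conditions by one of 16 counterbalance groups.  Every game
lasts 27 trials: four (center, pair-first, pair-second) presentations per
half plus three consecutive mid-game center trials forming an event
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np

N_GAMES = 8
N_LOCATIONS = 9  # index 0 = center, 1..8 peripheral
N_PERIPHERAL = 8
TRIALS_PER_GAME = 27
N_GROUPS = 16
N_INPUT_UNITS = N_GAMES + N_LOCATIONS  # 8 context + 9 location indicators
EARLIEST_PROBE_FRACTION = 0.375

# 0-based trial indices by structural role (fixed 27-trial layout:
# 4 x (center, first, second) | 3 boundary centers | 4 x (center, first, second))
PREPAIR_CENTER_IDX = (0, 3, 6, 9, 15, 18, 21, 24)
BOUNDARY_CENTER_IDX = (12, 13, 14)
PAIR_FIRST_IDX = (1, 4, 7, 10, 16, 19, 22, 25)
PAIR_SECOND_IDX = (2, 5, 8, 11, 17, 20, 23, 26)
PERIPHERAL_IDX = tuple(sorted(PAIR_FIRST_IDX + PAIR_SECOND_IDX))
EARLIEST_PERIPHERAL_IDX = 1


class Role(str, Enum):
    PREPAIR_CENTER = "prepair_center"
    BOUNDARY_CENTER = "boundary_center"
    PAIR_FIRST = "pair_first"
    PAIR_SECOND = "pair_second"


class Half(str, Enum):
    FIRST = "first"
    BOUNDARY = "boundary"
    SECOND = "second"


@dataclass(frozen=True)
class RuleCondition:
    """Joint assignment of one high-level and one low-level order rule."""

    high_rule: int  # 0 = H1, 1 = H2
    low_rule: int  # 0 = L1, 1 = L2

    def __post_init__(self) -> None:
        if self.high_rule not in (0, 1) or self.low_rule not in (0, 1):
            raise ValueError("rules are binary (0 or 1)")

    @property
    def label(self) -> str:
        return f"H{self.high_rule + 1}L{self.low_rule + 1}"


ALL_CONDITIONS = tuple(
    RuleCondition(h, l) for h in (0, 1) for l in (0, 1)
)


@dataclass(frozen=True)
class LocationLayout:
    """Randomized partition of the 8 peripheral locations.

    ``set_a`` and ``set_b`` are the two disjoint 4-location sets; under each
    low-level rule every set contributes two ordered (first, second) pairs.
    The two low-level rules share pair-first locations and differ only by
    swapping the pair-second locations within each set.
    """

    set_a: frozenset[int]
    set_b: frozenset[int]
    pairs_l1: tuple[tuple[int, int], ...]
    pairs_l2: tuple[tuple[int, int], ...]

    def pairs(self, low_rule: int) -> tuple[tuple[int, int], ...]:
        return self.pairs_l1 if low_rule == 0 else self.pairs_l2

    def pair_dict(self, low_rule: int) -> dict[int, int]:
        """Deterministic first -> second transition map under a low rule."""
        return dict(self.pairs(low_rule))

    def half_set(self, high_rule: int, half: Half) -> frozenset[int]:
        """The 4-location set active in a given half under a high rule."""
        if half == Half.BOUNDARY:
            raise ValueError("boundary trials have no active set")
        first_set = self.set_a if high_rule == 0 else self.set_b
        second_set = self.set_b if high_rule == 0 else self.set_a
        return first_set if half == Half.FIRST else second_set


def make_layout(seed: int) -> LocationLayout:
    """Randomly partition peripherals into sets and ordered pairs.

    The permutation ``p`` of locations 1..8 defines set A = {p0..p3},
    set B = {p4..p7}; L1 pairs are (p0,p1),(p2,p3),(p4,p5),(p6,p7) and L2
    swaps the seconds within each set.
    """
    rng = np.random.default_rng(seed)
    p = [int(x) for x in rng.permutation(np.arange(1, 9))]
    pairs_l1 = ((p[0], p[1]), (p[2], p[3]), (p[4], p[5]), (p[6], p[7]))
    pairs_l2 = ((p[0], p[3]), (p[2], p[1]), (p[4], p[7]), (p[6], p[5]))
    return LocationLayout(
        set_a=frozenset(p[:4]),
        set_b=frozenset(p[4:]),
        pairs_l1=pairs_l1,
        pairs_l2=pairs_l2,
    )


@dataclass(frozen=True)
class GameSpec:
    game_id: int  # 0..7, doubles as the context-unit index
    condition: RuleCondition
    layout: LocationLayout


@dataclass(frozen=True)
class CounterbalanceList:
    group_index: int
    assignment: dict[int, RuleCondition] = field(hash=False)

    def games(self, layout: LocationLayout) -> list[GameSpec]:
        return [
            GameSpec(g, self.assignment[g], layout) for g in range(N_GAMES)
        ]


def _family_objective(high: np.ndarray, low: np.ndarray) -> float:
    target = 12 * N_GROUPS / 28  # mean pair-sharing count, 48/7
    total = 0.0
    for bits in (high, low):
        same = bits.T @ bits + (1 - bits).T @ (1 - bits)
        iu = np.triu_indices(N_GAMES, 1)
        total += float(np.sum((same[iu] - target) ** 2))
    return total


def _search_family(rng: np.random.Generator) -> np.ndarray | None:
    """One randomized restart of the balanced-family search.

    Matrix entries are condition codes 0..3 ((high << 1) | low).  Rows keep
    exactly two games per joint condition; a within-row swap repair enforces
    exactly four occurrences of each condition per column, then 2x2
    interchange moves (which preserve both constraints) greedily minimize
    the imbalance of pair-sharing counts.
    """
    base = np.repeat(np.arange(4), 2)
    m = np.array([rng.permutation(base) for _ in range(N_GROUPS)])

    def col_penalty(mat: np.ndarray) -> int:
        return int(
            sum(
                np.sum((np.bincount(mat[:, c], minlength=4) - 4) ** 2)
                for c in range(N_GAMES)
            )
        )

    pen = col_penalty(m)
    for _ in range(20000):
        if pen == 0:
            break
        r = rng.integers(N_GROUPS)
        i, j = rng.integers(N_GAMES, size=2)
        if m[r, i] == m[r, j]:
            continue
        m[r, i], m[r, j] = m[r, j], m[r, i]
        new = col_penalty(m)
        if new <= pen:
            pen = new
        else:
            m[r, i], m[r, j] = m[r, j], m[r, i]
    if pen != 0:
        return None

    best = _family_objective(m >> 1, m & 1)
    # Provable optimum: sharing counts are even, so the best family has
    # counts in {6, 8}: 16 pairs at 6 and 12 at 8 per rule.
    optimum = 2 * (16 * (6 - 48 / 7) ** 2 + 12 * (8 - 48 / 7) ** 2)
    for _ in range(60000):
        if best <= optimum + 1e-9:
            break
        r1, r2 = rng.integers(N_GROUPS, size=2)
        i, j = rng.integers(N_GAMES, size=2)
        if r1 == r2 or i == j:
            continue
        a, b = m[r1, i], m[r1, j]
        if a == b or m[r2, i] != b or m[r2, j] != a:
            continue
        m[r1, i], m[r1, j] = b, a
        m[r2, i], m[r2, j] = a, b
        val = _family_objective(m >> 1, m & 1)
        if val <= best:
            best = val
        else:
            m[r1, i], m[r1, j] = a, b
            m[r2, i], m[r2, j] = b, a
    return m if best <= optimum + 1e-9 else None


@lru_cache(maxsize=1)
def counterbalance_family() -> np.ndarray:
    """The 16x8 condition-code matrix shared by all participants.

    Deterministic: the search runs from a fixed internal seed and stops at
    the provably optimal imbalance (pair-sharing counts in {6, 8}).
    """
    rng = np.random.default_rng(20240116)
    for _ in range(50):
        m = _search_family(rng)
        if m is not None:
            m.setflags(write=False)
            return m
    raise RuntimeError("counterbalance search failed to converge")


def make_counterbalance(group_index: int) -> CounterbalanceList:
    """Assignment of the 8 games to joint rule conditions for one group."""
    if not 0 <= group_index < N_GROUPS:
        raise ValueError(f"group_index must be in [0, {N_GROUPS})")
    codes = counterbalance_family()[group_index]
    assignment = {
        g: RuleCondition(int(c) >> 1, int(c) & 1) for g, c in enumerate(codes)
    }
    return CounterbalanceList(group_index=group_index, assignment=assignment)


def family_balance_report() -> dict[str, np.ndarray]:
    """Brute-force tallies used to check counterbalance balance.

    Returns per-game condition occupancy (8x4) and the pair-sharing counts
    (one entry per unordered game pair) for the high and low rules.
    """
    fam = counterbalance_family()
    occupancy = np.array(
        [np.bincount(fam[:, g], minlength=4) for g in range(N_GAMES)]
    )
    shares = {}
    for name, bits in (("high", fam >> 1), ("low", fam & 1)):
        counts = [
            int(np.sum(bits[:, i] == bits[:, j]))
            for i, j in combinations(range(N_GAMES), 2)
        ]
        shares[name] = np.array(counts)
    return {
        "occupancy": occupancy,
        "share_high": shares["high"],
        "share_low": shares["low"],
    }


@dataclass(frozen=True)
class Trial:
    index: int  # 0-based position within the game
    location: int
    role: Role
    half: Half


@dataclass(frozen=True)
class TrialSequence:
    game: GameSpec
    trials: tuple[Trial, ...]

    @property
    def locations(self) -> np.ndarray:
        return np.array([t.location for t in self.trials])


def _half_for_index(i: int) -> Half:
    if i < BOUNDARY_CENTER_IDX[0]:
        return Half.FIRST
    if i in BOUNDARY_CENTER_IDX:
        return Half.BOUNDARY
    return Half.SECOND


def role_for_index(i: int) -> Role:
    if i in PREPAIR_CENTER_IDX:
        return Role.PREPAIR_CENTER
    if i in BOUNDARY_CENTER_IDX:
        return Role.BOUNDARY_CENTER
    if i in PAIR_FIRST_IDX:
        return Role.PAIR_FIRST
    return Role.PAIR_SECOND


def generate_game_sequence(
    game: GameSpec, rng: np.random.Generator
) -> TrialSequence:
    """One game's 27-trial stream.

    Each half presents its two ordered pairs twice each, in randomized
    order, as (pre-pair center, pair-first, pair-second) triplets; the
    halves are separated by three boundary-center trials.
    """
    layout = game.layout
    pairs = layout.pairs(game.condition.low_rule)
    trials: list[Trial] = []
    for half in (Half.FIRST, Half.SECOND):
        active = layout.half_set(game.condition.high_rule, half)
        half_pairs = [p for p in pairs if p[0] in active]
        assert len(half_pairs) == 2
        order = [half_pairs[0], half_pairs[0], half_pairs[1], half_pairs[1]]
        order = [order[k] for k in rng.permutation(4)]
        for first, second in order:
            base = len(trials)
            trials.append(Trial(base, 0, Role.PREPAIR_CENTER, half))
            trials.append(Trial(base + 1, first, Role.PAIR_FIRST, half))
            trials.append(Trial(base + 2, second, Role.PAIR_SECOND, half))
        if half == Half.FIRST:
            for k in BOUNDARY_CENTER_IDX:
                trials.append(Trial(k, 0, Role.BOUNDARY_CENTER, Half.BOUNDARY))
    trials.sort(key=lambda t: t.index)
    return TrialSequence(game=game, trials=tuple(trials))


@dataclass(frozen=True)
class ProbeSchedule:
    """Probe positions: (round_index, game_slot) -> tuple of trial indices."""

    probes: dict[tuple[int, int], tuple[int, ...]] = field(hash=False)

    def total(self) -> int:
        return sum(len(v) for v in self.probes.values())


def draw_probe_index(rng: np.random.Generator) -> int:
    """One probe position: the earliest peripheral trial with probability
    0.375, otherwise uniform over the remaining peripheral trial indices."""
    if rng.random() < EARLIEST_PROBE_FRACTION:
        return EARLIEST_PERIPHERAL_IDX
    others = [i for i in PERIPHERAL_IDX if i != EARLIEST_PERIPHERAL_IDX]
    return int(rng.choice(others))


def schedule_probes(
    n_rounds: int,
    rng: np.random.Generator,
    n_games: int = N_GAMES,
    final_round_probes: int = 3,
) -> ProbeSchedule:
    """Probe placement for a whole session.

    One probe per game per round; the final round carries
    ``final_round_probes`` distinct probes per game (the first drawn with
    the earliest-trial bias, the rest uniform over remaining peripheral
    positions).
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    probes: dict[tuple[int, int], tuple[int, ...]] = {}
    for r in range(n_rounds):
        n_probes = final_round_probes if r == n_rounds - 1 else 1
        for g in range(n_games):
            first = draw_probe_index(rng)
            chosen = [first]
            if n_probes > 1:
                remaining = [i for i in PERIPHERAL_IDX if i != first]
                extra = rng.choice(remaining, size=n_probes - 1, replace=False)
                chosen.extend(int(x) for x in extra)
            probes[(r, g)] = tuple(sorted(chosen))
    return ProbeSchedule(probes=probes)


def encode_sequence(sequence: TrialSequence) -> np.ndarray:
    """27x17 indicator input: 8 context units (game identity) + 9 location
    units, exactly two active per time step."""
    x = np.zeros((len(sequence.trials), N_INPUT_UNITS))
    x[:, sequence.game.game_id] = 1.0
    for t, trial in enumerate(sequence.trials):
        x[t, N_GAMES + trial.location] = 1.0
    return x


def decode_inputs(x: np.ndarray) -> tuple[int, np.ndarray]:
    """Inverse of :func:`encode_sequence`: (game_id, locations per trial)."""
    context = x[:, :N_GAMES]
    game_ids = np.argmax(context, axis=1)
    if not np.all(game_ids == game_ids[0]):
        raise ValueError("context units are not constant within the game")
    locations = np.argmax(x[:, N_GAMES:], axis=1)
    return int(game_ids[0]), locations


def encode_games(sequences: Sequence[TrialSequence]) -> np.ndarray:
    """Stack per-game encodings into a (n_games, 27, 17) batch."""
    return np.stack([encode_sequence(s) for s in sequences])


@dataclass(frozen=True)
class Participant:
    """One simulated participant: a shared layout, a counterbalance list,
    and the derived game specifications."""

    seed: int
    group_index: int
    layout: LocationLayout
    games: tuple[GameSpec, ...]

    @property
    def assignment(self) -> dict[int, RuleCondition]:
        return {g.game_id: g.condition for g in self.games}


def make_participant(
    seed: int, group_index: int | None = None
) -> Participant:
    """Deterministically realize one participant's materials.

    The layout is regenerated per participant (locations are counterbalanced
    across participants); the group index defaults to ``seed % 16``.
    """
    if group_index is None:
        group_index = seed % N_GROUPS
    layout = make_layout(seed)
    cb = make_counterbalance(group_index)
    games = tuple(cb.games(layout))
    return Participant(
        seed=seed, group_index=group_index, layout=layout, games=games
    )


def generate_round(
    participant: Participant,
    rng: np.random.Generator,
    shuffle_games: bool = True,
) -> list[TrialSequence]:
    """Fresh randomized sequences for one round of the 8 games."""
    order = list(range(N_GAMES))
    if shuffle_games:
        order = [int(i) for i in rng.permutation(N_GAMES)]
    return [
        generate_game_sequence(participant.games[g], rng) for g in order
    ]
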