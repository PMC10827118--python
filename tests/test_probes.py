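"""Probe evaluation and sensitivity indices."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mtsl import task
from mtsl.gru import init_params
from mtsl.probes import (
    NoiseSpec,
    evaluate_checkpoint,
    high_level_sensitivity,
    low_level_sensitivity,
    noise_sweep,
    predict_at_probe,
    probe_responses,
    sensitivities_from_responses,
)
from mtsl.task import Role


def make_response_frame(rows):
    base = {
        "role": Role.PAIR_SECOND.value,
        "is_earliest": False,
        "own_second": np.nan,
        "opposite_second": np.nan,
        "in_correct_set": False,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


class TestIndices:
    def test_low_level_arithmetic(self):
        # 6/10 own-rule, 2/10 opposite, 2/10 other -> 0.4
        rows = (
            [{"response": 1, "own_second": 1, "opposite_second": 2}] * 6
            + [{"response": 2, "own_second": 1, "opposite_second": 2}] * 2
            + [{"response": 3, "own_second": 1, "opposite_second": 2}] * 2
        )
        assert low_level_sensitivity(make_response_frame(rows)) == pytest.approx(0.4)

    def test_low_level_bounds(self):
        all_correct = make_response_frame(
            [{"response": 4, "own_second": 4, "opposite_second": 5}] * 10
        )
        assert low_level_sensitivity(all_correct) == 1.0
        with pytest.raises(ValueError):
            low_level_sensitivity(all_correct.iloc[0:0])

    def test_high_level_equals_two_p_minus_one(self):
        rows = [
            {"role": Role.PAIR_FIRST.value, "response": 1, "in_correct_set": k < 7}
            for k in range(10)
        ]
        df = make_response_frame(rows)
        assert high_level_sensitivity(df) == pytest.approx(2 * 0.7 - 1)

    def test_high_level_earliest_restriction(self):
        rows = [
            {"role": Role.PAIR_FIRST.value, "response": 1,
             "in_correct_set": True, "is_earliest": True},
            {"role": Role.PAIR_FIRST.value, "response": 1,
             "in_correct_set": False, "is_earliest": False},
        ]
        df = make_response_frame(rows)
        assert high_level_sensitivity(df, earliest_only=True) == 1.0
        assert high_level_sensitivity(df) == 0.0

    def test_relabeling_invariance(self, rng):
        # permuting peripheral labels consistently leaves indices unchanged
        perm = dict(zip(range(1, 9), rng.permutation(np.arange(1, 9))))
        rows = []
        for _ in range(50):
            own, opp, resp = rng.integers(1, 9, 3)
            rows.append(
                {"response": resp, "own_second": own, "opposite_second": opp}
            )
        df = make_response_frame(rows)
        mapped = df.copy()
        for col in ("response", "own_second", "opposite_second"):
            mapped[col] = mapped[col].map(perm)
        assert low_level_sensitivity(df) == low_level_sensitivity(mapped)


class TestReferenceAgents:
    """Random and rule-oracle agents bracket the learner at 0 and 1."""

    @staticmethod
    def simulate_agent(participant, n_rounds, rng, oracle):
        records = []
        schedule = task.schedule_probes(n_rounds, rng)
        for r in range(n_rounds):
            seqs = task.generate_round(participant, rng, shuffle_games=False)
            for g, seq in enumerate(seqs):
                for idx in schedule.probes[(r, g)]:
                    trial = seq.trials[idx]
                    game = seq.game
                    layout = game.layout
                    correct_set = layout.half_set(
                        game.condition.high_rule, trial.half
                    )
                    if oracle:
                        if trial.role is Role.PAIR_SECOND:
                            resp = layout.pair_dict(game.condition.low_rule)[
                                seq.trials[idx - 1].location
                            ]
                        else:
                            resp = int(rng.choice(sorted(correct_set)))
                    else:
                        resp = int(rng.integers(1, 9))
                    own = opp = np.nan
                    if trial.role is Role.PAIR_SECOND:
                        first = seq.trials[idx - 1].location
                        own = layout.pair_dict(game.condition.low_rule)[first]
                        opp = layout.pair_dict(1 - game.condition.low_rule)[first]
                    records.append(
                        {
                            "role": trial.role.value,
                            "is_earliest": idx == task.EARLIEST_PERIPHERAL_IDX,
                            "response": resp,
                            "own_second": own,
                            "opposite_second": opp,
                            "in_correct_set": resp in correct_set,
                        }
                    )
        return pd.DataFrame.from_records(records)

    def test_random_agent_at_chance(self, participant):
        rng = np.random.default_rng(10)
        df = self.simulate_agent(participant, 500, rng, oracle=False)
        res = sensitivities_from_responses(df)
        assert abs(res.low_level) < 0.05
        assert abs(res.high_level_all) < 0.05
        assert abs(res.high_level_earliest) < 0.05

    def test_oracle_agent_at_ceiling(self, participant):
        rng = np.random.default_rng(11)
        df = self.simulate_agent(participant, 80, rng, oracle=True)
        res = sensitivities_from_responses(df)
        assert res.low_level == 1.0
        assert res.high_level_all == 1.0
        assert res.high_level_earliest == 1.0


class TestPredictAtProbe:
    def test_zero_noise_deterministic(self, trained_instances):
        p, ckpts = trained_instances[0]
        rng = np.random.default_rng(3)
        seq = task.generate_game_sequence(p.games[0], rng)
        noise = NoiseSpec(sigma=0.0, n_injections=5)
        preds = {
            predict_at_probe(ckpts[240].params, seq, 2, noise,
                             np.random.default_rng(k))
            for k in range(5)
        }
        assert len(preds) == 1

    def test_center_probe_rejected(self, trained_instances):
        p, ckpts = trained_instances[0]
        rng = np.random.default_rng(3)
        seq = task.generate_game_sequence(p.games[0], rng)
        with pytest.raises(ValueError):
            predict_at_probe(ckpts[240].params, seq, 0, NoiseSpec(), rng)

    def test_huge_noise_near_uniform(self, participant):
        # an untrained network under sigma = 10 responds near-uniformly
        params = init_params(123)
        rng = np.random.default_rng(4)
        seq = task.generate_game_sequence(participant.games[0], rng)
        noise = NoiseSpec(sigma=10.0, n_injections=1)
        preds = [
            predict_at_probe(params, seq, 2, noise, rng) for _ in range(800)
        ]
        freqs = np.bincount(preds, minlength=9)[1:] / len(preds)
        assert freqs.max() < 0.30
        assert freqs.min() > 0.03

    def test_output_averaging_reduces_flips(self, trained_instances):
        # averaging outputs over 10 injections yields more stable choices
        # than a single injection
        p, ckpts = trained_instances[0]
        params = ckpts[240].params
        rng = np.random.default_rng(5)
        seq = task.generate_game_sequence(p.games[0], rng)

        def flip_rate(n_inj):
            preds = [
                predict_at_probe(
                    params, seq, 2, NoiseSpec(1.0, n_inj), rng, average="output"
                )
                for _ in range(200)
            ]
            return 1.0 - max(np.bincount(preds).max() / len(preds), 0)

        assert flip_rate(10) <= flip_rate(1)


class TestEvaluateCheckpoint:
    def test_untrained_at_chance(self, trained_instances):
        p, ckpts = trained_instances[0]
        rng = np.random.default_rng(6)
        res = evaluate_checkpoint(ckpts[0].params, p, 200, NoiseSpec(), rng)
        assert abs(res.low_level) < 0.05
        assert abs(res.high_level_all) < 0.05
        assert abs(res.high_level_earliest) < 0.05

    def test_matches_independent_tally(self, trained_instances):
        # recount the indices from the raw response log with plain loops
        p, ckpts = trained_instances[0]
        rng = np.random.default_rng(7)
        res, responses = evaluate_checkpoint(
            ckpts[240].params, p, 30, NoiseSpec(), rng, return_responses=True
        )
        n_own = n_opp = n_sec = 0
        n_corr = n_first = 0
        for _, row in responses.iterrows():
            if row["role"] == Role.PAIR_SECOND.value:
                n_sec += 1
                n_own += row["response"] == row["own_second"]
                n_opp += row["response"] == row["opposite_second"]
            else:
                n_first += 1
                n_corr += row["in_correct_set"]
        assert res.low_level == pytest.approx(n_own / n_sec - n_opp / n_sec)
        assert res.high_level_all == pytest.approx(2 * n_corr / n_first - 1)

    def test_choice_mode_one_row_per_injection(self, trained_instances):
        p, ckpts = trained_instances[0]
        rng = np.random.default_rng(8)
        df = probe_responses(
            ckpts[240].params, p, 5, NoiseSpec(n_injections=10), rng,
            average="choice",
        )
        assert len(df) == 5 * 8 * 10
        df_out = probe_responses(
            ckpts[240].params, p, 5, NoiseSpec(n_injections=10),
            np.random.default_rng(8), average="output",
        )
        assert len(df_out) == 5 * 8

    def test_learning_trend_nondecreasing(self, trained_instances):
        # sensitivity indices trend upward over training checkpoints
        rhos = []
        for p, ckpts in trained_instances:
            rounds = sorted(ckpts)
            lows, highs = [], []
            for rr in rounds:
                rng = np.random.default_rng(1000 + rr)
                res = evaluate_checkpoint(
                    ckpts[rr].params, p, 40, NoiseSpec(), rng
                )
                lows.append(res.low_level)
                highs.append(res.high_level_earliest)
            rhos.append(spearmanr(rounds, lows).statistic)
            rhos.append(spearmanr(rounds, highs).statistic)
        assert np.mean(rhos) > 0


def test_noise_sweep_degrades_with_noise(trained_instances):
    p, ckpts = trained_instances[0]
    rng = np.random.default_rng(9)
    table = noise_sweep(
        ckpts[240].params, p, rng, sigmas=(0.01, 10.0), n_eval_rounds=40
    )
    assert list(table["sigma"]) == [0.01, 10.0]
    assert table.loc[0, "low_level"] >= table.loc[1, "low_level"]
    assert (
        table.loc[0, "high_level_earliest"]
        >= table.loc[1, "high_level_earliest"]
    )
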