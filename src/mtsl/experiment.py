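"""End-to-end experiment driver.

Fans a master seed out to per-instance seeds, trains the 48 model
instances, and runs the three readouts — online-prediction sensitivity,
simulated similarity judgements, and representational trajectory analysis
— then aggregates cross-instance statistics in the format the individual
analyses report (mean, t, df, p).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import probes, representation, similarity, task
from .config import ExperimentConfig
from .gru import Checkpoint, TrainingConfig, train_participant
from .probes import NoiseSpec
from .stats import bootstrap_band, one_sample_t, paired_t
from .task import Participant


def instance_seed_sequences(
    master_seed: int, n_instances: int
) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(master_seed).spawn(n_instances)


@dataclass
class InstanceResult:
    instance: int
    participant: Participant
    checkpoints: dict[int, Checkpoint]
    sensitivity: pd.DataFrame  # one row per evaluated checkpoint round
    similarity_by_type: pd.Series  # mean accuracy per trial type
    warping: dict[int, float]  # rounds -> warping contrast
    trajectories: dict[int, np.ndarray] = field(default_factory=dict)


def run_instance(
    instance: int,
    seed_seq: np.random.SeedSequence,
    config: ExperimentConfig,
    eval_checkpoint_rounds: tuple[int, ...] | None = None,
    keep_trajectories: bool = False,
) -> InstanceResult:
    """Train and analyze a single model instance.

    Each instance is paired with its own simulated participant: a fresh
    location layout and the counterbalance list for group ``instance % 16``,
    so the 16 groups are used three times each across 48 instances.
    """
    seeds = seed_seq.generate_state(6) % (2**31)
    participant = task.make_participant(
        seed=int(seeds[0]), group_index=instance % task.N_GROUPS
    )
    tcfg = TrainingConfig(
        learning_rate=config.learning_rate,
        n_rounds=config.n_train_rounds,
        checkpoint_rounds=config.checkpoint_rounds,
        variant=config.variant,
        init_seed=int(seeds[1]),
    )
    checkpoints = {
        c.rounds_seen: c
        for c in train_participant(tcfg, participant, int(seeds[2]))
    }

    noise = NoiseSpec(sigma=config.sigma, n_injections=config.n_injections)
    eval_rng = np.random.default_rng(int(seeds[3]))
    rows = []
    for rounds in eval_checkpoint_rounds or (config.analysis_round,):
        res = probes.evaluate_checkpoint(
            checkpoints[rounds].params,
            participant,
            config.eval_rounds,
            noise,
            eval_rng,
            config.variant,
            rounds_seen=rounds,
            instance=instance,
            average=config.noise_average,
        )
        rows.append(
            {
                "instance": instance,
                "rounds": rounds,
                "low_level": res.low_level,
                "high_level_all": res.high_level_all,
                "high_level_earliest": res.high_level_earliest,
            }
        )
    sensitivity = pd.DataFrame(rows)

    sim_rng = np.random.default_rng(int(seeds[4]))
    analysis_params = checkpoints[config.analysis_round].params
    trials = similarity.generate_similarity_trials(
        participant.assignment, sim_rng
    )
    judgements = similarity.simulate_judgements(
        analysis_params,
        trials,
        sim_rng,
        n_samples=config.n_choice_samples,
        temperature=config.temperature,
        variant=config.variant,
    )
    by_type = similarity.accuracy_by_type(judgements)

    traj_rng = np.random.default_rng(int(seeds[5]))
    warping: dict[int, float] = {}
    trajectories: dict[int, np.ndarray] = {}
    for rounds in (config.early_round, config.analysis_round):
        tensor = representation.average_trajectories(
            checkpoints[rounds].params,
            participant,
            config.trajectory_rounds,
            traj_rng,
            config.variant,
        )
        warping[rounds] = representation.warping_statistic(
            tensor, participant.assignment
        )
        if keep_trajectories:
            trajectories[rounds] = tensor
    return InstanceResult(
        instance=instance,
        participant=participant,
        checkpoints=checkpoints,
        sensitivity=sensitivity,
        similarity_by_type=by_type,
        warping=warping,
        trajectories=trajectories,
    )


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    sensitivity: pd.DataFrame
    similarity: pd.DataFrame
    warping: pd.DataFrame
    summary: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sensitivity.to_csv(out / "sensitivity.csv", index=False)
        self.similarity.to_csv(out / "similarity.csv", index=False)
        self.warping.to_csv(out / "warping.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2)


def _test_entry(result) -> dict:
    return {
        "mean": result.estimate,
        "t": result.t,
        "df": result.df,
        "p": result.p,
        "ci": [result.ci_low, result.ci_high],
    }


def summarize(
    config: ExperimentConfig,
    sensitivity: pd.DataFrame,
    sim_table: pd.DataFrame,
    warping: pd.DataFrame,
) -> dict:
    """Cross-instance statistics at the analysis round."""
    at = sensitivity[sensitivity["rounds"] == config.analysis_round]
    summary: dict = {
        "n_instances": int(at["instance"].nunique()),
        "analysis_round": config.analysis_round,
        "low_level_sensitivity": _test_entry(one_sample_t(at["low_level"])),
        "high_level_sensitivity_earliest": _test_entry(
            one_sample_t(at["high_level_earliest"])
        ),
        "low_minus_high_sensitivity": _test_entry(
            paired_t(at["low_level"], at["high_level_earliest"])
        ),
    }
    for ttype in similarity.TRIAL_TYPES:
        col = sim_table[sim_table["trial_type"] == ttype]["accuracy"]
        null = 0.5
        summary[f"similarity_type_{ttype}"] = _test_entry(
            one_sample_t(col, null=null)
        )
    pivot = sim_table.pivot(
        index="instance", columns="trial_type", values="accuracy"
    )
    low_diag = pivot[list(similarity.LOW_DIAGNOSTIC)].mean(axis=1)
    high_diag = pivot[list(similarity.HIGH_DIAGNOSTIC)].mean(axis=1)
    summary["similarity_low_minus_high"] = _test_entry(
        paired_t(low_diag, high_diag)
    )
    for rounds, grp in warping.groupby("rounds"):
        summary[f"warping_round_{rounds}"] = _test_entry(
            one_sample_t(grp["warping"])
        )
    return summary


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
    eval_checkpoint_rounds: tuple[int, ...] | None = None,
    progress: bool = False,
) -> ExperimentReport:
    """Generate, train, and analyze every instance, then aggregate.

    Deterministic given ``config.master_seed``: two runs with the same
    configuration produce identical tables.
    """
    seqs = instance_seed_sequences(config.master_seed, config.n_instances)
    sens_rows, sim_rows, warp_rows = [], [], []
    for i, ss in enumerate(seqs):
        result = run_instance(i, ss, config, eval_checkpoint_rounds)
        sens_rows.append(result.sensitivity)
        for ttype, acc in result.similarity_by_type.items():
            sim_rows.append(
                {"instance": i, "trial_type": ttype, "accuracy": acc}
            )
        for rounds, value in result.warping.items():
            warp_rows.append(
                {"instance": i, "rounds": rounds, "warping": value}
            )
        if progress:
            print(f"instance {i + 1}/{config.n_instances} done")
    sensitivity = pd.concat(sens_rows, ignore_index=True)
    sim_table = pd.DataFrame(sim_rows)
    warping = pd.DataFrame(warp_rows)
    summary = summarize(config, sensitivity, sim_table, warping)
    report = ExperimentReport(
        config=config,
        sensitivity=sensitivity,
        similarity=sim_table,
        warping=warping,
        summary=summary,
    )
    if out_dir is not None:
        report.save(out_dir)
        write_figures(report, out_dir)
    return report


def write_figures(report: ExperimentReport, out_dir: str | Path) -> None:
    """Learning-curve and similarity figures (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    sens = report.sensitivity
    rounds = sorted(sens["rounds"].unique())
    if len(rounds) > 1:
        fig, ax = plt.subplots(figsize=(6, 4))
        for col, label in [
            ("low_level", "low-level"),
            ("high_level_earliest", "high-level (earliest probe)"),
        ]:
            mat = (
                sens.pivot(index="instance", columns="rounds", values=col)
                .loc[:, rounds]
                .to_numpy()
            )
            band = bootstrap_band(mat, n_boot=2000, seed=0)
            ax.plot(rounds, band["mean"], label=label)
            ax.fill_between(rounds, band["lower"], band["upper"], alpha=0.3)
        ax.axhline(0, color="gray", lw=0.5)
        ax.set_xlabel("rounds of training")
        ax.set_ylabel("sensitivity index")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "sensitivity_curve.png", dpi=150)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    order = [t for t in ("b", "c", "d", "e", "f", "g")]
    data = [
        report.similarity.loc[
            report.similarity["trial_type"] == t, "accuracy"
        ].to_numpy()
        for t in order
    ]
    ax.boxplot(data, tick_labels=order, showmeans=True)
    ax.axhline(0.5, color="gray", lw=0.5)
    ax.set_xlabel("similarity trial type")
    ax.set_ylabel("proportion correct / high-level choice (g)")
    fig.tight_layout()
    fig.savefig(out / "similarity_types.png", dpi=150)
    plt.close(fig)


def plot_trajectories(
    tensor: np.ndarray,
    condition_map,
    out_path: str | Path,
    seed: int = 0,
) -> np.ndarray:
    """2-D MDS trajectory plot of one aggregate (8, 27, H) tensor; returns
    the embedded coordinates (216 x 2, game-major)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rdm = representation.trajectory_rdm(tensor)
    coords = representation.mds_embed(rdm, seed=seed)
    n_trials = tensor.shape[1]
    fig, ax = plt.subplots(figsize=(5, 5))
    cmap = plt.get_cmap("tab10")
    for g in range(tensor.shape[0]):
        xy = coords[g * n_trials : (g + 1) * n_trials]
        cond = condition_map[g]
        ax.plot(
            xy[:, 0], xy[:, 1], color=cmap(g), lw=1.0,
            label=f"game {g} ({cond.label})",
        )
        ax.scatter(xy[-1, 0], xy[-1, 1], color=cmap(g), s=12)
    ax.legend(fontsize=6)
    ax.set_title("hidden-state trajectories (MDS)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return coords
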