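"""Experiment configuration, loadable from a YAML or JSON mapping."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class ExperimentConfig:
    """Study conditions for a full simulated experiment.

    Defaults follow the study design: 48 model instances, 240 rounds of
    training with analyses at the final checkpoint and an early comparison
    checkpoint at one fifth of that exposure, input noise sigma 1.0 with
    10 injections averaged at the choice level, 10 choice samples per
    similarity trial at softmax temperature 1.
    """

    n_instances: int = 48
    n_games: int = 8
    trials_per_game: int = 27
    n_train_rounds: int = 240
    checkpoint_rounds: tuple[int, ...] = (0, 48, 240)
    analysis_round: int = 240
    early_round: int = 48
    eval_rounds: int = 100
    trajectory_rounds: int = 50
    sigma: float = 1.0
    n_injections: int = 10
    noise_average: str = "choice"
    n_choice_samples: int = 10
    temperature: float = 1.0
    learning_rate: float = 0.001
    variant: str = "reset_before"
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.checkpoint_rounds = tuple(
            sorted(
                set(self.checkpoint_rounds)
                | {self.analysis_round, self.early_round}
            )
        )
        if self.analysis_round > self.n_train_rounds:
            raise ValueError("analysis_round exceeds n_train_rounds")

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text)
            if path.suffix == ".json"
            else yaml.safe_load(text)
        )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["checkpoint_rounds"] = list(self.checkpoint_rounds)
        return d
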