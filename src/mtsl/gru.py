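"""Gated recurrent learner trained on next-location prediction.

A single-hidden-layer GRU (17 inputs -> 150 gated recurrent units -> 9
linear outputs) trained with mean-squared error against the one-hot next
location, one RMSprop step per round-batch of 8 games.  Hidden activations
are reset between games (each game is an independent batch element).

The implementation is self-contained numpy with analytic backpropagation
through time; gradients are verified against central finite differences in
the test suite.  Both gate-application variants are available:
``reset_before`` (the reset gate multiplies the previous hidden state
before the recurrent matrix product) and ``reset_after``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

N_INPUT = 17
N_HIDDEN = 150
N_OUTPUT = 9

WEIGHT_NAMES = (
    "Wz", "Wr", "Wc", "Uz", "Ur", "Uc",
    "bz", "br", "bc", "bc_rec", "Wo", "bo",
)


def _sigmoid(a: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-a))


@dataclass
class GRUParams:
    """Weight container for the 17 -> 150 -> 9 network."""

    Wz: np.ndarray
    Wr: np.ndarray
    Wc: np.ndarray
    Uz: np.ndarray
    Ur: np.ndarray
    Uc: np.ndarray
    bz: np.ndarray
    br: np.ndarray
    bc: np.ndarray
    bc_rec: np.ndarray  # recurrent candidate bias, used by reset_after only
    Wo: np.ndarray
    bo: np.ndarray

    @property
    def n_hidden(self) -> int:
        return self.Wz.shape[1]

    @property
    def n_input(self) -> int:
        return self.Wz.shape[0]

    @property
    def n_output(self) -> int:
        return self.Wo.shape[1]

    def arrays(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in WEIGHT_NAMES}

    def copy(self) -> "GRUParams":
        return GRUParams(**{k: v.copy() for k, v in self.arrays().items()})

    def check_finite(self) -> None:
        for name, arr in self.arrays().items():
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"non-finite values in {name}")


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    """Orthogonal matrix from the QR decomposition of a random normal
    matrix, with the conventional sign fix for a uniform distribution."""
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def init_params(
    seed: int,
    n_input: int = N_INPUT,
    n_hidden: int = N_HIDDEN,
    n_output: int = N_OUTPUT,
) -> GRUParams:
    """Glorot-uniform feedforward weights, orthogonal recurrent weights,
    zero biases; deterministic given the seed."""
    rng = np.random.default_rng(seed)

    def glorot(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return GRUParams(
        Wz=glorot(n_input, n_hidden),
        Wr=glorot(n_input, n_hidden),
        Wc=glorot(n_input, n_hidden),
        Uz=_orthogonal(rng, n_hidden),
        Ur=_orthogonal(rng, n_hidden),
        Uc=_orthogonal(rng, n_hidden),
        bz=np.zeros(n_hidden),
        br=np.zeros(n_hidden),
        bc=np.zeros(n_hidden),
        bc_rec=np.zeros(n_hidden),
        Wo=glorot(n_hidden, n_output),
        bo=np.zeros(n_output),
    )


def gru_step(
    params: GRUParams,
    h_prev: np.ndarray,
    x: np.ndarray,
    variant: str = "reset_before",
) -> np.ndarray:
    """One recurrent update.  Accepts 1-D or (batch, dim) arrays."""
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(h_prev))):
        raise FloatingPointError("non-finite input to gru_step")
    z = _sigmoid(x @ params.Wz + h_prev @ params.Uz + params.bz)
    r = _sigmoid(x @ params.Wr + h_prev @ params.Ur + params.br)
    if variant == "reset_before":
        c = np.tanh(x @ params.Wc + (r * h_prev) @ params.Uc + params.bc)
    elif variant == "reset_after":
        c = np.tanh(
            x @ params.Wc + r * (h_prev @ params.Uc + params.bc_rec)
            + params.bc
        )
    else:
        raise ValueError(f"unknown gate variant: {variant}")
    return z * h_prev + (1.0 - z) * c


def readout(params: GRUParams, h: np.ndarray) -> np.ndarray:
    """Linear output layer: the next-location prediction vector."""
    return h @ params.Wo + params.bo


def forward_sequence(
    params: GRUParams,
    inputs: np.ndarray,
    variant: str = "reset_before",
    return_cache: bool = False,
):
    """Run one or more games from a zero hidden state.

    ``inputs`` is (T, n_input) or (batch, T, n_input); each batch element is
    an independent game (activations reset at every game start).  Returns
    hidden states and outputs per step, shaped like the input batch.
    """
    squeeze = inputs.ndim == 2
    x = inputs[None] if squeeze else inputs
    b, t, _ = x.shape
    h = np.zeros((b, params.n_hidden))
    hs = np.empty((b, t, params.n_hidden))
    cache = {"z": [], "r": [], "c": [], "h_prev": [], "s": []}
    for step in range(t):
        xt = x[:, step]
        z = _sigmoid(xt @ params.Wz + h @ params.Uz + params.bz)
        r = _sigmoid(xt @ params.Wr + h @ params.Ur + params.br)
        if variant == "reset_before":
            c = np.tanh(xt @ params.Wc + (r * h) @ params.Uc + params.bc)
            s = None
        else:
            s = h @ params.Uc + params.bc_rec
            c = np.tanh(xt @ params.Wc + r * s + params.bc)
        h_new = z * h + (1.0 - z) * c
        if return_cache:
            cache["z"].append(z)
            cache["r"].append(r)
            cache["c"].append(c)
            cache["h_prev"].append(h)
            cache["s"].append(s)
        h = h_new
        hs[:, step] = h
    ys = hs @ params.Wo + params.bo
    if squeeze:
        hs, ys = hs[0], ys[0]
    if return_cache:
        return hs, ys, cache
    return hs, ys


def targets_from_inputs(inputs: np.ndarray, n_context: int = 8) -> np.ndarray:
    """Next-location one-hot targets: the location block of the following
    trial.  The final trial of each game has no within-game successor and
    is excluded."""
    return inputs[..., 1:, n_context:]


def loss_and_grads(
    params: GRUParams,
    inputs: np.ndarray,
    targets: np.ndarray | None = None,
    variant: str = "reset_before",
) -> tuple[float, dict[str, np.ndarray]]:
    """MSE loss (mean over batch, timesteps, output units) and analytic
    gradients via backpropagation through time."""
    x = inputs[None] if inputs.ndim == 2 else inputs
    if targets is None:
        targets = targets_from_inputs(x)
    elif targets.ndim == 2:
        targets = targets[None]
    b, t, _ = x.shape
    hs, ys, cache = forward_sequence(params, x, variant, return_cache=True)
    t_loss = targets.shape[1]
    err = ys[:, :t_loss] - targets
    n_terms = err.size
    loss = float(np.sum(err**2) / n_terms)

    grads = {k: np.zeros_like(v) for k, v in params.arrays().items()}
    dys = np.zeros_like(ys)
    dys[:, :t_loss] = 2.0 * err / n_terms
    grads["Wo"] = np.einsum("bth,bto->ho", hs, dys)
    grads["bo"] = dys.sum(axis=(0, 1))
    dh_next = np.zeros((b, params.n_hidden))
    for step in range(t - 1, -1, -1):
        dh = dys[:, step] @ params.Wo.T + dh_next
        z = cache["z"][step]
        r = cache["r"][step]
        c = cache["c"][step]
        h_prev = cache["h_prev"][step]
        xt = x[:, step]
        dz = dh * (h_prev - c)
        dc = dh * (1.0 - z)
        dh_prev = dh * z
        da_c = dc * (1.0 - c**2)
        grads["Wc"] += xt.T @ da_c
        grads["bc"] += da_c.sum(axis=0)
        if variant == "reset_before":
            d_rh = da_c @ params.Uc.T
            grads["Uc"] += (r * h_prev).T @ da_c
            dr = d_rh * h_prev
            dh_prev += d_rh * r
        else:
            s = cache["s"][step]
            dr = da_c * s
            ds = da_c * r
            grads["Uc"] += h_prev.T @ ds
            grads["bc_rec"] += ds.sum(axis=0)
            dh_prev += ds @ params.Uc.T
        da_z = dz * z * (1.0 - z)
        da_r = dr * r * (1.0 - r)
        grads["Wz"] += xt.T @ da_z
        grads["Uz"] += h_prev.T @ da_z
        grads["bz"] += da_z.sum(axis=0)
        grads["Wr"] += xt.T @ da_r
        grads["Ur"] += h_prev.T @ da_r
        grads["br"] += da_r.sum(axis=0)
        dh_next = dh_prev + da_z @ params.Uz.T + da_r @ params.Ur.T
    return loss, grads


@dataclass
class RMSProp:
    """RMSprop with the common defaults (rho 0.9, epsilon 1e-7)."""

    learning_rate: float = 0.001
    rho: float = 0.9
    epsilon: float = 1e-7
    v: dict[str, np.ndarray] = field(default_factory=dict)

    def update(self, params: GRUParams, grads: dict[str, np.ndarray]) -> None:
        for name, g in grads.items():
            if name not in self.v:
                self.v[name] = np.zeros_like(g)
            v = self.v[name]
            v *= self.rho
            v += (1.0 - self.rho) * g**2
            getattr(params, name)[...] -= (
                self.learning_rate * g / (np.sqrt(v) + self.epsilon)
            )

    def copy(self) -> "RMSProp":
        return RMSProp(
            learning_rate=self.learning_rate,
            rho=self.rho,
            epsilon=self.epsilon,
            v={k: val.copy() for k, val in self.v.items()},
        )


@dataclass
class TrainingConfig:
    learning_rate: float = 0.001
    rho: float = 0.9
    epsilon: float = 1e-7
    n_rounds: int = 240
    checkpoint_rounds: tuple[int, ...] = (0, 8, 40, 240)
    variant: str = "reset_before"
    init_seed: int = 0


@dataclass
class Checkpoint:
    rounds_seen: int
    params: GRUParams
    optimizer: RMSProp
    losses: tuple[float, ...] = ()


def train(
    config: TrainingConfig,
    round_stream: Iterable[np.ndarray],
    params: GRUParams | None = None,
) -> list[Checkpoint]:
    """Train on a stream of round-batches.

    Each stream element is an (8, 27, 17) encoded round; one gradient step
    is taken per round on the MSE next-location loss.  Checkpoints (deep
    copies of weights and optimizer state) are captured at the configured
    round counts; round 0 is the untrained initialization.
    """
    if params is None:
        params = init_params(config.init_seed)
    opt = RMSProp(config.learning_rate, config.rho, config.epsilon)
    wanted = set(config.checkpoint_rounds)
    checkpoints: list[Checkpoint] = []
    losses: list[float] = []
    if 0 in wanted:
        checkpoints.append(Checkpoint(0, params.copy(), opt.copy(), ()))
    rounds_seen = 0
    for batch in round_stream:
        if rounds_seen >= config.n_rounds:
            break
        loss, grads = loss_and_grads(params, batch, variant=config.variant)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged at round {rounds_seen + 1}"
            )
        opt.update(params, grads)
        losses.append(loss)
        rounds_seen += 1
        if rounds_seen in wanted:
            checkpoints.append(
                Checkpoint(rounds_seen, params.copy(), opt.copy(),
                           tuple(losses))
            )
    return checkpoints


def train_participant(
    config: TrainingConfig,
    participant,
    stream_seed: int,
) -> list[Checkpoint]:
    """Train one model instance on its participant's randomized rounds."""
    from . import task

    rng = np.random.default_rng(stream_seed)

    def stream():
        for _ in range(config.n_rounds):
            seqs = task.generate_round(participant, rng)
            yield task.encode_games(seqs)

    return train(config, stream())
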