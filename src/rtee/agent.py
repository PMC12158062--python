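"""DQN agent over the discrete activity-intensity grid.

The Q-network is a fully connected feedforward net — five inputs
(weight, height, age, gender, heart rate), two hidden layers of 64
rectified-linear units, and 201 linear outputs, one per grid
coefficient.  Training uses experience replay (FIFO, capacity 50,000),
an Adam optimizer at learning rate 1e-4, discount 0.95, epsilon-greedy
exploration with a linear decay, and a periodically synced target
network.

The network, optimizer and replay buffer are implemented directly on
numpy so that inference and training carry no deep-learning framework
dependency; the checkpoint format is a flat-array archive readable with
numpy alone.

Inputs are z-scored by a scaler fit on the training states; the
environment always hands out raw states and the agent owns the scaler.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .env import ActionGrid, EnvironmentWindow, make_windows, reward
from .formulas import rmr_per_second
from .synth import SessionRecord

__all__ = [
    "QNetworkSpec",
    "TrainingConfig",
    "QNetwork",
    "ReplayBuffer",
    "StateScaler",
    "DQNAgent",
    "select_action",
    "td_update",
    "train",
    "predict_ee_series",
]


@dataclass(frozen=True)
class QNetworkSpec:
    input_dim: int = 5
    hidden: tuple[int, ...] = (64, 64)
    output_dim: int = 201


@dataclass
class TrainingConfig:
    """Hyperparameters; defaults follow the reference configuration
    (Adam, lr 1e-4, discount 0.95, replay capacity 50,000)."""

    learning_rate: float = 1e-4
    lr_final_frac: float = 1.0  # linear lr decay to lr * frac over training (1 = constant)
    gamma: float = 0.95
    replay_capacity: int = 50_000
    epochs: int = 35
    batch_size: int = 64
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay_frac: float = 0.5  # fraction of env steps over which eps decays
    target_sync_interval: int = 1_000  # gradient steps between target syncs
    warmup_transitions: int = 1_000
    update_every: int = 4  # env steps per gradient step
    window_length_s: int = 300
    train_stride_s: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError(f"gamma must be in (0, 1), got {self.gamma}")
        if self.replay_capacity <= self.batch_size:
            raise ValueError("replay_capacity must exceed batch_size")
        for eps in (self.epsilon_start, self.epsilon_end):
            if not 0.0 <= eps <= 1.0:
                raise ValueError(f"epsilon must be in [0, 1], got {eps}")


class StateScaler:
    """Per-feature z-scoring with training-set statistics."""

    def __init__(self, mean: np.ndarray, std: np.ndarray):
        self.mean = np.asarray(mean, dtype=float)
        self.std = np.where(np.asarray(std, dtype=float) > 0, std, 1.0)

    @classmethod
    def fit(cls, states: np.ndarray) -> "StateScaler":
        states = np.asarray(states, dtype=float)
        return cls(states.mean(axis=0), states.std(axis=0))

    @classmethod
    def identity(cls, dim: int) -> "StateScaler":
        return cls(np.zeros(dim), np.ones(dim))

    def transform(self, states: np.ndarray) -> np.ndarray:
        return (np.asarray(states, dtype=float) - self.mean) / self.std


class QNetwork:
    """Feedforward ReLU network with a built-in Adam optimizer."""

    def __init__(self, spec: QNetworkSpec, rng: np.random.Generator, learning_rate: float = 1e-4):
        self.spec = spec
        self.lr = learning_rate
        dims = [spec.input_dim, *spec.hidden, spec.output_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init for ReLU layers
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._adam_t = 0
        self._adam_m = [np.zeros_like(p) for p in self._params()]
        self._adam_v = [np.zeros_like(p) for p in self._params()]

    def _params(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Q-values for a batch of standardized states, shape (n, 201)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.spec.input_dim:
            raise ValueError(f"expected input dim {self.spec.input_dim}, got {x.shape[1]}")
        h = x
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return h @ self.weights[-1] + self.biases[-1]

    def _forward_cached(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [x]
        h = x
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        return h @ self.weights[-1] + self.biases[-1], acts

    def sgd_step(self, x: np.ndarray, actions: np.ndarray, targets: np.ndarray) -> float:
        """One Adam step on the mean-squared TD error of the chosen actions."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = len(x)
        q, acts = self._forward_cached(x)
        q_sel = q[np.arange(n), actions]
        residual = q_sel - targets
        loss = float(np.mean(residual**2))

        dq = np.zeros_like(q)
        dq[np.arange(n), actions] = 2.0 * residual / n
        grads_w: list[np.ndarray] = [None] * len(self.weights)  # type: ignore[list-item]
        grads_b: list[np.ndarray] = [None] * len(self.biases)  # type: ignore[list-item]
        delta = dq
        for layer in range(len(self.weights) - 1, -1, -1):
            grads_w[layer] = acts[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (acts[layer] > 0)
        self._adam([*grads_w, *grads_b])
        return loss

    def _adam(self, grads: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for p, g, m, v in zip(self._params(), grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g**2
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + eps)

    def copy_from(self, other: "QNetwork") -> None:
        for dst, src in zip(self._params(), other._params()):
            dst[...] = src

    def clone(self) -> "QNetwork":
        twin = QNetwork(self.spec, np.random.default_rng(0), self.lr)
        twin.copy_from(self)
        return twin


class ReplayBuffer:
    """Bounded FIFO of transitions with uniform batch sampling
    (without replacement within a batch)."""

    def __init__(self, capacity: int, state_dim: int = 5):
        if capacity <= 0:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self.states = np.empty((capacity, state_dim))
        self.actions = np.empty(capacity, dtype=np.int64)
        self.rewards = np.empty(capacity)
        self.next_states = np.empty((capacity, state_dim))
        self.dones = np.empty(capacity, dtype=bool)
        self._next = 0
        self._size = 0

    def __len__(self) -> int:
        return self._size

    def push(self, state, action, reward_value, next_state, done) -> None:
        i = self._next
        self.states[i] = state
        self.actions[i] = action
        self.rewards[i] = reward_value
        self.next_states[i] = next_state
        self.dones[i] = done
        self._next = (i + 1) % self.capacity
        self._size = min(self._size + 1, self.capacity)

    def push_batch(self, states, actions, rewards, next_states, dones) -> None:
        for row in zip(states, actions, rewards, next_states, dones):
            self.push(*row)

    def sample(self, batch_size: int, rng: np.random.Generator):
        if batch_size > self._size:
            raise ValueError(f"cannot sample {batch_size} from buffer of size {self._size}")
        idx = rng.choice(self._size, size=batch_size, replace=False)
        return (
            self.states[idx],
            self.actions[idx],
            self.rewards[idx],
            self.next_states[idx],
            self.dones[idx],
        )


class DQNAgent:
    """Greedy/epsilon-greedy policy over the action grid, backed by a
    Q-network and its target copy."""

    def __init__(
        self,
        config: Optional[TrainingConfig] = None,
        spec: Optional[QNetworkSpec] = None,
        scaler: Optional[StateScaler] = None,
    ):
        self.config = config or TrainingConfig()
        self.spec = spec or QNetworkSpec()
        self.rng = np.random.default_rng(self.config.seed)
        self.network = QNetwork(self.spec, self.rng, self.config.learning_rate)
        self.target_network = self.network.clone()
        self.scaler = scaler or StateScaler.identity(self.spec.input_dim)
        self.grid = ActionGrid()

    # -- policy ----------------------------------------------------------

    def q_values(self, state: np.ndarray) -> np.ndarray:
        """Q-values for one raw state; output length equals the grid size."""
        return self.network.forward(self.scaler.transform(np.atleast_2d(state)))[0]

    def greedy_actions(self, raw_states: np.ndarray) -> np.ndarray:
        """Lowest-index argmax of the Q-values, batched over raw states."""
        q = self.network.forward(self.scaler.transform(np.atleast_2d(raw_states)))
        return np.argmax(q, axis=1)  # np.argmax takes the first maximum

    def select_action(
        self, state: np.ndarray, epsilon: float, rng: Optional[np.random.Generator] = None
    ) -> int:
        return select_action(self, state, epsilon, rng if rng is not None else self.rng)

    def predict_actions(self, session: SessionRecord) -> np.ndarray:
        """Causal per-second greedy action indices for a whole session."""
        states = np.empty((len(session), self.spec.input_dim))
        p = session.profile
        states[:, 0], states[:, 1] = p.weight, p.height
        states[:, 2], states[:, 3] = p.age, p.gender_flag
        states[:, 4] = session.hr
        return self.greedy_actions(states)

    def predict_ee_series(self, session: SessionRecord) -> np.ndarray:
        """Per-second predicted EE in kcal/s: ``rmr_sec * (1 + a_t)``."""
        actions = self.predict_actions(session)
        rmr_sec = rmr_per_second(session.profile).value
        return rmr_sec * (1.0 + self.grid.coefficients[actions])

    # -- persistence -----------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        """Portable checkpoint: architecture, flat parameter arrays,
        scaler statistics, config and seed in one numpy archive."""
        arrays = {f"W{i}": w for i, w in enumerate(self.network.weights)}
        arrays |= {f"b{i}": b for i, b in enumerate(self.network.biases)}
        arrays["scaler_mean"] = self.scaler.mean
        arrays["scaler_std"] = self.scaler.std
        meta = {"spec": asdict(self.spec), "config": asdict(self.config)}
        arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "DQNAgent":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"]).decode())
            spec = QNetworkSpec(
                input_dim=meta["spec"]["input_dim"],
                hidden=tuple(meta["spec"]["hidden"]),
                output_dim=meta["spec"]["output_dim"],
            )
            config = TrainingConfig(**meta["config"])
            agent = cls(config=config, spec=spec)
            agent.scaler = StateScaler(data["scaler_mean"], data["scaler_std"])
            for i in range(len(agent.network.weights)):
                agent.network.weights[i][...] = data[f"W{i}"]
                agent.network.biases[i][...] = data[f"b{i}"]
            agent.target_network.copy_from(agent.network)
        return agent


def select_action(
    agent: DQNAgent, state: np.ndarray, epsilon: float, rng: np.random.Generator
) -> int:
    """Epsilon-greedy: uniform over the grid with probability epsilon,
    otherwise the greedy (lowest-index tie-break) action."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    if epsilon > 0 and rng.random() < epsilon:
        return int(rng.integers(0, agent.grid.n_actions))
    return int(agent.greedy_actions(np.atleast_2d(state))[0])


def td_update(
    network: QNetwork,
    target_network: QNetwork,
    batch: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    gamma: float,
) -> float:
    """One gradient step of Q(s, a) toward r + gamma * max_a' Q_target(s', a').

    Terminal transitions regress toward the reward alone.  Returns the
    mean-squared TD error of the batch (before the step).
    """
    states, actions, rewards, next_states, dones = batch
    next_q = target_network.forward(next_states).max(axis=1)
    targets = rewards + gamma * next_q * (~np.asarray(dones, dtype=bool))
    return network.sgd_step(states, np.asarray(actions, dtype=np.int64), targets)


def _collect_states(sessions: Sequence[SessionRecord]) -> np.ndarray:
    blocks = []
    for s in sessions:
        block = np.empty((len(s), 5))
        block[:, 0], block[:, 1] = s.profile.weight, s.profile.height
        block[:, 2], block[:, 3] = s.profile.age, s.profile.gender_flag
        block[:, 4] = s.hr
        blocks.append(block)
    return np.concatenate(blocks)


def train(
    sessions: Sequence[SessionRecord],
    config: Optional[TrainingConfig] = None,
    progress: bool = False,
) -> tuple[DQNAgent, list[float]]:
    """Train an agent over sliding windows of the given sessions.

    Each epoch sweeps every window (at ``train_stride_s``) of every
    session.  Within a window the agent acts epsilon-greedily at every
    second; transitions go to the replay buffer and, after warm-up, one
    TD update runs every ``update_every`` env steps, with the target
    network synced every ``target_sync_interval`` gradient steps.

    Returns the trained agent and the mean TD loss per epoch.  Fully
    reproducible under ``config.seed``.
    """
    if not sessions:
        raise ValueError("at least one training session is required")
    config = config or TrainingConfig()
    for s in sessions:
        if s.gt_ee is None:
            raise ValueError("training sessions must carry VO2-derived ground-truth EE")

    agent = DQNAgent(config=config)
    agent.scaler = StateScaler.fit(_collect_states(sessions))
    rng = agent.rng
    buffer = ReplayBuffer(config.replay_capacity, state_dim=agent.spec.input_dim)
    grid_coeffs = agent.grid.coefficients

    windows_per_session = [
        make_windows(s, config.window_length_s, config.train_stride_s) for s in sessions
    ]
    steps_per_epoch = sum(len(w) for w in windows_per_session) * config.window_length_s
    total_steps = max(config.epochs * steps_per_epoch, 1)
    decay_steps = max(int(config.epsilon_decay_frac * total_steps), 1)

    # approximate total gradient steps, for the lr decay schedule
    total_grad_steps = max(total_steps // config.update_every, 1)

    loss_history: list[float] = []
    env_step = 0
    grad_step = 0
    for epoch in range(config.epochs):
        epoch_losses: list[float] = []
        for windows in windows_per_session:
            for window in windows:
                L = window.length
                raw_states = window.states()
                std_states = agent.scaler.transform(raw_states)
                greedy = np.argmax(agent.network.forward(std_states), axis=1)

                frac = np.clip((env_step + np.arange(L)) / decay_steps, 0.0, 1.0)
                eps = config.epsilon_start + frac * (config.epsilon_end - config.epsilon_start)
                explore = rng.random(L) < eps
                actions = np.where(explore, rng.integers(0, len(grid_coeffs), L), greedy)

                preds = window.rmr_sec * (1.0 + grid_coeffs[actions])
                rewards = reward(window.gt_ee, preds)
                next_idx = np.minimum(np.arange(1, L + 1), L - 1)
                dones = np.zeros(L, dtype=bool)
                dones[-1] = True
                buffer.push_batch(raw_states, actions, rewards, raw_states[next_idx], dones)
                env_step += L

                if len(buffer) >= max(config.warmup_transitions, config.batch_size):
                    n_updates = L // config.update_every
                    for _ in range(n_updates):
                        if config.lr_final_frac < 1.0:
                            progress = min(grad_step / total_grad_steps, 1.0)
                            agent.network.lr = config.learning_rate * (
                                1.0 - (1.0 - config.lr_final_frac) * progress
                            )
                        s, a, r, s2, d = buffer.sample(config.batch_size, rng)
                        batch = (
                            agent.scaler.transform(s),
                            a,
                            r,
                            agent.scaler.transform(s2),
                            d,
                        )
                        loss = td_update(
                            agent.network, agent.target_network, batch, config.gamma
                        )
                        epoch_losses.append(loss)
                        grad_step += 1
                        if grad_step % config.target_sync_interval == 0:
                            agent.target_network.copy_from(agent.network)
        loss_history.append(float(np.mean(epoch_losses)) if epoch_losses else float("nan"))
        if progress:
            print(f"epoch {epoch + 1}/{config.epochs}: mean TD loss {loss_history[-1]:.3e}")
    return agent, loss_history


def predict_ee_series(agent: DQNAgent, session: SessionRecord) -> np.ndarray:
    """Module-level convenience wrapper around
    :meth:`DQNAgent.predict_ee_series`."""
    return agent.predict_ee_series(session)
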