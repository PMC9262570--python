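"""Deep Q-learning on the imbalanced-classification MDP.

The agent rolls out episodes of the classification environment with an
epsilon-greedy policy, stores (s, a, r, s', end) transitions in a bounded
replay memory, and after every environment step (once the memory holds a
full batch) performs one stochastic-gradient descent step on the squared
temporal-difference loss

    L(theta_k) = sum_{(s,a,r,s') in B} (y - Q(s, a; theta_k))^2,
    y = r                                    if the transition is terminal,
        r + gamma max_a' Q(s', a'; theta_{k-1})  otherwise,

where theta_{k-1} is a snapshot of the weights taken before the update
(a one-step-lagged target network; the snapshot cadence is configurable).
Setting epsilon to zero recovers a purely greedy policy.

Training starts from a supplied weight vector -- typically the best food
source found by the bee-colony pretrainer -- and optionally early-stops
on a validation F-measure, returning the best-scoring checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .env import ClassificationEnv, LabeledImageSet, RewardSpec, Transition
from .exceptions import ConfigurationError, DimensionMismatchError, InputError
from .network import NetworkArchitecture, QNetwork, WeightVector

__all__ = [
    "ReplayMemory",
    "TrainConfig",
    "TrainResult",
    "select_action",
    "td_target",
    "td_targets",
    "td_loss",
    "gradient_update",
    "train",
    "predict",
]


class ReplayMemory:
    """Bounded FIFO buffer of transitions, sampled uniformly."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ConfigurationError("replay capacity must be >= 1")
        self.capacity = capacity
        self._buffer: list[Transition] = []
        self._head = 0  # ring-buffer write position once full

    def push(self, tr: Transition) -> None:
        if len(self._buffer) < self.capacity:
            self._buffer.append(tr)
        else:
            self._buffer[self._head] = tr
            self._head = (self._head + 1) % self.capacity

    def sample(self, batch_size: int, rng: np.random.Generator) -> list[Transition]:
        if not self._buffer:
            raise InputError("cannot sample from an empty replay memory")
        idx = rng.integers(len(self._buffer), size=batch_size)
        return [self._buffer[i] for i in idx]

    def __len__(self) -> int:
        return len(self._buffer)


@dataclass
class TrainConfig:
    """Q-learning hyper-parameters.

    Defaults follow the full-scale training recipe (18,000 episodes,
    batch 64); tests and examples override ``episodes`` and the network
    size downward.  ``epsilon_decay`` is applied multiplicatively per
    episode; ``target_sync`` = 1 means every update's targets come from
    the weights as they stood immediately before that update.
    """

    episodes: int = 18_000
    gamma: float = 0.9
    batch_size: int = 64
    learning_rate: float = 1e-4
    epsilon_start: float = 1.0
    epsilon_min: float = 0.01
    epsilon_decay: float = 0.995
    memory_capacity: int = 50_000
    target_sync: int = 1
    eval_every: int = 50          # episodes between validation evaluations
    patience: int = 20            # non-improving evaluations before stopping
    seed: int = 0

    def validate(self) -> None:
        if self.episodes < 0:
            raise ConfigurationError("episodes must be >= 0")
        if not 0.0 < self.gamma <= 1.0:
            raise ConfigurationError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")


def select_action(q_values, epsilon: float, rng: np.random.Generator) -> int:
    """Epsilon-greedy choice between the two action values (tie -> 0)."""
    q = np.asarray(q_values, dtype=np.float64).ravel()
    if not np.all(np.isfinite(q)):
        raise InputError("non-finite action values")
    if epsilon > 0.0 and rng.random() < epsilon:
        return int(rng.integers(q.size))
    return int(np.argmax(q))  # argmax returns the first maximum: tie -> 0


def td_target(tr: Transition, prev_net: QNetwork, gamma: float,
              data: LabeledImageSet) -> float:
    """Regression target: r if terminal, else r + gamma max_a' Q(s'; prev)."""
    if tr.end:
        return float(tr.reward)
    if tr.next_state is None:
        raise InputError("non-terminal transition without a next state")
    q_next = prev_net.forward(data.images[tr.next_state][None], training=False)
    return float(tr.reward + gamma * np.max(q_next))


def td_targets(batch: list[Transition], prev_net: QNetwork, gamma: float,
               data: LabeledImageSet) -> np.ndarray:
    """Vectorized targets for a batch (equal elementwise to td_target)."""
    y = np.array([tr.reward for tr in batch], dtype=np.float64)
    open_idx = [i for i, tr in enumerate(batch) if not tr.end]
    if open_idx:
        for tr in (batch[i] for i in open_idx):
            if tr.next_state is None:
                raise InputError("non-terminal transition without a next state")
        nxt = np.array([batch[i].next_state for i in open_idx])
        q_next = prev_net.forward(data.images[nxt], training=False)
        y[open_idx] += gamma * q_next.max(axis=1)
    return y


def td_loss(batch: list[Transition], net: QNetwork, prev_net: QNetwork,
            gamma: float, data: LabeledImageSet) -> float:
    """Sum of squared TD residuals over the batch (evaluation mode)."""
    if not batch:
        raise InputError("empty batch")
    y = td_targets(batch, prev_net, gamma, data)
    states = np.array([tr.state for tr in batch])
    actions = np.array([tr.action for tr in batch])
    q = net.forward(data.images[states], training=False)
    qa = q[np.arange(len(batch)), actions]
    return float(np.sum((y - qa) ** 2))


def gradient_update(net: QNetwork, batch: list[Transition], prev_net: QNetwork,
                    gamma: float, learning_rate: float,
                    data: LabeledImageSet, rng=None,
                    training: bool = True) -> tuple[float, float]:
    """One descent step on the squared TD loss; targets held fixed.

    Mutates ``net`` in place and returns the (pre, post) loss pair
    evaluated without dropout.  ``learning_rate`` 0 leaves the weights
    unchanged.
    """
    if not batch:
        raise InputError("empty batch")
    y = td_targets(batch, prev_net, gamma, data)
    states = np.array([tr.state for tr in batch])
    actions = np.array([tr.action for tr in batch])
    images = data.images[states]
    pre = td_loss(batch, net, prev_net, gamma, data)
    _, grads = net.loss_and_grads(images, actions, y, training=training, rng=rng)
    for name, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in {name}")
        net.params[name] -= learning_rate * g
    post = td_loss(batch, net, prev_net, gamma, data)
    return pre, post


@dataclass
class TrainResult:
    network: QNetwork                 # best (or final) checkpoint
    log: pd.DataFrame                 # per-episode length / return / loss
    best_val_f_measure: Optional[float]
    episodes_run: int
    stopped_early: bool


def predict(net: QNetwork, images) -> np.ndarray:
    """Greedy labels: per-image argmax of the action values (tie -> 0)."""
    q = net.forward(images, training=False)
    return np.argmax(q, axis=1)


def _f_measure(y_true, y_pred) -> float:
    # minority class (label 0) is the positive class
    tp = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 1) & (y_pred == 0)))
    fn = int(np.sum((y_true == 0) & (y_pred == 1)))
    if tp == 0:
        return 0.0
    r = tp / (tp + fn)
    p = tp / (tp + fp)
    return 2 * r * p / (r + p)


def train(data: LabeledImageSet, init, cfg: TrainConfig,
          arch: Optional[NetworkArchitecture] = None,
          reward_spec: RewardSpec = RewardSpec(),
          val_data: Optional[LabeledImageSet] = None) -> TrainResult:
    """Full Q-learning loop.

    ``init`` may be a :class:`QNetwork`, a :class:`WeightVector`, a flat
    array (with ``arch``), or None to start from seeded uniform weights.
    If ``val_data`` is given, the validation F-measure is evaluated every
    ``cfg.eval_every`` episodes, training stops after ``cfg.patience``
    non-improving evaluations, and the best-scoring checkpoint is
    returned; otherwise the final weights are.
    """
    cfg.validate()
    if isinstance(init, QNetwork):
        net = init.copy()
    elif init is None:
        if arch is None:
            raise ConfigurationError("arch required when init is None")
        net = QNetwork.build(arch, cfg.seed)
    else:
        if arch is None:
            raise ConfigurationError("arch required for a raw weight vector")
        net = QNetwork.from_vector(init, arch)

    rng = np.random.default_rng(cfg.seed)
    env = ClassificationEnv(data, reward_spec)
    memory = ReplayMemory(cfg.memory_capacity)
    target_net = net.copy()
    updates = 0
    epsilon = cfg.epsilon_start

    best_net = net.copy()
    best_f: Optional[float] = None
    stale = 0
    stopped_early = False

    rows = []
    episodes_run = 0
    for episode in range(cfg.episodes):
        state_img = env.reset(rng)
        ep_rewards: list[float] = []
        ep_losses: list[float] = []
        done = False
        while not done:
            q = net.forward(state_img[None], training=False)[0]
            action = select_action(q, epsilon, rng)
            tr = env.step(action)
            memory.push(tr)
            done = tr.end
            if not done:
                state_img = data.images[tr.next_state]
            ep_rewards.append(tr.reward)

            if len(memory) >= cfg.batch_size:
                if updates % cfg.target_sync == 0:
                    target_net = net.copy()
                batch = memory.sample(cfg.batch_size, rng)
                _, post = gradient_update(
                    net, batch, target_net, cfg.gamma, cfg.learning_rate,
                    data, rng=rng,
                )
                ep_losses.append(post)
                updates += 1

        epsilon = max(cfg.epsilon_min, epsilon * cfg.epsilon_decay)
        episodes_run = episode + 1
        row = {
            "episode": episode,
            "length": len(ep_rewards),
            "return": float(np.sum(ep_rewards)),
            "loss": float(np.mean(ep_losses)) if ep_losses else np.nan,
            "epsilon": epsilon,
            "val_f_measure": np.nan,
        }

        if val_data is not None and (episode + 1) % cfg.eval_every == 0:
            f = _f_measure(val_data.labels, predict(net, val_data.images))
            row["val_f_measure"] = f
            if best_f is None or f > best_f:
                best_f, best_net, stale = f, net.copy(), 0
            else:
                stale += 1
            if stale >= cfg.patience:
                rows.append(row)
                stopped_early = True
                break
        rows.append(row)

    log = pd.DataFrame(
        rows,
        columns=["episode", "length", "return", "loss", "epsilon", "val_f_measure"],
    )
    final = best_net if (val_data is not None and best_f is not None) else net
    return TrainResult(
        network=final,
        log=log,
        best_val_f_measure=best_f,
        episodes_run=episodes_run,
        stopped_early=stopped_early,
    )
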