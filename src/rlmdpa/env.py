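"""Imbalanced-classification Markov decision process (ICMDP).

Binary image classification is recast as a sequential game: each episode
shuffles the training set, serves one image (the state) at a time, and the
agent's action is the predicted label.  Rewards are class-asymmetric --
+-1 on the minority class and +-lambda (lambda in [0, 1]) on the majority
class -- and an episode terminates either when the data are exhausted or
immediately upon the first misclassified minority sample.  The short
episodes this induces under a poor policy concentrate learning signal on
the minority class.

Label convention: after loading, label 0 is always the minority class
(clinically, the healthy controls D_H) and label 1 the majority class
(the diseased images D_S).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import ConfigurationError, DataError, EpisodeStateError, InputError

__all__ = [
    "LabeledImageSet",
    "RewardSpec",
    "Transition",
    "ClassificationEnv",
    "identify_minority",
    "reward",
    "episode_return",
]


def identify_minority(labels) -> tuple[int, int, dict[int, int]]:
    """Return (minority_label, majority_label, remap) for raw 0/1 labels.

    The remap sends the minority label to 0 and the majority to 1; ties in
    class size are broken toward label 0 being the minority.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise DataError(f"expected exactly two classes, found {list(classes)}")
    c0, c1 = int(classes[0]), int(classes[1])
    n0, n1 = int(counts[0]), int(counts[1])
    if n0 <= n1:  # tie -> label 0 is minority
        minority, majority = c0, c1
    else:
        minority, majority = c1, c0
    return minority, majority, {minority: 0, majority: 1}


@dataclass
class LabeledImageSet:
    """Images with binary labels, minority class remapped to 0.

    ``images`` is (N, H, W) with intensities in [0, 1]; ``labels`` is (N,)
    over {0, 1} with 0 = minority.  ``original_minority_label`` records
    which raw label became 0.
    """

    images: np.ndarray
    labels: np.ndarray
    original_minority_label: int = 0

    @classmethod
    def from_arrays(cls, images, labels) -> "LabeledImageSet":
        images = np.asarray(images, dtype=np.float64)
        labels = np.asarray(labels)
        if images.ndim != 3:
            raise InputError(f"images must be (N, H, W), got ndim={images.ndim}")
        if images.shape[0] != labels.shape[0]:
            raise InputError("images and labels disagree in length")
        minority, _, remap = identify_minority(labels)
        remapped = np.array([remap[int(l)] for l in labels], dtype=np.int64)
        return cls(images=images, labels=remapped, original_minority_label=minority)

    def __len__(self) -> int:
        return int(self.images.shape[0])

    @property
    def n_minority(self) -> int:
        return int(np.sum(self.labels == 0))

    @property
    def n_majority(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def imbalance_ratio(self) -> float:
        return self.n_minority / self.n_majority

    def subset(self, idx) -> "LabeledImageSet":
        idx = np.asarray(idx)
        return LabeledImageSet(
            images=self.images[idx],
            labels=self.labels[idx],
            original_minority_label=self.original_minority_label,
        )


@dataclass(frozen=True)
class RewardSpec:
    """Majority-class reward magnitude lambda in [0, 1]."""

    lam: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ConfigurationError(f"lambda must be in [0, 1], got {self.lam}")


def reward(action: int, label: int, spec: RewardSpec) -> float:
    """Class-asymmetric reward.

    +1 / -1 for a correct / wrong minority-class (label 0) decision;
    +lambda / -lambda for the majority class.
    """
    if action not in (0, 1):
        raise InputError(f"action must be 0 or 1, got {action}")
    magnitude = 1.0 if label == 0 else spec.lam
    return magnitude if action == label else -magnitude


@dataclass
class Transition:
    """One (s, a, r, s', end) experience-replay tuple, states as indices."""

    state: int
    action: int
    reward: float
    next_state: Optional[int]
    end: bool


class ClassificationEnv:
    """Episode server over a :class:`LabeledImageSet`.

    ``reset`` draws a fresh permutation of the data; ``step`` scores one
    action and advances.  An episode ends when every sample has been
    classified or a minority sample is misclassified.
    """

    def __init__(self, data: LabeledImageSet, spec: RewardSpec = RewardSpec()):
        if len(data) == 0:
            raise DataError("empty dataset")
        self.data = data
        self.spec = spec
        self.order: np.ndarray | None = None
        self.cursor = 0
        self.done = True
        self.trajectory: list[tuple[int, int, float]] = []

    def reset(self, rng: np.random.Generator) -> np.ndarray:
        """Shuffle and return the first state's image."""
        self.order = rng.permutation(len(self.data))
        self.cursor = 0
        self.done = False
        self.trajectory = []
        return self.data.images[self.order[0]]

    @property
    def current_index(self) -> int:
        return int(self.order[self.cursor])

    def step(self, action: int) -> Transition:
        if self.done or self.order is None:
            raise EpisodeStateError("step() called on a finished episode; call reset()")
        idx = self.current_index
        label = int(self.data.labels[idx])
        r = reward(action, label, self.spec)
        minority_miss = label == 0 and action != label
        exhausted = self.cursor == len(self.data) - 1
        end = minority_miss or exhausted
        nxt = None if end else int(self.order[self.cursor + 1])
        self.trajectory.append((idx, action, r))
        self.cursor += 0 if end else 1
        self.done = end
        return Transition(state=idx, action=action, reward=r, next_state=nxt, end=end)


def episode_return(rewards, gamma: float) -> float:
    """Discounted return g = sum_k gamma^k r_k of a reward sequence."""
    if not 0.0 < gamma <= 1.0:
        raise ConfigurationError(f"gamma must be in (0, 1], got {gamma}")
    rewards = np.asarray(rewards, dtype=np.float64)
    if rewards.size == 0:
        raise InputError("empty trajectory")
    return float(np.sum(rewards * gamma ** np.arange(rewards.size)))
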