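"""High-level model / results interface.

:class:`RLMDPA` bundles the full two-stage pipeline -- artificial bee
colony pretraining of the Q-network weights followed by deep Q-learning
on the imbalanced-classification MDP -- behind a familiar
model-object pattern: construct from data, call :meth:`RLMDPA.fit`, and
inspect the returned :class:`RLMDPAResults` (trained network, search and
training histories, metrics, ``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .metrics import MetricsReport, cross_validate as _cross_validate, evaluate_predictions
from .abc_search import ABCConfig, ABCResult, FitnessContext, run_abc
from .env import LabeledImageSet, RewardSpec
from .exceptions import ConfigurationError
from .network import NetworkArchitecture, QNetwork
from .synthetic import read_dataset
from .trainer import TrainConfig, TrainResult, predict, train

__all__ = ["RLMDPA", "RLMDPAResults", "cross_validate_pipeline"]


class RLMDPA:
    """Reinforcement-learning classifier for imbalanced grayscale images.

    Parameters
    ----------
    data
        Training images and binary labels (minority remapped to 0).
    architecture
        Q-network architecture; defaults to the full-scale five-conv-layer
        stack sized to the data's image dimension.
    reward_lambda
        Majority-class reward magnitude in [0, 1] (0.3 by default, the
        best-performing setting of the lambda sweep).
    abc_config, train_config
        Stage hyper-parameters; sensible full-scale defaults.
    pretrain
        If False, skip the bee-colony stage and start Q-learning from
        seeded uniform weights.
    fitness_subsample
        Optional cap on the number of samples scored per ABC fitness
        evaluation.
    val_fraction
        Held-out stratified fraction for early stopping (0 disables).
    checkpoint_on_train
        If True (and no validation split is in use), monitor the
        F-measure on the training set itself and return the
        best-scoring checkpoint instead of the final weights.  Useful at
        small problem sizes where a held-out split would be tiny.
    """

    def __init__(
        self,
        data: LabeledImageSet,
        architecture: Optional[NetworkArchitecture] = None,
        reward_lambda: float = 0.3,
        abc_config: Optional[ABCConfig] = None,
        train_config: Optional[TrainConfig] = None,
        pretrain: bool = True,
        fitness_subsample: Optional[int] = None,
        val_fraction: float = 0.0,
        checkpoint_on_train: bool = False,
    ):
        self.data = data
        size = int(data.images.shape[1])
        self.architecture = architecture or NetworkArchitecture(input_size=size)
        self.architecture.validate()
        if self.architecture.input_size != size:
            raise ConfigurationError(
                f"architecture expects {self.architecture.input_size}px images, data is {size}px"
            )
        self.reward_spec = RewardSpec(reward_lambda)
        self.abc_config = abc_config or ABCConfig()
        self.train_config = train_config or TrainConfig()
        self.pretrain = pretrain
        self.fitness_subsample = fitness_subsample
        if not 0.0 <= val_fraction < 1.0:
            raise ConfigurationError("val_fraction must be in [0, 1)")
        self.val_fraction = val_fraction
        self.checkpoint_on_train = checkpoint_on_train

    @classmethod
    def from_manifest(cls, manifest, image_size: int = 100, **kwargs) -> "RLMDPA":
        """Build from a path,label manifest CSV of raster images."""
        return cls(read_dataset(manifest, image_size=image_size), **kwargs)

    # ------------------------------------------------------------------

    def fit(self, seed: int = 0) -> "RLMDPAResults":
        """Run pretraining (optional) then Q-learning; return results."""
        train_set, val_set = self.data, None
        if self.val_fraction > 0.0:
            idx_train, idx_val = train_test_split(
                np.arange(len(self.data)),
                test_size=self.val_fraction,
                random_state=seed,
                stratify=self.data.labels,
            )
            train_set = self.data.subset(idx_train)
            val_set = self.data.subset(idx_val)
        elif self.checkpoint_on_train:
            val_set = train_set

        abc_result: Optional[ABCResult] = None
        if self.pretrain:
            ctx = FitnessContext(
                train_set, self.architecture,
                subsample=self.fitness_subsample, seed=seed,
            )
            abc_result = run_abc(self.abc_config, ctx, seed=seed)
            init = abc_result.best_position
        else:
            init = QNetwork.build(self.architecture, seed).encode().values

        cfg = TrainConfig(**{**self.train_config.__dict__, "seed": seed})
        train_result = train(
            train_set, init, cfg,
            arch=self.architecture,
            reward_spec=self.reward_spec,
            val_data=val_set,
        )
        return RLMDPAResults(model=self, abc=abc_result, training=train_result, seed=seed)


@dataclass
class RLMDPAResults:
    """Fitted pipeline: trained network plus stage-by-stage diagnostics."""

    model: RLMDPA
    abc: Optional[ABCResult]
    training: TrainResult
    seed: int

    @property
    def network(self) -> QNetwork:
        return self.training.network

    @property
    def log(self) -> pd.DataFrame:
        return self.training.log

    def predict(self, images) -> np.ndarray:
        """Greedy per-image labels (0 = minority class)."""
        return predict(self.network, images)

    def evaluate(self, images, labels, positive_class: int = 0) -> MetricsReport:
        return evaluate_predictions(
            np.asarray(labels), self.predict(images), positive_class
        )

    def summary(self) -> str:
        m = self.model
        train_report = self.evaluate(m.data.images, m.data.labels)
        arch = m.architecture
        lines = [
            "            Imbalanced-Image Q-Learning Results",
            "=" * 62,
            f"{'No. samples:':<24}{len(m.data):>8}    "
            f"{'Minority fraction:':<22}{m.data.n_minority / len(m.data):>8.3f}",
            f"{'Image size:':<24}{arch.input_size:>8}    "
            f"{'Parameters D:':<22}{arch.n_parameters:>8}",
            f"{'Conv filters:':<24}{str(list(arch.conv_filters)):>8}",
            f"{'FC sizes:':<24}{str(list(arch.fc_sizes)):>8}",
            f"{'lambda (majority):':<24}{m.reward_spec.lam:>8.2f}    "
            f"{'gamma:':<22}{m.train_config.gamma:>8.2f}",
        ]
        if self.abc is not None:
            lines.append(
                f"{'ABC evaluations:':<24}{self.abc.n_evaluations:>8}    "
                f"{'ABC best fitness:':<22}{self.abc.best_fitness:>8.4f}"
            )
        lines.append(
            f"{'Episodes run:':<24}{self.training.episodes_run:>8}    "
            f"{'Stopped early:':<22}{str(self.training.stopped_early):>8}"
        )
        if self.training.best_val_f_measure is not None:
            lines.append(f"{'Best val F-measure:':<24}{self.training.best_val_f_measure:>8.3f}")
        lines.append("-" * 62)
        lines.append("Training-set metrics (positive class = minority):")
        for name, value in train_report.as_dict().items():
            lines.append(f"  {name:<14}{value:>8.3f}")
        lines.append("=" * 62)
        return "\n".join(lines)


def cross_validate_pipeline(
    data: LabeledImageSet,
    k: int = 5,
    seed: int = 0,
    **model_kwargs,
) -> tuple[list[MetricsReport], pd.DataFrame]:
    """Stratified k-fold evaluation of the full pretrain+train pipeline.

    Each fold fits a fresh :class:`RLMDPA` on the training split (seeded
    per fold) and scores greedy predictions on the held-out split.
    Returns per-fold reports and the min/median/max/mean/std summary.
    """

    fold_counter = {"i": 0}

    def fit_predict(train_set: LabeledImageSet, test_images: np.ndarray) -> np.ndarray:
        fold_seed = seed * 1000 + fold_counter["i"]
        fold_counter["i"] += 1
        results = RLMDPA(train_set, **model_kwargs).fit(seed=fold_seed)
        return results.predict(test_images)

    return _cross_validate(data, fit_predict, k=k, seed=seed)
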