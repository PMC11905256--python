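"""Scikit-learn-style front end for the mean-teacher segmenter.

`MeanTeacherSegmenter` flattens the network, loss and optimization
configuration into constructor parameters (so ``get_params`` /
``set_params`` / ``clone`` behave as sklearn users expect), trains on a
:class:`~ssdaseg.synthetic.SplitDataset` via ``fit``, and predicts label
maps for target-domain volumes.  ``score`` returns mean foreground DSC.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .mean_teacher import (LossWeights, TrainConfig, evaluate_model,
                           predict_labels, train)
from .preprocess import LabelMap, Volume
from .segnet import NetworkConfig
from .synthetic import DomainSample, SplitDataset

__all__ = ["MeanTeacherSegmenter"]


class MeanTeacherSegmenter(BaseEstimator):
    """Semi-supervised domain-adaptive 3D segmenter (student-teacher UNet).

    Parameters mirror the method's knobs: ``use_sad`` / ``use_glf`` toggle
    the scale-aware encoder blocks and the global-local fusion bottleneck,
    ``use_semt`` the teacher/consistency machinery, ``use_source`` the
    labeled source stream; ``lam``, ``lam_dice``, ``lam_ce`` are the loss
    trade-offs; the remaining parameters follow the training recipe.

    Fitted attributes: ``student_`` (the deliverable network), ``teacher_``,
    ``history_`` (per-step loss table).
    """

    def __init__(self, *, n_stages: int = 3, base_width: int = 8,
                 use_sad: bool = True, use_glf: bool = True,
                 use_semt: bool = True, use_source: bool = True,
                 dilation_rates: tuple[int, int] = (1, 3),
                 glf_depth: int = 4, glf_d_head: int = 8,
                 lam: float = 2.0, lam_dice: float = 0.7, lam_ce: float = 0.3,
                 steps: int = 500, lr: float = 9e-4, weight_decay: float = 5e-5,
                 ema_decay: float = 0.99, noise_sd: float = 0.05,
                 augment: bool = True, random_state: int = 0):
        self.n_stages = n_stages
        self.base_width = base_width
        self.use_sad = use_sad
        self.use_glf = use_glf
        self.use_semt = use_semt
        self.use_source = use_source
        self.dilation_rates = dilation_rates
        self.glf_depth = glf_depth
        self.glf_d_head = glf_d_head
        self.lam = lam
        self.lam_dice = lam_dice
        self.lam_ce = lam_ce
        self.steps = steps
        self.lr = lr
        self.weight_decay = weight_decay
        self.ema_decay = ema_decay
        self.noise_sd = noise_sd
        self.augment = augment
        self.random_state = random_state

    # ------------------------------------------------------------------ config
    def _network_config(self) -> NetworkConfig:
        return NetworkConfig(n_stages=self.n_stages, base_width=self.base_width,
                             use_sad=self.use_sad, use_glf=self.use_glf,
                             dilation_rates=tuple(self.dilation_rates),
                             glf_depth=self.glf_depth, glf_d_head=self.glf_d_head,
                             input_noise_sd=self.noise_sd)

    def _loss_weights(self) -> LossWeights:
        return LossWeights(lam=self.lam, lam_dice=self.lam_dice, lam_ce=self.lam_ce)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(steps=self.steps, lr=self.lr,
                           weight_decay=self.weight_decay,
                           ema_decay=self.ema_decay, noise_sd=self.noise_sd,
                           augment=self.augment, use_source=self.use_source,
                           use_semt=self.use_semt)

    # --------------------------------------------------------------------- api
    def fit(self, dataset: SplitDataset, y=None) -> "MeanTeacherSegmenter":
        """Train on a SplitDataset (SL/TL/TU); ``y`` is ignored (labels live
        inside the dataset)."""
        result = train(dataset, self._network_config(), self._loss_weights(),
                       self._train_config(), seed=self.random_state)
        self.student_ = result.student
        self.teacher_ = result.teacher
        self.history_ = result.history
        return self

    def predict(self, volumes: list[Volume], domain: str = "target") -> list[LabelMap]:
        self._check_fitted()
        return predict_labels(self.student_, volumes, domain)

    def score(self, samples: list[DomainSample], y=None,
              domain: str = "target") -> float:
        """Mean foreground DSC over labeled samples (higher is better)."""
        self._check_fitted()
        cases = evaluate_model(self.student_, samples, domain)
        return float(np.mean([c.mean_dsc for c in cases]))

    def _check_fitted(self) -> None:
        if not hasattr(self, "student_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
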