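"""Scikit-learn style estimator wrapping the fusion segmenter.

``FusionSegmenter`` exposes the whole train/predict pipeline through the
familiar ``fit`` / ``predict`` / ``get_params`` / ``set_params`` surface so it
composes with sklearn model selection; fitted state lives in trailing-
underscore attributes (``model_``, ``history_``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .metrics import dice
from .training import AblationVariant, TrainConfig, build_variant, predict, train
from .volume_io import SamplePair

__all__ = ["FusionSegmenter"]


class FusionSegmenter(BaseEstimator):
    """Anatomy-guided PET-CT fusion segmenter with an sklearn interface.

    Parameters mirror the model and training configuration; ``variant``
    selects the architecture (default the full CT-guided fusion model).
    ``fit`` takes a list of :class:`SamplePair` with masks; ``predict``
    returns binary mask arrays.
    """

    def __init__(self, variant: str = "CT_GUIDED", dims: int | None = None,
                 encoder_filters: tuple[int, ...] = (128, 64, 32, 16),
                 se_reduction: int = 4, learning_rate: float = 0.005,
                 max_epochs: int = 20, loss: str = "bce_dice",
                 threshold: float = 0.5, normalize: bool = True,
                 augment_ops: tuple[str, ...] = (), seed: int = 0):
        self.variant = variant
        self.dims = dims
        self.encoder_filters = encoder_filters
        self.se_reduction = se_reduction
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.loss = loss
        self.threshold = threshold
        self.normalize = normalize
        self.augment_ops = augment_ops
        self.seed = seed

    def _config(self) -> TrainConfig:
        return TrainConfig(learning_rate=self.learning_rate,
                           max_epochs=self.max_epochs, loss=self.loss,
                           threshold=self.threshold, normalize=self.normalize,
                           augment_ops=tuple(self.augment_ops), seed=self.seed)

    def fit(self, X: list[SamplePair], y=None) -> "FusionSegmenter":
        if not X:
            raise ValueError("fit requires at least one SamplePair")
        dims = self.dims if self.dims is not None else X[0].pet.data.ndim
        self.model_ = build_variant(AblationVariant(self.variant), dims=dims,
                                    encoder_filters=tuple(self.encoder_filters),
                                    seed=self.seed, se_reduction=self.se_reduction)
        self.history_ = train(self.model_, list(X), self._config())
        return self

    def predict(self, X: list[SamplePair]) -> list[np.ndarray]:
        if not hasattr(self, "model_"):
            raise RuntimeError("FusionSegmenter is not fitted yet")
        return [predict(self.model_, s, threshold=self.threshold,
                        normalize=self.normalize).data for s in X]

    def score(self, X: list[SamplePair], y=None) -> float:
        """Mean Dice over samples (requires ground-truth masks)."""
        preds = self.predict(X)
        return float(np.mean([dice(s.mask.data, p) for s, p in zip(X, preds)]))
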