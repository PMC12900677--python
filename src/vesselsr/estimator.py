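"""Scikit-learn style estimator facades.

``SuperResolver`` wraps network construction, training and inference in a
fit/predict interface so the model composes with sklearn tooling
(``get_params``/``set_params``, clone, grid search over e.g. loss
weights).  ``Degrader`` is the transform-shaped counterpart for the
degradation operators.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .degrade import DegradationSpec, apply_degradation
from .errors import ContractError
from .imaging import psnr
from .losses import LossWeights
from .model import ModelConfig
from .synthetic import DatasetItem, SyntheticFundus
from .training import TrainConfig, evaluate_pairs, train


class SuperResolver(BaseEstimator):
    """Structure-preserving super-resolution estimator.

    Parameters mirror the model/training configuration at desk scale; the
    full-size architecture is selected with ``preset='full'``.

    Fitted attributes: ``net_`` (the trained network), ``history_``
    (per-epoch records), ``model_config_``.
    """

    def __init__(self, scale: int = 2, preset: str = "tiny", path: str = "dual",
                 epochs: int = 10, steps_per_epoch: int = 25, batch: int = 4,
                 patch: int = 16, eta_max: float = 2e-3, eta_min: float = 1e-6,
                 lambda_mse: float = 1.0, lambda_perceptual: float = 0.1,
                 lambda_fractal: float = 0.05, fractal_tau: float = 0.25,
                 curriculum_switch: float = 0.3, val_delta_df: bool = False,
                 seed: int = 0):
        self.scale = scale
        self.preset = preset
        self.path = path
        self.epochs = epochs
        self.steps_per_epoch = steps_per_epoch
        self.batch = batch
        self.patch = patch
        self.eta_max = eta_max
        self.eta_min = eta_min
        self.lambda_mse = lambda_mse
        self.lambda_perceptual = lambda_perceptual
        self.lambda_fractal = lambda_fractal
        self.fractal_tau = fractal_tau
        self.curriculum_switch = curriculum_switch
        self.val_delta_df = val_delta_df
        self.seed = seed

    # ------------------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        if self.preset == "tiny":
            return ModelConfig.tiny(scale=self.scale)
        if self.preset == "full":
            return ModelConfig(scale=self.scale)
        raise ContractError(f"unknown preset {self.preset!r}")

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            eta_max=self.eta_max, eta_min=self.eta_min, epochs=self.epochs,
            steps_per_epoch=self.steps_per_epoch, batch=self.batch,
            patch=self.patch, seed=self.seed,
            curriculum_switch=self.curriculum_switch,
            weights=LossWeights(self.lambda_mse, self.lambda_perceptual,
                                self.lambda_fractal),
            fractal_tau=self.fractal_tau, val_delta_df=self.val_delta_df,
        )

    @staticmethod
    def _as_items(X, y) -> list[DatasetItem]:
        if y is None:
            items = list(X)
            if not all(isinstance(it, DatasetItem) for it in items):
                raise ContractError(
                    "fit expects DatasetItem list, or X=LR images with y=HR images")
            return items
        items = []
        n = len(X)
        n_train = max(1, int(round(0.8 * n)))
        for i, (lr, hr) in enumerate(zip(X, y)):
            hr_arr = hr.image if isinstance(hr, SyntheticFundus) else np.asarray(hr)
            fundus = hr if isinstance(hr, SyntheticFundus) else SyntheticFundus(
                image=hr_arr, mask=np.zeros(hr_arr.shape[:2], np.uint8),
                params=None)
            items.append(DatasetItem(hr=fundus, lr=np.asarray(lr),
                                     split="train" if i < n_train else "val",
                                     index=i))
        return items

    # ------------------------------------------------------------------
    def fit(self, X, y=None) -> "SuperResolver":
        """Train on paired data: X a list of DatasetItem, or X=LR images
        and y=matching HR images."""
        items = self._as_items(X, y)
        self.model_config_ = self._model_config()
        self.net_, self.history_ = train(self.model_config_, items,
                                         self._train_config(), path=self.path)
        return self

    def predict(self, X) -> list[np.ndarray]:
        """Super-resolve a list of LR images."""
        if not hasattr(self, "net_"):
            raise ContractError("estimator is not fitted")
        return [self.net_.enhance(np.asarray(img)) for img in X]

    def transform(self, X):
        return self.predict(X)

    def score(self, X, y) -> float:
        """Mean PSNR (dB) of predictions against the HR references."""
        preds = self.predict(X)
        vals = []
        for p, hr in zip(preds, y):
            hr_arr = hr.image if isinstance(hr, SyntheticFundus) else np.asarray(hr)
            vals.append(psnr(hr_arr, p))
        return float(np.mean(vals))

    def evaluate(self, items: list[DatasetItem], with_delta_df: bool = False) -> dict:
        if not hasattr(self, "net_"):
            raise ContractError("estimator is not fitted")
        return evaluate_pairs(self.net_, items, with_delta_df=with_delta_df)


class Degrader(BaseEstimator, TransformerMixin):
    """Transform-shaped wrapper applying one degradation spec to images."""

    def __init__(self, spec: DegradationSpec | None = None):
        self.spec = spec

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> list[np.ndarray]:
        spec = self.spec or DegradationSpec(kind="gaussian_blur", sigma=1.2)
        return [apply_degradation(np.asarray(img), spec) for img in X]
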