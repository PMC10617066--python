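"""scikit-learn estimator facade over the GA-initialized Kernel-Huber CNN.

`KernelHuberCNNRegressor` accepts an ordinary (n_samples, n_channels) feature
matrix (one preprocessed, scaled spectrum per row) and a target vector, so it
composes with sklearn pipelines, cross-validation and grid search.  The heavy
lifting lives in :mod:`ramanquant.network`, :mod:`ramanquant.ga` and
:mod:`ramanquant.losses`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .ga import GAConfig, run_ga
from .losses import KernelHuberParams, median_bandwidth
from .network import ModelConfig, OptimizerConfig, build_model, predict, train


class KernelHuberCNNRegressor(RegressorMixin, BaseEstimator):
    """Residual separable 1D CNN trained under the Kernel-Huber loss, with an
    optional adaptive-genetic-algorithm search of the initial weights.

    Parameters
    ----------
    delta, sigma
        Huber truncation tolerance and Gaussian-kernel bandwidth, on the
        target scale.  ``sigma="auto"`` uses the median pairwise distance of
        the training targets.
    detach_weights
        Treat kernel weights as constants when computing gradients (default).
    ga_init
        Run the adaptive GA to pick initial weights before gradient training.
    lr, epochs, batch_size
        Adam settings; ``batch_size=None`` trains full batch.
    random_state
        Root seed fanned out to initialization, the GA and the optimizer.

    Attributes
    ----------
    model_ : Model
        The trained network.
    history_ : list of float
        Training loss per epoch (plus the final loss).
    ga_result_ : GAResult or None
        Search trace when ``ga_init`` is on.
    sigma_ : float
        The kernel bandwidth actually used.
    """

    def __init__(
        self,
        stem_channels: int = 8,
        stem_kernel: int = 7,
        n_blocks: int = 2,
        block_channels: int = 16,
        block_kernel: int = 5,
        hidden_units: int = 16,
        delta: float = 1.0,
        sigma: float | str = "auto",
        detach_weights: bool = True,
        lr: float = 1e-2,
        epochs: int = 300,
        batch_size: int | None = None,
        ga_init: bool = True,
        ga_pop_size: int = 30,
        ga_generations: int = 50,
        random_state: int = 0,
    ):
        self.stem_channels = stem_channels
        self.stem_kernel = stem_kernel
        self.n_blocks = n_blocks
        self.block_channels = block_channels
        self.block_kernel = block_kernel
        self.hidden_units = hidden_units
        self.delta = delta
        self.sigma = sigma
        self.detach_weights = detach_weights
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.ga_init = ga_init
        self.ga_pop_size = ga_pop_size
        self.ga_generations = ga_generations
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _stage_seed(self, offset: int) -> int:
        return int(
            np.random.SeedSequence(
                entropy=self.random_state, spawn_key=(offset,)
            ).generate_state(1)[0] % 2**31
        )

    def _model_config(self, n_features: int) -> ModelConfig:
        return ModelConfig(
            input_length=n_features,
            in_channels=1,
            stem_kernel=self.stem_kernel,
            stem_channels=self.stem_channels,
            n_blocks=self.n_blocks,
            block_channels=self.block_channels,
            block_kernel=self.block_kernel,
            hidden_units=self.hidden_units,
            seed=self._stage_seed(0),
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        self.n_features_in_ = X.shape[1]
        cfg = self._model_config(X.shape[1])

        sigma = self.sigma
        if sigma == "auto":
            sigma = median_bandwidth(y)
        self.sigma_ = float(sigma)
        loss_params = KernelHuberParams(
            delta=self.delta, sigma=self.sigma_, detach_weights=self.detach_weights
        )

        init = None
        self.ga_result_ = None
        if self.ga_init:
            ga_cfg = GAConfig(
                pop_size=self.ga_pop_size,
                generations=self.ga_generations,
                seed=self._stage_seed(1),
            )
            self.ga_result_ = run_ga(cfg, X, y, ga_cfg)
            init = self.ga_result_.best_chromosome

        model = build_model(cfg)
        opt = OptimizerConfig(
            lr=self.lr, epochs=self.epochs, batch=self.batch_size,
            seed=self._stage_seed(2),
        )
        self.model_, history = train(model, X, y, loss_params, opt, init=init)
        self.history_ = history.loss
        self.loss_params_ = loss_params
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return predict(self.model_, X)

    def _more_tags(self):  # sklearn <1.6 compatibility hook
        return {"poor_score": True, "non_deterministic": False}
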