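"""End-to-end experiment: simulate -> airPLS -> windows -> split -> scale ->
GA init -> train -> evaluate, all driven by one root seed.

Stage seeds are derived from the root seed through fixed spawn keys, so every
stage is independently reproducible and the whole run is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ga import CatastropheConfig, GAConfig, GAResult, run_ga
from .io import SpectraDataset
from .losses import KernelHuberParams, median_bandwidth
from .metrics import MetricsReport, evaluate
from .network import Model, ModelConfig, OptimizerConfig, build_model, train
from .preprocessing import (AirPLSParams, WindowSet, correct_baseline,
                            scale_features, select_windows, split_dataset)
from .synthetic import SyntheticConfig, generate_dataset


def stage_seed(root_seed: int, offset: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int(
        np.random.SeedSequence(entropy=root_seed, spawn_key=(offset,))
        .generate_state(1)[0] % 2**31
    )


@dataclass
class PreprocessConfig:
    lam: float = 1e5
    max_iter: int = 15
    ratio_tol: float = 0.05
    windows: tuple[tuple[float, float], ...] = ((519.0, 617.0), (1292.0, 1713.0))
    n_train: int = 40
    stratified: bool = True


@dataclass
class LossConfig:
    delta: float = 1.0
    sigma: float | str = "auto"
    detach_weights: bool = True


@dataclass
class TrainConfig:
    lr: float = 1e-2
    epochs: int = 300
    batch: int | None = None


@dataclass
class RunConfig:
    """Nested configuration of the whole pipeline; round-trips through YAML."""

    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    use_ga: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        if "synthetic" in kwargs:
            syn = dict(kwargs["synthetic"])
            if "peaks" in syn:
                syn["peaks"] = tuple(tuple(p) for p in syn["peaks"])
            kwargs["synthetic"] = SyntheticConfig(**syn)
        if "preprocess" in kwargs:
            pre = dict(kwargs["preprocess"])
            if "windows" in pre:
                pre["windows"] = tuple(tuple(w) for w in pre["windows"])
            kwargs["preprocess"] = PreprocessConfig(**pre)
        if "loss" in kwargs:
            kwargs["loss"] = LossConfig(**kwargs["loss"])
        if "model" in kwargs:
            kwargs["model"] = ModelConfig(**kwargs["model"])
        if "ga" in kwargs:
            ga = dict(kwargs["ga"])
            if "catastrophe" in ga:
                ga["catastrophe"] = CatastropheConfig(**ga["catastrophe"])
            kwargs["ga"] = GAConfig(**ga)
        if "train" in kwargs:
            kwargs["train"] = TrainConfig(**kwargs["train"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _plain(obj):
    """YAML-safe deep copy (tuples -> lists, numpy scalars -> python)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class RunResult:
    report: MetricsReport
    model: Model
    ga_result: GAResult | None
    history: list[float]
    train_set: SpectraDataset
    test_set: SpectraDataset
    sigma: float

    def report_dict(self) -> dict:
        return self.report.to_dict()


def prepare_data(cfg: RunConfig):
    """simulate -> baseline-correct -> window-select -> split -> scale.

    Returns scaled (X, y) arrays for train and test plus the scaler and the
    raw datasets.
    """
    syn = dataclasses.replace(cfg.synthetic, seed=stage_seed(cfg.seed, 0))
    dataset, truth = generate_dataset(syn)

    params = AirPLSParams(cfg.preprocess.lam, cfg.preprocess.max_iter,
                          cfg.preprocess.ratio_tol)
    corrected = correct_baseline(dataset, params)
    windowed = select_windows(corrected, WindowSet(cfg.preprocess.windows))
    train_ds, test_ds = split_dataset(
        windowed, cfg.preprocess.n_train, seed=stage_seed(cfg.seed, 1),
        stratified=cfg.preprocess.stratified,
    )
    train_s, (test_s,), scaler = scale_features(train_ds, [test_ds])
    X_tr = train_s.intensity_matrix()
    y_tr = train_s.concentrations
    X_te = test_s.intensity_matrix()
    y_te = test_s.concentrations
    return (X_tr, y_tr), (X_te, y_te), scaler, train_ds, test_ds, truth


def run_all(cfg: RunConfig | None = None) -> RunResult:
    """Execute the full synthetic experiment and score it on the ppm scale."""
    cfg = cfg or RunConfig()
    (X_tr, y_tr), (X_te, y_te), scaler, train_ds, test_ds, _ = prepare_data(cfg)

    model_cfg = dataclasses.replace(
        cfg.model, input_length=X_tr.shape[1], seed=stage_seed(cfg.seed, 2)
    )

    sigma = cfg.loss.sigma
    if sigma == "auto":
        sigma = median_bandwidth(y_tr)
    loss_params = KernelHuberParams(cfg.loss.delta, float(sigma),
                                    cfg.loss.detach_weights)

    ga_result = None
    init = None
    if cfg.use_ga:
        ga_cfg = dataclasses.replace(cfg.ga, seed=stage_seed(cfg.seed, 3))
        ga_result = run_ga(model_cfg, X_tr, y_tr, ga_cfg)
        init = ga_result.best_chromosome

    model = build_model(model_cfg)
    opt = OptimizerConfig(lr=cfg.train.lr, epochs=cfg.train.epochs,
                          batch=cfg.train.batch, seed=stage_seed(cfg.seed, 4))
    model, history = train(model, X_tr, y_tr, loss_params, opt, init=init)

    report = evaluate(model, (X_tr, y_tr), (X_te, y_te), scaler)
    return RunResult(report, model, ga_result, history.loss,
                     train_ds, test_ds, float(sigma))


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(model: Model, path) -> None:
    """Weights as .npz next to a JSON sidecar describing the architecture."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, weights=model.get_flat())
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(dataclasses.asdict(model.cfg), fh, indent=2, sort_keys=True)


def load_checkpoint(path) -> Model:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        cfg = ModelConfig(**json.load(fh))
    model = build_model(cfg)
    model.set_flat(np.load(path)["weights"])
    return model
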