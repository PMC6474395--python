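"""Experiment configuration: nested YAML blocks mirroring the module configs.

A config file has top-level blocks ``study``, ``train`` and ``evaluate``
plus ``seed``, ``out_dir`` and ``preset`` ({"toy", "study_scale"}).
Unknown fields raise a schema error naming the field; every run writes
its resolved config beside its outputs so results are reproducible from
the run directory alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass, field

import yaml

from .experiments import StudyConfig, toy_study_config, toy_train_config
from .models import LossWeights
from .training import TrainConfig

__all__ = ["ExperimentConfig", "load_config", "save_config"]


@dataclass
class EvalConfig:
    metric: str = "pearson"
    rescale_mode: str = "sqrt_n"
    per_image: int | None = None     # lure subsampling (None = all lures)
    n_perm: int = 199                # RV permutation baseline


@dataclass
class ExperimentConfig:
    seed: int = 0
    out_dir: str = "runs/toy"
    preset: str = "toy"
    study: StudyConfig = None
    train: TrainConfig = None
    evaluate: EvalConfig = field(default_factory=EvalConfig)

    def __post_init__(self):
        if self.preset not in ("toy", "study_scale"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.study is None:
            self.study = (toy_study_config(self.seed) if self.preset == "toy"
                          else StudyConfig(seed=self.seed))
        if self.train is None:
            self.train = (toy_train_config(self.seed) if self.preset == "toy"
                          else TrainConfig(seed=self.seed))


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(
            f"unknown config field '{path}.{sorted(unknown)[0]}'")
    kw = dict(data)
    if cls is TrainConfig and isinstance(kw.get("weights"), dict):
        kw["weights"] = _build(LossWeights, kw["weights"], f"{path}.weights")
    return cls(**kw)


def load_config(path_or_dict) -> ExperimentConfig:
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as f:
            raw = yaml.safe_load(f) or {}
    top = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - top
    if unknown:
        raise ValueError(f"unknown config field '{sorted(unknown)[0]}'")
    kw = dict(raw)
    if isinstance(kw.get("study"), dict):
        kw["study"] = _build(StudyConfig, kw["study"], "study")
    if isinstance(kw.get("train"), dict):
        kw["train"] = _build(TrainConfig, kw["train"], "train")
    if isinstance(kw.get("evaluate"), dict):
        kw["evaluate"] = _build(EvalConfig, kw["evaluate"], "evaluate")
    return ExperimentConfig(**kw)


def save_config(cfg: ExperimentConfig, path: str) -> None:
    d = asdict(cfg)
    with open(path, "w") as f:
        yaml.safe_dump(d, f, sort_keys=False)
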