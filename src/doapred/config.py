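"""Run configuration: one YAML document covering every pipeline stage.

Every hyperparameter of the method is surfaced here with its default
(learning rate 0.005 decayed x0.1 every 10 epochs, batch 256/128,
lambda 0.05, K 5, cosine distance, 120-step windows).  Unknown keys are
rejected so typos fail loudly, and a config round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


def _check_keys(d: dict, allowed, where: str):
    unknown = set(d) - set(allowed)
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass
class SimulateSection:
    n: int = 40
    duration: int = 2400
    shift: dict = field(default_factory=dict)  # overrides of the generator trends
    noise_bis_sd: float = 1.5
    noise_gap_s: int = 20
    noise_glitches: int = 1


@dataclass
class PreprocessSection:
    split: tuple = (0.6, 0.2, 0.2)  # train / validation / test case fractions
    window_length: int = 120
    stride: int = 1
    lowess_frac: float = 0.03


@dataclass
class TdcSection:
    K: int = 5
    n_candidates: int = 10
    metric: str = "cosine"
    dmin: float = 0.1
    dmax: float = 1.0


@dataclass
class ModelSection:
    gru_hidden: int = 64
    gru_layers: int = 1
    bottleneck_widths: tuple = (64, 32)


@dataclass
class TrainSection:
    lr: float = 0.005
    decay_every: int = 10
    decay_factor: float = 0.1
    batch_train: int = 256
    batch_eval: int = 128
    lam: float = 0.05
    epochs: int = 30
    grad_clip_norm: float = 10.0
    importance_mode: str = "neural"
    kd_enabled: bool = True
    tdm_enabled: bool = True
    train_teacher: bool = True


@dataclass
class RunConfig:
    seed: int = 0
    simulate: SimulateSection = field(default_factory=SimulateSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    tdc: TdcSection = field(default_factory=TdcSection)
    model: ModelSection = field(default_factory=ModelSection)
    train: TrainSection = field(default_factory=TrainSection)

    def __post_init__(self):
        if self.tdc.K < 2:
            raise ValueError("tdc.K must be >= 2")
        if abs(sum(self.preprocess.split) - 1.0) > 1e-9:
            raise ValueError("preprocess.split fractions must sum to 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["preprocess"]["split"] = list(self.preprocess.split)
        d["model"]["bottleneck_widths"] = list(self.model.bottleneck_widths)
        return d


_SECTIONS = {
    "simulate": SimulateSection,
    "preprocess": PreprocessSection,
    "tdc": TdcSection,
    "model": ModelSection,
    "train": TrainSection,
}


def config_from_dict(d: dict) -> RunConfig:
    _check_keys(d, list(_SECTIONS) + ["seed"], "top level")
    kwargs: dict = {"seed": int(d.get("seed", 0))}
    for name, cls in _SECTIONS.items():
        sub = dict(d.get(name, {}))
        _check_keys(sub, cls.__dataclass_fields__, name)
        for key in ("split", "bottleneck_widths"):
            if key in sub:
                sub[key] = tuple(sub[key])
        kwargs[name] = cls(**sub)
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
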