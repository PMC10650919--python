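"""Teacher and student networks.

Both networks share one architecture: a GRU over the 120-step dose window,
a two-layer fully connected bottleneck that fuses the final hidden state
with the static covariates (age, sex, height, weight), and a scalar output
head.  The only difference is the input width — the teacher receives a
third channel carrying the previous-bin BIS, which makes its intermediate
features a strong reference for distillation.

Parameters live in a flat ``{name: Tensor}`` dict; forwards are pure
functions of (params, inputs) on the autodiff tape, so training code can
differentiate any loss assembled from the returned
:class:`FeatureBundle`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad

__all__ = ["NetworkConfig", "FeatureBundle", "init_params", "forward",
           "forward_student", "forward_teacher", "count_parameters",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetworkConfig:
    input_channels: int  # 2 student, 3 teacher
    gru_hidden: int = 64
    gru_layers: int = 1
    bottleneck_widths: tuple = (64, 32)
    static_dim: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.input_channels < 1 or self.gru_hidden < 1 or self.gru_layers < 1:
            raise ValueError("widths and layer counts must be positive")
        if len(self.bottleneck_widths) != 2 or min(self.bottleneck_widths) < 1:
            raise ValueError("bottleneck needs two positive widths")


@dataclass
class FeatureBundle:
    """Artifacts of one forward pass."""

    hidden_states: ad.Tensor  # (batch, V, hidden) final-layer GRU states
    bottleneck_feature: ad.Tensor  # (batch, b2)
    prediction: ad.Tensor  # (batch,) normalized BIS estimate


def init_params(config: NetworkConfig) -> dict:
    """Glorot-style initialization, deterministic in ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xD0)))
    params: dict[str, ad.Tensor] = {}

    def glorot(shape):
        lim = np.sqrt(6.0 / (shape[0] + shape[-1]))
        return ad.tensor(rng.uniform(-lim, lim, shape), requires_grad=True)

    def zeros(shape):
        return ad.tensor(np.zeros(shape), requires_grad=True)

    h = config.gru_hidden
    for layer in range(config.gru_layers):
        d = config.input_channels if layer == 0 else h
        params[f"gru{layer}.W_ih"] = glorot((d, 3 * h))
        params[f"gru{layer}.W_hh"] = glorot((h, 3 * h))
        params[f"gru{layer}.b_ih"] = zeros(3 * h)
        params[f"gru{layer}.b_hh"] = zeros(3 * h)
    b1, b2 = config.bottleneck_widths
    params["bott1.W"] = glorot((h + config.static_dim, b1))
    params["bott1.b"] = zeros(b1)
    params["bott2.W"] = glorot((b1, b2))
    params["bott2.b"] = zeros(b2)
    params["head.W"] = glorot((b2, 1))
    params["head.b"] = zeros(1)
    return params


def _gru_layer(params: dict, layer: int, x: ad.Tensor) -> ad.Tensor:
    """One GRU layer over a (batch, V, d) tensor via the fused recurrence."""
    return ad.gru_sequence(x, params[f"gru{layer}.W_ih"], params[f"gru{layer}.W_hh"],
                           params[f"gru{layer}.b_ih"], params[f"gru{layer}.b_hh"])


def forward(params: dict, config: NetworkConfig, window: np.ndarray,
            statics: np.ndarray) -> FeatureBundle:
    """Forward pass; ``window`` is (batch, V, C) with C == input_channels."""
    window = np.asarray(window, float)
    statics = np.asarray(statics, float)
    if window.ndim != 3 or window.shape[2] != config.input_channels:
        raise ValueError(
            f"window shape {window.shape} incompatible with {config.input_channels} input channels")
    if statics.shape != (window.shape[0], config.static_dim):
        raise ValueError(f"statics shape {statics.shape} incompatible with config")
    hidden_states = ad.tensor(window)
    for layer in range(config.gru_layers):
        hidden_states = _gru_layer(params, layer, hidden_states)  # (batch, V, hidden)
    fused = ad.concat([hidden_states[:, -1, :], ad.tensor(statics)], axis=1)
    z1 = ad.relu(fused @ params["bott1.W"] + params["bott1.b"])
    z2 = ad.relu(z1 @ params["bott2.W"] + params["bott2.b"])
    pred = (z2 @ params["head.W"] + params["head.b"])[:, 0]
    return FeatureBundle(hidden_states=hidden_states, bottleneck_feature=z2, prediction=pred)


def forward_student(params: dict, config: NetworkConfig, window: np.ndarray,
                    statics: np.ndarray) -> FeatureBundle:
    """Student: 2-channel incremental-dose window plus statics."""
    return forward(params, config, window, statics)


def forward_teacher(params: dict, config: NetworkConfig, window: np.ndarray,
                    prev_bis: np.ndarray, statics: np.ndarray) -> FeatureBundle:
    """Teacher: dose window with the previous-bin BIS as a third channel."""
    if prev_bis is None:
        raise ValueError("teacher forward requires the prev_bis channel")
    prev_bis = np.asarray(prev_bis, float)
    if prev_bis.shape != window.shape[:2]:
        raise ValueError("prev_bis must be (batch, V)")
    full = np.concatenate([window, prev_bis[:, :, None]], axis=2)
    return forward(params, config, full, statics)


def count_parameters(config: NetworkConfig) -> int:
    """Exact trainable-parameter count for a config."""
    h = config.gru_hidden
    total = 0
    for layer in range(config.gru_layers):
        d = config.input_channels if layer == 0 else h
        total += 3 * h * (d + h + 2)
    b1, b2 = config.bottleneck_widths
    total += (h + config.static_dim + 1) * b1
    total += (b1 + 1) * b2
    total += b2 + 1
    return total


def save_checkpoint(path, params: dict, config: NetworkConfig, extra: dict | None = None) -> None:
    """Single-file checkpoint: one JSON header line, then raw ``.npy`` blocks.

    The container is byte-deterministic (no archive timestamps), so
    identical runs produce identical checkpoint files.
    """
    header = {
        "config": {**config.__dict__, "bottleneck_widths": list(config.bottleneck_widths)},
        "extra": extra or {},
        "names": list(params.keys()),
    }
    with open(path, "wb") as fh:
        fh.write((json.dumps(header, sort_keys=True) + "\n").encode())
        for name in header["names"]:
            np.save(fh, params[name].data, allow_pickle=False)


def load_checkpoint(path):
    """Returns (params, config, extra)."""
    with open(path, "rb") as fh:
        header = json.loads(fh.readline().decode())
        params = {name: ad.tensor(np.load(fh, allow_pickle=False), requires_grad=True)
                  for name in header["names"]}
    cfg_d = dict(header["config"])
    cfg_d["bottleneck_widths"] = tuple(cfg_d["bottleneck_widths"])
    return params, NetworkConfig(**cfg_d), header["extra"]
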