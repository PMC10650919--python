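"""Feature-based knowledge distillation losses.

The teacher sees the previous-bin BIS, so its GRU states and bottleneck
feature track depth of anesthesia closely; the student is trained to
imitate both:

    L_g = || T_gru(z) - S_gru(x) ||^2   (per-step hidden states)
    L_b = || T_b(z) - S_b(x) ||^2       (bottleneck features)

Both are squared Euclidean norms averaged over the batch (and over the V
states for L_g), so their scale is comparable to the MSE prediction loss.
With ``detach_teacher`` (the default) the teacher features enter the
student loss as constants: distillation gradients flow to the student only,
and the teacher keeps its own objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .model import FeatureBundle
from .tdm import combined_loss

__all__ = ["KDConfig", "gru_kd_loss", "bottleneck_kd_loss", "student_total_loss"]


@dataclass(frozen=True)
class KDConfig:
    detach_teacher: bool = True
    weight_g: float = 1.0
    weight_b: float = 1.0

    def __post_init__(self):
        if self.weight_g < 0 or self.weight_b < 0:
            raise ValueError("distillation weights must be >= 0")


def _maybe_detach(t: ad.Tensor, detach: bool) -> ad.Tensor:
    return t.detach() if detach else t


def gru_kd_loss(teacher: FeatureBundle, student: FeatureBundle,
                config: KDConfig = KDConfig()) -> ad.Tensor:
    """Mean over windows and states of the squared hidden-state difference."""
    t = _maybe_detach(teacher.hidden_states, config.detach_teacher)
    s = student.hidden_states
    if t.shape != s.shape:
        raise ValueError(f"hidden-state shapes differ: {t.shape} vs {s.shape}")
    diff = t - s
    return (diff * diff).sum(axis=2).mean()


def bottleneck_kd_loss(teacher: FeatureBundle, student: FeatureBundle,
                       config: KDConfig = KDConfig()) -> ad.Tensor:
    """Mean over windows of the squared bottleneck-feature difference."""
    t = _maybe_detach(teacher.bottleneck_feature, config.detach_teacher)
    s = student.bottleneck_feature
    if t.shape != s.shape:
        raise ValueError(f"bottleneck shapes differ: {t.shape} vs {s.shape}")
    diff = t - s
    return (diff * diff).sum(axis=1).mean()


def student_total_loss(lpred: ad.Tensor, pair_losses: list, lg: ad.Tensor,
                       lb: ad.Tensor, lam: float, K: int,
                       config: KDConfig = KDConfig()) -> ad.Tensor:
    """Prediction + TDM regularization + weighted distillation terms."""
    for name, term in (("lpred", lpred), ("lg", lg), ("lb", lb)):
        val = float(term.data if isinstance(term, ad.Tensor) else term)
        if not np.isfinite(val) or val < 0:
            raise ValueError(f"loss component {name} must be finite and >= 0, got {val}")
    base = combined_loss(lpred, pair_losses, lam, K)
    return base + config.weight_g * lg + config.weight_b * lb
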