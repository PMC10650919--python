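"""Temporal distribution matching losses.

Given a segmentation into K periods, training regularizes the GRU so the
hidden-state distributions of different periods align.  For a period pair
(i, j) the loss is an importance-weighted sum over the V hidden states

    L_tdm(D_i, D_j) = sum_t alpha_t * d(h_i^t, h_j^t)

where h^t is the minibatch-mean hidden state of the period at step t, d is
cosine distance (the same metric as the segmentation step), and alpha lies
on the V-simplex.  alpha comes from a small fully connected evaluator fed
the concatenated period summaries — trained jointly with the network — or,
as an ablation, from a boosting-style multiplicative update that raises the
weight of states whose distance grew between epochs.

The prediction loss averages per-period MSE so every period counts equally
regardless of how many windows fall in it; the combined objective is

    L = L_pred + lambda * mean over unordered period pairs of L_tdm.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad

__all__ = [
    "init_importance",
    "init_importance_net",
    "importance_net",
    "cosine_state_distance",
    "tdm_pair_loss",
    "pred_loss",
    "combined_loss",
    "boosting_importance_update",
]


def init_importance(V: int) -> np.ndarray:
    """Uniform importance vector (1/V, ..., 1/V)."""
    if V < 1:
        raise ValueError("V must be >= 1")
    return np.full(V, 1.0 / V)


def init_importance_net(hidden: int, seed: int = 0) -> dict:
    """Evaluator parameters for one period pair.

    Zero-initialized so the first alphas are exactly uniform — the uniform
    initialization of the importance weights — and learn away from it as
    training shapes the hidden states.
    """
    return {
        "W": ad.tensor(np.zeros((2 * hidden, 1)), requires_grad=True),
        "b": ad.tensor(np.zeros(1), requires_grad=True),
    }


def importance_net(H_i: ad.Tensor, H_j: ad.Tensor, params: dict) -> ad.Tensor:
    """alpha = softmax over V of a linear read-out of (H_i, H_j).

    ``H_i``/``H_j`` are (V, hidden) per-step period summaries; the output is
    a (V,) tensor on the simplex, differentiable in both the summaries and
    the evaluator weights.
    """
    if H_i.shape != H_j.shape:
        raise ValueError("period summaries must share a shape")
    both = ad.concat([H_i, H_j], axis=1)  # (V, 2h)
    if both.shape[1] != params["W"].shape[0]:
        raise ValueError(
            f"summary width {both.shape[1]} does not match evaluator weight {params['W'].shape}")
    logits = (both @ params["W"] + params["b"])[:, 0]
    return ad.softmax(logits, axis=0)


def cosine_state_distance(H_i: ad.Tensor, H_j: ad.Tensor, eps: float = 1e-12) -> ad.Tensor:
    """Per-state cosine distance between (V, hidden) summaries -> (V,)."""
    dot = (H_i * H_j).sum(axis=1)
    ni = ad.sqrt((H_i * H_i).sum(axis=1) + eps)
    nj = ad.sqrt((H_j * H_j).sum(axis=1) + eps)
    return 1.0 - dot / (ni * nj)


def tdm_pair_loss(H_i: ad.Tensor, H_j: ad.Tensor, alpha) -> ad.Tensor:
    """Importance-weighted state distance for one period pair (scalar tensor)."""
    if H_i.shape[0] != H_j.shape[0]:
        raise ValueError("period summaries must cover the same V states")
    alpha_t = alpha if isinstance(alpha, ad.Tensor) else ad.tensor(np.asarray(alpha, float))
    if alpha_t.shape[0] != H_i.shape[0]:
        raise ValueError("alpha length must equal V")
    return (alpha_t * cosine_state_distance(H_i, H_j)).sum()


def pred_loss(period_batches) -> ad.Tensor:
    """Mean over periods of the period's MSE.

    ``period_batches`` is a list of (prediction Tensor, target array) pairs,
    one per period, each with at least one sample.
    """
    if not period_batches:
        raise ValueError("need at least one period batch")
    terms = []
    for pred, target in period_batches:
        target = np.asarray(target, float)
        if target.size == 0:
            raise ValueError("a period batch is empty")
        diff = pred - ad.tensor(target)
        terms.append((diff * diff).mean())
    return ad.stack(terms).mean()


def combined_loss(lpred: ad.Tensor, pair_losses: list, lam: float, K: int) -> ad.Tensor:
    """L_pred plus lambda times the mean over unordered period-pair losses."""
    expected = K * (K - 1) // 2
    if len(pair_losses) != expected:
        raise ValueError(f"expected {expected} pair losses for K={K}, got {len(pair_losses)}")
    if lam == 0.0:
        return lpred
    return lpred + lam * ad.stack(list(pair_losses)).mean()


def boosting_importance_update(alpha_prev: np.ndarray, dist_now: np.ndarray,
                               dist_before: np.ndarray) -> np.ndarray:
    """Boosting-style ablation update of the importance vector.

    States whose distribution distance grew since the previous epoch are
    boosted multiplicatively (factor 1 + sigmoid of the increase), then the
    vector is renormalized to the simplex.  Distances that did not grow
    leave their weight factor at 1.
    """
    alpha_prev = np.asarray(alpha_prev, float)
    dist_now = np.asarray(dist_now, float)
    dist_before = np.asarray(dist_before, float)
    if not (alpha_prev.shape == dist_now.shape == dist_before.shape):
        raise ValueError("alpha and distance vectors must share length V")
    growth = dist_now - dist_before
    factor = np.where(growth > 0, 1.0 + 1.0 / (1.0 + np.exp(-growth)), 1.0)
    boosted = alpha_prev * factor
    return boosted / boosted.sum()
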