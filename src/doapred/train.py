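"""Joint teacher-student training.

Each optimizer step draws one period-stratified minibatch, runs both
networks, and updates them simultaneously from the same batch:

* teacher: per-period MSE plus the lambda-weighted TDM regularizer;
* student: the same form plus the two distillation terms, with teacher
  features detached so distillation gradients reach the student only.

Optimization is Adam (initial lr 0.005, decayed x0.1 every 10 epochs) with
global gradient-norm clipping; "weight clipping to prevent gradient
explosion" is realized as gradient clipping, with literal weight-value
clipping available behind a flag.  Every source of randomness derives from
one root seed through named substreams, so a run is bitwise reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from . import distill, model as md, tdm
from .preprocess import Normalizer, WindowSet
from .tdc import Segmentation, assign_periods

__all__ = ["TrainConfig", "TrainHistory", "stratified_batches", "train_joint", "predict"]


@dataclass
class TrainConfig:
    lr: float = 0.005
    decay_every: int = 10  # epochs
    decay_factor: float = 0.1
    batch_train: int = 256
    batch_eval: int = 128
    lam: float = 0.05
    epochs: int = 30
    grad_clip_norm: float = 10.0
    weight_clip: float | None = None  # literal weight-value clipping, off by default
    seed: int = 0
    importance_mode: str = "neural"  # {neural, boosting}
    kd_enabled: bool = True
    tdm_enabled: bool = True
    train_teacher: bool = True  # skippable only when distillation is off
    eval_every: int = 1  # validation cadence in epochs (the last epoch always runs)

    def __post_init__(self):
        if self.lr <= 0 or self.batch_train < 1 or self.batch_eval < 1 or self.epochs < 1:
            raise ValueError("invalid training configuration")
        if self.importance_mode not in ("neural", "boosting"):
            raise ValueError(f"unknown importance_mode {self.importance_mode!r}")
        if self.kd_enabled and not self.train_teacher:
            raise ValueError("distillation requires the teacher to be trained")


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    teacher_loss: float
    student_loss: float
    lpred_teacher: float
    lpred_student: float
    ltdm_teacher: float
    ltdm_student: float
    lg: float
    lb: float
    val_rmse_teacher: float
    val_mae_teacher: float
    val_rmse_student: float
    val_mae_student: float


@dataclass
class TrainHistory:
    epochs: list = field(default_factory=list)  # EpochRecord per epoch
    steps: list = field(default_factory=list)  # per-step loss component dicts
    simplex_ok: bool = True  # every alpha on the simplex at every step

    def epoch_frame(self):
        import pandas as pd
        return pd.DataFrame([asdict(e) for e in self.epochs])

    def step_frame(self):
        import pandas as pd
        return pd.DataFrame(self.steps)


class Adam:
    """Adam with optional global gradient-norm clipping."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self, clip_norm: float | None = None):
        grads = {k: (p.grad if p.grad is not None else np.zeros_like(p.data))
                 for k, p in self.params.items()}
        if clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if total > clip_norm:
                scale = clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            p.data -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def stratified_batches(n_per_period: list, batch: int, rng: np.random.Generator):
    """Yield index batches with every period represented proportionally.

    ``n_per_period[p]`` is the array of window indices owned by period p.
    Each period's (shuffled) indices are split into the same number of
    near-equal consecutive chunks; batch b is the concatenation of chunk b
    of every period, so an epoch covers all windows exactly once and each
    batch mixes all periods.
    """
    for p, idx in enumerate(n_per_period):
        if len(idx) == 0:
            raise ValueError(f"period {p} owns zero windows; cannot stratify")
    total = sum(len(idx) for idx in n_per_period)
    n_batches = max(int(np.ceil(total / batch)), 1)
    shuffled = [rng.permutation(idx) for idx in n_per_period]
    chunks = [np.array_split(s, n_batches) for s in shuffled]
    for b in range(n_batches):
        yield np.concatenate([c[b] for c in chunks])


def _period_indices(ws: WindowSet, seg: Segmentation) -> list:
    labels = assign_periods(ws.end_fractions, seg.boundaries)
    return [np.where(labels == p)[0] for p in range(seg.K)]


def _period_mean_hidden(bundle: md.FeatureBundle, rows_per_period: list) -> list:
    """Minibatch-mean hidden state per step for each period -> [(V, hidden)].

    Implemented as one averaging matmul over the flattened states, which is
    far cheaper on the tape than per-period row gathers.
    """
    B, V, h = bundle.hidden_states.shape
    sel = np.zeros((len(rows_per_period), B))
    for p, rows in enumerate(rows_per_period):
        sel[p, rows] = 1.0 / len(rows)
    flat = bundle.hidden_states.reshape((B, V * h))
    means = (ad.tensor(sel) @ flat).reshape((len(rows_per_period), V, h))
    return [means[p] for p in range(len(rows_per_period))]


def _check_simplex(alpha: np.ndarray) -> bool:
    return bool(np.all(alpha >= -1e-12) and abs(alpha.sum() - 1.0) < 1e-9)


def _evaluate(params, config, ws: WindowSet, norm: Normalizer, batch: int,
              teacher: bool):
    preds = predict(ws, params, config, norm, batch_size=batch, teacher=teacher)
    truth = norm.denorm_bis(ws.targets)
    err = preds - truth
    return float(np.sqrt(np.mean(err**2))), float(np.mean(np.abs(err)))


def train_joint(train_ws: WindowSet, val_ws: WindowSet, seg: Segmentation,
                student_cfg: md.NetworkConfig, teacher_cfg: md.NetworkConfig,
                cfg: TrainConfig, norm: Normalizer):
    """Train teacher and student simultaneously; returns (teacher params,
    student params, TrainHistory).

    ``train_ws``/``val_ws`` must already be normalized with ``norm``.
    """
    if teacher_cfg.input_channels != student_cfg.input_channels + 1:
        raise ValueError("teacher must have exactly one extra input channel")
    root = np.random.SeedSequence((cfg.seed, 0xE0))
    batch_rng = np.random.default_rng(root.spawn(1)[0])

    t_params = md.init_params(teacher_cfg)
    s_params = md.init_params(md.NetworkConfig(**{**student_cfg.__dict__, "seed": student_cfg.seed + 1}))
    pairs = list(itertools.combinations(range(seg.K), 2))
    t_imp = {p: tdm.init_importance_net(teacher_cfg.gru_hidden) for p in pairs}
    s_imp = {p: tdm.init_importance_net(student_cfg.gru_hidden) for p in pairs}

    V = train_ws.sequences.shape[1]
    # boosting-mode state: alphas and last epoch's per-state distances
    boost_alpha = {("t", p): tdm.init_importance(V) for p in pairs}
    boost_alpha.update({("s", p): tdm.init_importance(V) for p in pairs})
    boost_prev_dist: dict = {}
    boost_cur_dist: dict = {k: [] for k in boost_alpha}

    t_opt = Adam({**t_params, **{f"imp{p}.{k}": v for p in pairs for k, v in t_imp[p].items()}}, cfg.lr)
    s_opt = Adam({**s_params, **{f"imp{p}.{k}": v for p in pairs for k, v in s_imp[p].items()}}, cfg.lr)

    period_idx = _period_indices(train_ws, seg)
    history = TrainHistory()
    step = 0

    for epoch in range(cfg.epochs):
        lr = cfg.lr * cfg.decay_factor ** (epoch // cfg.decay_every)
        t_opt.lr = s_opt.lr = lr
        epoch_stats = {k: [] for k in ("lt", "ls", "lpt", "lps", "tdt", "tds", "lg", "lb")}

        for batch_idx in stratified_batches(period_idx, cfg.batch_train, batch_rng):
            labels = assign_periods(train_ws.end_fractions[batch_idx], seg.boundaries)
            seq = train_ws.sequences[batch_idx]
            prev = train_ws.prev_bis[batch_idx]
            stat = train_ws.statics[batch_idx]
            y = train_ws.targets[batch_idx]
            rows = [np.where(labels == p)[0] for p in range(seg.K)]
            if any(len(r) == 0 for r in rows):  # pragma: no cover - stratifier guarantees
                raise RuntimeError("stratified batch lost a period")

            t_bundle = (md.forward_teacher(t_params, teacher_cfg, seq, prev, stat)
                        if cfg.train_teacher else None)
            s_bundle = md.forward_student(s_params, student_cfg, seq, stat)

            def tdm_terms(bundle, imp_nets, who):
                means = _period_mean_hidden(bundle, rows)
                losses = []
                for (i, j) in pairs:
                    if cfg.importance_mode == "neural":
                        alpha = tdm.importance_net(means[i].detach(), means[j].detach(),
                                                   imp_nets[(i, j)])
                        if not _check_simplex(alpha.data):
                            history.simplex_ok = False
                    else:
                        alpha = ad.tensor(boost_alpha[(who, (i, j))])
                        if not _check_simplex(alpha.data):
                            history.simplex_ok = False
                        d = tdm.cosine_state_distance(means[i], means[j]).data
                        boost_cur_dist[(who, (i, j))].append(d)
                    losses.append(tdm.tdm_pair_loss(means[i], means[j], alpha))
                return losses

            def period_batches(pred):
                return [(pred[r], y[r]) for r in rows]

            lpred_t = (tdm.pred_loss(period_batches(t_bundle.prediction))
                       if cfg.train_teacher else ad.tensor(np.nan))
            lpred_s = tdm.pred_loss(period_batches(s_bundle.prediction))

            if cfg.tdm_enabled:
                pairs_t = tdm_terms(t_bundle, t_imp, "t") if cfg.train_teacher else []
                pairs_s = tdm_terms(s_bundle, s_imp, "s")
                lam = cfg.lam
            else:
                pairs_t = [ad.tensor(0.0) for _ in pairs] if cfg.train_teacher else []
                pairs_s = [ad.tensor(0.0) for _ in pairs]
                lam = 0.0

            loss_t = (tdm.combined_loss(lpred_t, pairs_t, lam, seg.K)
                      if cfg.train_teacher else ad.tensor(np.nan))

            if cfg.kd_enabled:
                lg = distill.gru_kd_loss(t_bundle, s_bundle)
                lb = distill.bottleneck_kd_loss(t_bundle, s_bundle)
            else:
                lg = ad.tensor(0.0)
                lb = ad.tensor(0.0)
            loss_s = distill.student_total_loss(lpred_s, pairs_s, lg, lb, lam, seg.K)

            checks = [("student", loss_s)] + ([("teacher", loss_t)] if cfg.train_teacher else [])
            for name, t in checks:
                if not np.isfinite(t.data):
                    raise FloatingPointError(f"non-finite {name} loss at step {step}")

            ad.zero_grads(t_opt.params)
            ad.zero_grads(s_opt.params)
            if cfg.train_teacher:
                ad.backward(loss_t)
            ad.backward(loss_s)
            if cfg.importance_mode == "neural" and cfg.tdm_enabled:
                # the evaluator plays the adversary: it moves toward the
                # weighting that exposes the largest distribution mismatch
                # (the same direction the boosting rule takes), while the
                # networks minimize under that weighting
                for nets in (t_imp, s_imp):
                    for net in nets.values():
                        for p in net.values():
                            if p.grad is not None:
                                p.grad = -p.grad
            if cfg.train_teacher:
                t_opt.step(cfg.grad_clip_norm)
            s_opt.step(cfg.grad_clip_norm)
            if cfg.weight_clip is not None:
                for p in (*t_params.values(), *s_params.values()):
                    np.clip(p.data, -cfg.weight_clip, cfg.weight_clip, out=p.data)

            vals = dict(
                step=step,
                lpred=float(lpred_s.data),
                ltdm_mean=float(np.mean([p.data for p in pairs_s])),
                lg=float(lg.data), lb=float(lb.data),
                total_teacher=float(loss_t.data), total_student=float(loss_s.data),
            )
            history.steps.append(vals)
            tdt = np.mean([p.data for p in pairs_t]) if pairs_t else np.nan
            for key, val in zip(("lt", "ls", "lpt", "lps", "tdt", "tds", "lg", "lb"),
                                (loss_t.data, loss_s.data, lpred_t.data, lpred_s.data,
                                 tdt, np.mean([p.data for p in pairs_s]), lg.data, lb.data)):
                epoch_stats[key].append(float(val))
            step += 1

        if cfg.importance_mode == "boosting":
            for key, dists in boost_cur_dist.items():
                if not dists:
                    continue
                cur = np.mean(dists, axis=0)
                if key in boost_prev_dist:
                    boost_alpha[key] = tdm.boosting_importance_update(
                        boost_alpha[key], cur, boost_prev_dist[key])
                    if not _check_simplex(boost_alpha[key]):
                        history.simplex_ok = False
                boost_prev_dist[key] = cur
                boost_cur_dist[key] = []

        do_eval = ((epoch + 1) % cfg.eval_every == 0) or (epoch == cfg.epochs - 1)
        vrt, vmt = (_evaluate(t_params, teacher_cfg, val_ws, norm, cfg.batch_eval, teacher=True)
                    if (cfg.train_teacher and do_eval) else (np.nan, np.nan))
        vrs, vms = (_evaluate(s_params, student_cfg, val_ws, norm, cfg.batch_eval, teacher=False)
                    if do_eval else (np.nan, np.nan))
        history.epochs.append(EpochRecord(
            epoch=epoch, lr=lr,
            teacher_loss=float(np.mean(epoch_stats["lt"])),
            student_loss=float(np.mean(epoch_stats["ls"])),
            lpred_teacher=float(np.mean(epoch_stats["lpt"])),
            lpred_student=float(np.mean(epoch_stats["lps"])),
            ltdm_teacher=float(np.mean(epoch_stats["tdt"])),
            ltdm_student=float(np.mean(epoch_stats["tds"])),
            lg=float(np.mean(epoch_stats["lg"])),
            lb=float(np.mean(epoch_stats["lb"])),
            val_rmse_teacher=vrt, val_mae_teacher=vmt,
            val_rmse_student=vrs, val_mae_student=vms,
        ))

    return t_params, s_params, history


def predict(ws: WindowSet, params: dict, config: md.NetworkConfig,
            norm: Normalizer, batch_size: int = 128, teacher: bool = False) -> np.ndarray:
    """De-normalized BIS predictions aligned to ``ws.window_end_times``.

    Works at any batch size down to 1 (the real-time contract); predictions
    are independent of the batching.
    """
    if norm is None:
        raise ValueError("normalization stats are required for prediction")
    out = np.empty(len(ws))
    for lo in range(0, len(ws), batch_size):
        sl = slice(lo, min(lo + batch_size, len(ws)))
        if teacher:
            bundle = md.forward_teacher(params, config, ws.sequences[sl],
                                        ws.prev_bis[sl], ws.statics[sl])
        else:
            bundle = md.forward_student(params, config, ws.sequences[sl], ws.statics[sl])
        out[sl] = bundle.prediction.data
    return norm.denorm_bis(out)
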