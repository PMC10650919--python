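"""Desk-scale experiment drivers on the synthetic cohort.

These functions run the full method end to end in memory and return the
quantities the package's empirical claims rest on: that training converges,
that the teacher (which sees the previous-bin BIS) outperforms the student,
and that distribution matching plus distillation improves the student over
a plain dose-only GRU regressor under cross-patient covariate shift.

Problem sizes are chosen for a single desktop CPU: 40 patients per cohort,
GRU width 32, 30 epochs; one full-vs-ablation comparison takes a few
minutes per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evalmetrics as em, model as md, preprocess as pp
from . import synthcase as sc, tdc, train as tr
from .pipeline import build_windows, split_cases

__all__ = ["SeedOutcome", "prepare_cohort_splits", "run_learning_experiment",
           "two_regime_features", "tdc_oracle_study"]


def two_regime_features(rng: np.random.Generator, n: int = 200, shift_at: float = 0.5,
                        dim: int = 4, gap: float = 2.0, noise: float = 0.1):
    """Synthetic feature series with a mean shift at a normalized position."""
    positions = np.linspace(0, 1, n)
    m1 = np.abs(rng.normal(1.0, 0.3, dim)) + 0.5
    m2 = m1 + gap * np.abs(rng.normal(0.5, 0.2, dim))
    feats = np.where(positions[:, None] < shift_at, m1, m2) + rng.normal(0, noise, (n, dim))
    return np.abs(feats), positions


def tdc_oracle_study(n_instances: int = 100, seed: int = 0,
                     n_candidates: int = 12) -> dict:
    """Greedy vs exhaustive segmentation on random two-regime series.

    For each instance (K alternating 2 and 3) the greedy solution is
    compared against the brute-force optimum over the same candidate grid
    and against the grid-aligned equal split.
    """
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x7DC)))
    hits = 0
    never_worse = True
    for i in range(n_instances):
        feats, pos = two_regime_features(rng, shift_at=rng.uniform(0.2, 0.8))
        K = 2 + (i % 2)
        g = tdc.tdc_greedy(feats, pos, K=K, n_candidates=n_candidates, dmin=0.0)
        b = tdc.tdc_bruteforce(feats, pos, K=K, n_candidates=n_candidates, dmin=0.0)
        if abs(g.objective - b.objective) <= 1e-12:
            hits += 1
        grid = np.arange(1, n_candidates) / n_candidates
        eq = tuple(float(grid[np.argmin(np.abs(grid - j / K))]) for j in range(1, K))
        if g.objective < tdc.objective(eq, feats, pos) - 1e-12:
            never_worse = False
    return {"optimal_rate": hits / n_instances, "never_worse_than_equal_split": never_worse,
            "n": n_instances}


@dataclass
class SeedOutcome:
    seed: int
    epoch_losses_full: list  # per-epoch mean student loss, full model
    test_rmse_full: float  # student, TDM+KD
    test_rmse_ablation: float  # student, no TDM / no KD
    test_rmse_teacher: float
    simplex_ok_full: bool
    simplex_ok_ablation: bool


def prepare_cohort_splits(seed: int, n_cases: int = 40, duration: int = 2400,
                          split=(0.5, 0.25, 0.25), K: int = 5):
    """Simulate a shifted cohort and return normalized window splits.

    All cases carry the benign defect menu (BIS noise, one short gap, one
    dose glitch), which the cleaning stage repairs; the covariate trends of
    the generator supply the cross-patient distribution shift.
    """
    cases, _ = sc.generate_cohort(n_cases, seed, duration=duration)
    roles = split_cases([c.case_id for c in cases], split,
                        np.random.default_rng(np.random.SeedSequence((seed, 7))))
    cleans = {r: [] for r in ("train", "validation", "test")}
    for case in cases:
        keep, _ = pp.eligibility_filter(case)
        if keep:  # the benign menu never plants a violation
            role = roles[case.case_id]
            cleans[role].append(pp.clean_case(case, role))
    raw_train = build_windows(cleans["train"])
    norm = pp.Normalizer.fit(raw_train)
    seg = tdc.segment_windows(raw_train, K=K)
    return {
        "train": norm.transform(raw_train),
        "validation": norm.transform(build_windows(cleans["validation"])),
        "test_cleans": cleans["test"],
        "norm": norm,
        "seg": seg,
    }


def _test_rmse(cleans, params, net_cfg, norm, teacher: bool) -> float:
    errs = []
    for clean in cleans:
        ws = pp.make_windows(clean)
        preds = tr.predict(norm.transform(ws), params, net_cfg, norm,
                           batch_size=128, teacher=teacher)
        errs.append(em.rmse_mae(ws.targets, preds)[0])
    return float(np.mean(errs))


def run_one_seed(seed: int, n_cases: int = 40, epochs: int = 30,
                 gru_hidden: int = 32, K: int = 5, lam: float = 0.05,
                 importance_mode: str = "neural") -> SeedOutcome:
    """Full model vs no-TDM/no-KD ablation on one simulated cohort."""
    data = prepare_cohort_splits(seed, n_cases=n_cases, K=K)
    s_cfg = md.NetworkConfig(2, gru_hidden, 1, (64, 32), 4, seed=seed)
    t_cfg = md.NetworkConfig(3, gru_hidden, 1, (64, 32), 4, seed=seed)

    full_cfg = tr.TrainConfig(epochs=epochs, lam=lam, seed=seed, eval_every=10,
                              importance_mode=importance_mode)
    t_params, s_params, hist_full = tr.train_joint(
        data["train"], data["validation"], data["seg"], s_cfg, t_cfg, full_cfg, data["norm"])

    abl_cfg = tr.TrainConfig(epochs=epochs, lam=lam, seed=seed, eval_every=10,
                             kd_enabled=False, tdm_enabled=False, train_teacher=False)
    _, s_params_abl, hist_abl = tr.train_joint(
        data["train"], data["validation"], data["seg"], s_cfg, t_cfg, abl_cfg, data["norm"])

    return SeedOutcome(
        seed=seed,
        epoch_losses_full=[e.student_loss for e in hist_full.epochs],
        test_rmse_full=_test_rmse(data["test_cleans"], s_params, s_cfg, data["norm"], False),
        test_rmse_ablation=_test_rmse(data["test_cleans"], s_params_abl, s_cfg,
                                      data["norm"], False),
        test_rmse_teacher=_test_rmse(data["test_cleans"], t_params, t_cfg, data["norm"], True),
        simplex_ok_full=hist_full.simplex_ok,
        simplex_ok_ablation=hist_abl.simplex_ok,
    )


def run_learning_experiment(base_seed: int = 0, n_seeds: int = 5, **kw) -> dict:
    """The multi-seed comparison; returns per-seed outcomes and medians."""
    seeds = [int(np.random.SeedSequence((int(base_seed), i)).generate_state(1)[0] % (2**31))
             for i in range(n_seeds)]
    outcomes = [run_one_seed(s, **kw) for s in seeds]
    return {
        "outcomes": outcomes,
        "median_rmse_full": float(np.median([o.test_rmse_full for o in outcomes])),
        "median_rmse_ablation": float(np.median([o.test_rmse_ablation for o in outcomes])),
        "median_rmse_teacher": float(np.median([o.test_rmse_teacher for o in outcomes])),
        "loss_decreased_all_seeds": all(o.epoch_losses_full[4] < o.epoch_losses_full[0]
                                        for o in outcomes),
        "simplex_ok": all(o.simplex_ok_full and o.simplex_ok_ablation for o in outcomes),
    }
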