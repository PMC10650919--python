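"""Temporal distribution characterization.

Splits the normalized training timeline [0, 1] into K periods that are
maximally dissimilar: the segmentation maximizes the mean pairwise distance

    J(D_1..D_K) = (1/K) * sum_{i != j} d(D_i, D_j)

subject to per-period length bounds, where a period is summarized by the
mean feature vector of the windows whose (relative) end position falls in
it, and d is cosine distance by default.  Training on maximally dissimilar
periods exposes the model to the worst-case distribution shift inside the
training data, which is the shift it must survive across patients.

Boundaries are restricted to a small candidate grid (tenths of the timeline
by default).  ``tdc_greedy`` inserts one boundary at a time, keeping the
insertion that maximizes the objective; ``tdc_bruteforce`` enumerates every
admissible boundary subset and serves as the exact oracle on small grids.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceConfig",
    "Segmentation",
    "period_distance",
    "assign_periods",
    "period_summaries",
    "objective",
    "tdc_greedy",
    "tdc_bruteforce",
    "segment_windows",
]

_METRICS = {}


def _register(name):
    def deco(fn):
        _METRICS[name] = fn
        return fn
    return deco


@_register("cosine")
def _cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for a zero summary vector")
    return float(1.0 - (u @ v) / (nu * nv))


@dataclass(frozen=True)
class DistanceConfig:
    metric: str = "cosine"

    def distance(self, u, v) -> float:
        if self.metric not in _METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; registered: {sorted(_METRICS)}")
        return _METRICS[self.metric](np.asarray(u, float), np.asarray(v, float))


@dataclass(frozen=True)
class Segmentation:
    """K periods of normalized time, defined by K-1 interior boundaries."""

    boundaries: tuple  # strictly increasing fractions in (0, 1)
    K: int
    objective: float
    metric: str = "cosine"

    def __post_init__(self):
        b = np.asarray(self.boundaries, float)
        if len(b) != self.K - 1:
            raise ValueError("need exactly K-1 boundaries")
        if b.size and (np.any(np.diff(b) <= 0) or b[0] <= 0 or b[-1] >= 1):
            raise ValueError("boundaries must be strictly increasing inside (0, 1)")

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate([[0.0], self.boundaries, [1.0]])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"boundaries": list(self.boundaries), "K": self.K,
                       "objective": self.objective, "metric": self.metric}, fh, indent=2)

    @staticmethod
    def from_json(path) -> "Segmentation":
        with open(path) as fh:
            d = json.load(fh)
        return Segmentation(tuple(d["boundaries"]), int(d["K"]),
                            float(d["objective"]), d.get("metric", "cosine"))


def period_distance(u, v, config: DistanceConfig = DistanceConfig()) -> float:
    """Distance between two period summary vectors (cosine by default)."""
    u, v = np.asarray(u, float), np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("summary vectors must have equal length")
    return config.distance(u, v)


def assign_periods(positions: np.ndarray, boundaries) -> np.ndarray:
    """Period index of each normalized position; period i is [b_{i-1}, b_i),
    with the last period closed at 1."""
    edges = np.concatenate([boundaries, [np.inf]])
    return np.searchsorted(edges, np.asarray(positions, float), side="right")


def period_summaries(features: np.ndarray, positions: np.ndarray, boundaries) -> np.ndarray:
    """Per-period mean feature vector; raises if any period is empty."""
    labels = assign_periods(positions, boundaries)
    k = len(boundaries) + 1
    out = np.empty((k, features.shape[1]))
    for i in range(k):
        mask = labels == i
        if not mask.any():
            raise ValueError(f"period {i} of segmentation {list(boundaries)} is empty")
        out[i] = features[mask].mean(axis=0)
    return out


def objective(boundaries, features: np.ndarray, positions: np.ndarray,
              config: DistanceConfig = DistanceConfig()) -> float:
    """Mean pairwise period distance (1/K) * sum_{i != j} d(D_i, D_j)."""
    summaries = period_summaries(features, positions, boundaries)
    k = len(summaries)
    total = 0.0
    for i, j in itertools.combinations(range(k), 2):
        total += 2.0 * period_distance(summaries[i], summaries[j], config)
    return total / k


def _candidate_grid(n_candidates: int) -> np.ndarray:
    return np.arange(1, n_candidates) / n_candidates


def _lengths_ok(boundaries, dmin, dmax) -> bool:
    edges = np.concatenate([[0.0], boundaries, [1.0]])
    lengths = np.diff(edges)
    return bool(np.all(lengths >= dmin - 1e-12) and np.all(lengths <= dmax + 1e-12))


def tdc_greedy(features: np.ndarray, positions: np.ndarray, K: int,
               n_candidates: int = 10, dmin: float = 0.1, dmax: float = 1.0,
               config: DistanceConfig = DistanceConfig()) -> Segmentation:
    """Greedy boundary insertion on the candidate grid.

    Starts from the undivided timeline and repeatedly inserts the candidate
    boundary whose resulting segmentation has the highest objective, until K
    periods exist.  Ties break to the lowest candidate index, making the
    solver deterministic.  The objective at the final size never decreases
    across the insertions that reach it.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if n_candidates < K:
        raise ValueError("need at least K candidate chunks")
    if dmin * K > 1.0 + 1e-12:
        raise ValueError(f"infeasible: K={K} periods of at least {dmin} exceed the timeline")
    grid = _candidate_grid(n_candidates)
    chosen: list[float] = []
    for _ in range(K - 1):
        best = None
        for b in grid:
            if any(abs(b - c) < 1e-12 for c in chosen):
                continue
            trial = tuple(sorted(chosen + [b]))
            if len(trial) == K - 1 and not _lengths_ok(trial, dmin, dmax):
                continue
            # interim sizes only need non-empty periods
            try:
                val = objective(trial, features, positions, config)
            except ValueError:
                continue
            if best is None or val > best[0] + 1e-15:
                best = (val, b)
        if best is None:
            raise ValueError("no admissible boundary insertion; relax length bounds or grid")
        chosen = sorted(chosen + [best[1]])
    final = objective(tuple(chosen), features, positions, config)
    return Segmentation(tuple(chosen), K, final, config.metric)


def tdc_bruteforce(features: np.ndarray, positions: np.ndarray, K: int,
                   n_candidates: int = 10, dmin: float = 0.1, dmax: float = 1.0,
                   config: DistanceConfig = DistanceConfig()) -> Segmentation:
    """Exhaustive optimum over the candidate grid (test oracle; small grids only)."""
    grid = _candidate_grid(n_candidates)
    if len(grid) > 15:
        raise ValueError("brute-force oracle limited to <= 15 candidate boundaries")
    best = None
    for combo in itertools.combinations(grid, K - 1):
        if not _lengths_ok(combo, dmin, dmax):
            continue
        try:
            val = objective(combo, features, positions, config)
        except ValueError:
            continue
        if best is None or val > best[0] + 1e-15:
            best = (val, combo)
    if best is None:
        raise ValueError("no admissible segmentation on the candidate grid")
    return Segmentation(tuple(best[1]), K, best[0], config.metric)


def window_features(window_set) -> np.ndarray:
    """Feature vector distanced by TDC for each window: mean and final
    incremental doses of both drugs over the window."""
    seq = window_set.sequences
    return np.column_stack([
        seq.mean(axis=1),  # (n, 2)
        seq[:, -1, :],  # (n, 2)
    ])


def segment_windows(window_set, K: int = 5, n_candidates: int = 10,
                    dmin: float = 0.1, dmax: float = 1.0,
                    config: DistanceConfig = DistanceConfig()) -> Segmentation:
    """TDC over a training WindowSet on the normalized per-case time axis."""
    feats = window_features(window_set)
    return tdc_greedy(feats, window_set.end_fractions, K, n_candidates, dmin, dmax, config)
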