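"""Case cleaning and windowing.

The cleaning rules mirror standard TCI-record hygiene for infusion-pump /
BIS exports:

* discard a case if (a) BIS at the start of drug infusion is below 80,
  (b) any channel is missing for more than 300 s, or (c) the first recorded
  BIS occurs when the cumulative infused drug is nonzero;
* linearly interpolate remaining missing values;
* repair non-monotone cumulative-dose samples with the mean of the
  neighbouring moments;
* LOWESS-smooth the BIS of *training* cases only (frac 0.03); validation
  and test BIS stay untouched;
* resample to one point per 10 s — pump records update on that cadence —
  taking the incremental dose per 10-s bin as the dynamic feature;
* slide a 120-step window (stride 1) to produce model-ready sequences with
  the window-end BIS as target and the previous-bin BIS as the teacher's
  extra channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .synthcase import CaseRecord

__all__ = [
    "CleanCase",
    "WindowSet",
    "eligibility_filter",
    "fill_missing",
    "repair_cumulative",
    "smooth_bis",
    "resample_10s",
    "make_windows",
    "Normalizer",
    "clean_case",
]

MAX_GAP_S = 300
START_BIS_MIN = 80.0
WINDOW_LEN = 120
LOWESS_FRAC = 0.03


@dataclass
class CleanCase:
    """10-s-grid model-ready case."""

    case_id: str
    t10: np.ndarray  # s, bin-endpoint timestamps
    prop_inc: np.ndarray  # mg per 10-s bin
    remi_inc: np.ndarray  # µg per 10-s bin
    bis10: np.ndarray  # BIS at bin endpoints (smoothed iff role == "train")
    covariates: np.ndarray  # (age, sex01, height, weight)
    role: str  # {train, validation, test}
    infusion_start: int
    infusion_stop: int

    def validate(self) -> None:
        if np.any(np.isnan(self.prop_inc)) or np.any(np.isnan(self.remi_inc)) or np.any(np.isnan(self.bis10)):
            raise ValueError("clean case must have no missing values")
        if self.prop_inc.min() < 0 or self.remi_inc.min() < 0:
            raise ValueError("incremental doses must be nonnegative")
        if self.bis10.min() < 0 or self.bis10.max() > 100:
            raise ValueError("bis10 must lie in [0, 100]")


@dataclass
class WindowSet:
    """Sliding windows over one or more clean cases."""

    sequences: np.ndarray  # (n, 120, 2) incremental doses
    prev_bis: np.ndarray  # (n, 120) previous-bin BIS (teacher channel)
    statics: np.ndarray  # (n, 4) covariates
    targets: np.ndarray  # (n,) BIS at window end
    case_ids: np.ndarray  # (n,) str
    window_end_times: np.ndarray  # (n,) s
    end_fractions: np.ndarray  # (n,) window-end position in [0, 1] within its case

    def __len__(self) -> int:
        return len(self.targets)

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        return WindowSet(*(np.concatenate([getattr(w, f) for w in sets])
                           for f in ("sequences", "prev_bis", "statics", "targets",
                                     "case_ids", "window_end_times", "end_fractions")))


def _missing_runs(x: np.ndarray):
    """(start, length) of each maximal NaN run."""
    isnan = np.isnan(x)
    runs = []
    i = 0
    n = len(x)
    while i < n:
        if isnan[i]:
            j = i
            while j < n and isnan[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def eligibility_filter(case: CaseRecord):
    """Apply the discard rules; returns ``(keep, reason)``.

    ``reason`` is ``"ok"`` for kept cases, else the first violated rule among
    ``start_bis`` / ``long_gap`` / ``dose_before_bis``.
    """
    present = ~np.isnan(case.bis)
    if not present.any():
        raise ValueError(f"{case.case_id}: record has no BIS samples at all")

    # (a) BIS at the start of drug infusion below 80 (most recent present
    # value at or before the start of infusion, if any)
    i0 = int(case.infusion_start)
    before = np.where(present[: i0 + 1])[0]
    if before.size and case.bis[before[-1]] < START_BIS_MIN:
        return False, "start_bis"

    # (b) any channel missing for more than 300 s; the rules cover the span
    # from the start of drug infusion to the end of the BIS measurement, so
    # gaps in any pre-infusion baseline do not count
    span = slice(i0, len(case.t))
    for ch in (case.bis, case.prop_cum, case.remi_cum):
        if any(length > MAX_GAP_S for _, length in _missing_runs(ch[span])):
            return False, "long_gap"

    # (c) first recorded BIS while the cumulative infused drug is nonzero
    first_bis = int(np.argmax(present))
    total_cum = np.nan_to_num(case.prop_cum[first_bis]) + np.nan_to_num(case.remi_cum[first_bis])
    if total_cum != 0:
        return False, "dose_before_bis"

    return True, "ok"


def fill_missing(case: CaseRecord) -> CaseRecord:
    """Linear interpolation of NaN runs in every channel; present values kept."""
    out = case.copy()
    for name in ("prop_cum", "remi_cum", "bis"):
        x = getattr(out, name)
        nan = np.isnan(x)
        if not nan.any():
            continue
        if nan[0] or nan[-1]:
            raise ValueError(f"{case.case_id}: {name} missing at a record boundary; cannot interpolate")
        idx = np.where(~nan)[0]
        x[nan] = np.interp(np.where(nan)[0], idx, x[idx])
    return out


def repair_cumulative(case: CaseRecord) -> CaseRecord:
    """Make cumulative channels nondecreasing.

    Each sample lower than its predecessor is replaced by the mean of its
    immediate neighbours; the pass iterates to a fixed point (bounded by the
    series length) since one replacement can expose another decrease.
    """
    out = case.copy()
    for name in ("prop_cum", "remi_cum"):
        x = getattr(out, name)
        if np.any(np.isnan(x)):
            raise ValueError("repair_cumulative requires a gap-free record (run fill_missing first)")
        for _ in range(len(x)):
            drops = np.where(np.diff(x) < 0)[0] + 1
            if drops.size == 0:
                break
            i = int(drops[0])
            if i >= len(x) - 1:
                raise ValueError(f"{case.case_id}: {name} decreases at the last sample (index {i}); no right neighbour")
            x[i] = 0.5 * (x[i - 1] + x[i + 1])
        if np.any(np.diff(x) < 0):
            raise ValueError(f"{case.case_id}: {name} could not be repaired to a nondecreasing series")
    return out


def smooth_bis(bis: np.ndarray, frac: float = LOWESS_FRAC) -> np.ndarray:
    """LOWESS fit of a 1-Hz BIS series at its own abscissae."""
    if not (0 < frac <= 1):
        raise ValueError("frac must lie in (0, 1]")
    if len(bis) * frac < 2:
        raise ValueError(f"series of {len(bis)} points too short for frac={frac}")
    t = np.arange(len(bis), dtype=float)
    return lowess(bis, t, frac=frac, return_sorted=False)


def resample_10s(case: CaseRecord, role: str = "train", smooth: bool | None = None) -> CleanCase:
    """10-s resampling of a gap-free, repaired 1-Hz record.

    Bin endpoints are every 10th sample; incremental doses are differences
    of the cumulative channels between consecutive endpoints (the first bin
    is differenced against the infusion-start value, zero for records that
    begin before any drug is given).  Training-role BIS is LOWESS-smoothed
    first unless ``smooth`` overrides.
    """
    if len(case.t) < 11:
        raise ValueError("record shorter than one 10-s bin")
    for ch in (case.prop_cum, case.remi_cum, case.bis):
        if np.any(np.isnan(ch)):
            raise ValueError("resample_10s requires a gap-free record")
    if smooth is None:
        smooth = role == "train"
    bis = smooth_bis(case.bis) if smooth else case.bis

    sel = np.arange(0, len(case.t), 10)
    # reference for the first bin: the cumulative value at infusion onset
    # (the sample just before the first dosed second; zero for records that
    # begin before any drug is given — the usual layout)
    ref = max(min(int(case.infusion_start), len(case.t) - 1) - 1, 0)
    prop = case.prop_cum[sel]
    remi = case.remi_cum[sel]
    prop_inc = np.diff(prop, prepend=min(case.prop_cum[ref], prop[0]))
    remi_inc = np.diff(remi, prepend=min(case.remi_cum[ref], remi[0]))
    clean = CleanCase(
        case_id=case.case_id,
        t10=case.t[sel],
        prop_inc=np.clip(prop_inc, 0.0, None),
        remi_inc=np.clip(remi_inc, 0.0, None),
        bis10=np.clip(bis[sel], 0.0, 100.0),
        covariates=case.covariates,
        role=role,
        infusion_start=case.infusion_start,
        infusion_stop=case.infusion_stop,
    )
    clean.validate()
    return clean


def clean_case(case: CaseRecord, role: str) -> CleanCase:
    """fill -> repair -> (smooth) -> resample, for an eligible case."""
    return resample_10s(repair_cumulative(fill_missing(case)), role=role)


def make_windows(clean: CleanCase, length: int = WINDOW_LEN, stride: int = 1) -> WindowSet:
    """Slide a ``length``-step window over the 10-s bins.

    The previous-BIS channel at window step t is ``bis10[s + t - 1]`` in the
    case timeline, so the first admissible window starts at bin 1; a case of
    N bins yields N - length windows at stride 1.
    """
    n = len(clean.t10)
    starts = np.arange(1, n - length + 1, stride)
    if starts.size == 0:
        warnings.warn(f"{clean.case_id}: fewer than {length + 1} bins; no windows produced")
        empty = lambda *shape: np.empty(shape)
        return WindowSet(empty(0, length, 2), empty(0, length), empty(0, 4),
                         empty(0), np.empty(0, dtype=object), empty(0), empty(0))
    seq = np.stack([
        np.stack([clean.prop_inc[s: s + length], clean.remi_inc[s: s + length]], axis=1)
        for s in starts
    ])
    prev = np.stack([clean.bis10[s - 1: s + length - 1] for s in starts])
    ends = starts + length - 1
    # normalized position of each prediction within the case's span of
    # admissible window ends — the timeline the segmentation step divides
    span = max(ends[-1] - ends[0], 1)
    return WindowSet(
        sequences=seq,
        prev_bis=prev,
        statics=np.tile(clean.covariates, (len(starts), 1)),
        targets=clean.bis10[ends],
        case_ids=np.array([clean.case_id] * len(starts), dtype=object),
        window_end_times=clean.t10[ends],
        end_fractions=(ends - ends[0]) / span,
    )


@dataclass
class Normalizer:
    """Per-feature z-scores fitted on the training split only."""

    seq_mean: np.ndarray
    seq_sd: np.ndarray
    stat_mean: np.ndarray
    stat_sd: np.ndarray
    bis_mean: float
    bis_sd: float

    @staticmethod
    def fit(train: WindowSet) -> "Normalizer":
        seq = train.sequences.reshape(-1, train.sequences.shape[-1])
        return Normalizer(
            seq_mean=seq.mean(axis=0),
            seq_sd=np.maximum(seq.std(axis=0), 1e-8),
            stat_mean=train.statics.mean(axis=0),
            stat_sd=np.maximum(train.statics.std(axis=0), 1e-8),
            bis_mean=float(train.targets.mean()),
            bis_sd=max(float(train.targets.std()), 1e-8),
        )

    def transform(self, ws: WindowSet) -> WindowSet:
        return WindowSet(
            sequences=(ws.sequences - self.seq_mean) / self.seq_sd,
            prev_bis=(ws.prev_bis - self.bis_mean) / self.bis_sd,
            statics=(ws.statics - self.stat_mean) / self.stat_sd,
            targets=(ws.targets - self.bis_mean) / self.bis_sd,
            case_ids=ws.case_ids,
            window_end_times=ws.window_end_times,
            end_fractions=ws.end_fractions,
        )

    def denorm_bis(self, y: np.ndarray) -> np.ndarray:
        return y * self.bis_sd + self.bis_mean

    def to_dict(self) -> dict:
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()}

    @staticmethod
    def from_dict(d: dict) -> "Normalizer":
        return Normalizer(
            seq_mean=np.asarray(d["seq_mean"]), seq_sd=np.asarray(d["seq_sd"]),
            stat_mean=np.asarray(d["stat_mean"]), stat_sd=np.asarray(d["stat_sd"]),
            bis_mean=float(d["bis_mean"]), bis_sd=float(d["bis_sd"]),
        )
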