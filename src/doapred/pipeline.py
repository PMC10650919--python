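"""End-to-end pipeline: simulate -> preprocess -> segment -> train -> evaluate.

Each stage writes its artifacts under the run directory and the manifest
records stage seeds and SHA-256 digests of every file, so two runs from the
same root seed can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import caseio, evalmetrics as em, model as md, preprocess as pp
from . import synthcase as sc, tdc, train as tr
from .config import RunConfig

__all__ = ["run_pipeline", "split_cases", "build_windows", "save_windowset",
           "load_windowset", "PipelineResult"]


def _substream(root_seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(root_seed), int(tag))))


def split_cases(case_ids: list, fractions, rng: np.random.Generator) -> dict:
    """Random case-level role assignment honouring the split fractions."""
    ids = list(case_ids)
    order = rng.permutation(len(ids))
    n_train = int(round(fractions[0] * len(ids)))
    n_val = int(round(fractions[1] * len(ids)))
    roles = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            roles[ids[idx]] = "train"
        elif rank < n_train + n_val:
            roles[ids[idx]] = "validation"
        else:
            roles[ids[idx]] = "test"
    return roles


def build_windows(cleans: list, length: int = 120, stride: int = 1) -> pp.WindowSet:
    sets = [pp.make_windows(c, length=length, stride=stride) for c in cleans]
    sets = [s for s in sets if len(s)]
    if not sets:
        raise ValueError("no case produced any windows")
    return pp.WindowSet.concatenate(sets)


def save_windowset(ws: pp.WindowSet, path) -> None:
    np.savez(path, sequences=ws.sequences, prev_bis=ws.prev_bis, statics=ws.statics,
             targets=ws.targets, case_ids=ws.case_ids.astype(str),
             window_end_times=ws.window_end_times, end_fractions=ws.end_fractions)


def load_windowset(path) -> pp.WindowSet:
    with np.load(path, allow_pickle=False) as z:
        return pp.WindowSet(z["sequences"], z["prev_bis"], z["statics"], z["targets"],
                            z["case_ids"].astype(object), z["window_end_times"],
                            z["end_fractions"])


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    report: pd.DataFrame
    manifest: dict
    history: tr.TrainHistory
    out_dir: Path


def run_pipeline(cfg: RunConfig, out_dir) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "digests": {}}

    # -- simulate ---------------------------------------------------------
    sim_seed = int(np.random.SeedSequence((cfg.seed, 1)).generate_state(1)[0] % (2**31))
    noise_menu = {
        i: sc.NoiseConfig(bis_sd=cfg.simulate.noise_bis_sd,
                          missing_gap_lengths=(cfg.simulate.noise_gap_s,),
                          glitch_count=cfg.simulate.noise_glitches)
        for i in range(cfg.simulate.n)
    }
    cases, metas = sc.generate_cohort(cfg.simulate.n, sim_seed,
                                      shift_config=cfg.simulate.shift or None,
                                      noise_menu=noise_menu,
                                      duration=cfg.simulate.duration)
    case_dir = out / "cases"
    caseio.write_cohort(cases, metas, case_dir)
    manifest["stages"]["simulate"] = {"seed": sim_seed, "n": len(cases)}

    # -- preprocess -------------------------------------------------------
    filter_rows = []
    kept = []
    for case in cases:
        keep, reason = pp.eligibility_filter(case)
        filter_rows.append({"case_id": case.case_id, "kept": keep, "reason": reason})
        if keep:
            kept.append(case)
    pd.DataFrame(filter_rows).to_csv(out / "filter_report.csv", index=False)
    if len(kept) < 3:
        raise RuntimeError("pipeline needs at least 3 eligible cases")

    roles = split_cases([c.case_id for c in kept], cfg.preprocess.split,
                        _substream(cfg.seed, 2))
    cleans = {r: [] for r in ("train", "validation", "test")}
    for case in kept:
        role = roles[case.case_id]
        cleans[role].append(pp.clean_case(case, role))
    length, stride = cfg.preprocess.window_length, cfg.preprocess.stride
    raw_train = build_windows(cleans["train"], length, stride)
    raw_val = build_windows(cleans["validation"], length, stride)
    raw_test = build_windows(cleans["test"], length, stride)
    norm = pp.Normalizer.fit(raw_train)
    with open(out / "normalizer.json", "w") as fh:
        json.dump(norm.to_dict(), fh)
    train_ws = norm.transform(raw_train)
    val_ws = norm.transform(raw_val)
    manifest["stages"]["preprocess"] = {
        "kept": len(kept),
        "roles": {r: sorted(c.case_id for c in cleans[r]) for r in cleans},
        "windows": {"train": len(raw_train), "validation": len(raw_val),
                    "test": len(raw_test)},
    }

    # -- temporal distribution characterization ---------------------------
    seg = tdc.segment_windows(raw_train, K=cfg.tdc.K, n_candidates=cfg.tdc.n_candidates,
                              dmin=cfg.tdc.dmin, dmax=cfg.tdc.dmax,
                              config=tdc.DistanceConfig(cfg.tdc.metric))
    seg.to_json(out / "segmentation.json")
    manifest["stages"]["tdc"] = {"boundaries": list(seg.boundaries),
                                 "objective": seg.objective}

    # -- train ------------------------------------------------------------
    m = cfg.model
    student_cfg = md.NetworkConfig(2, m.gru_hidden, m.gru_layers,
                                   tuple(m.bottleneck_widths), 4, seed=cfg.seed)
    teacher_cfg = md.NetworkConfig(3, m.gru_hidden, m.gru_layers,
                                   tuple(m.bottleneck_widths), 4, seed=cfg.seed)
    t = cfg.train
    tcfg = tr.TrainConfig(lr=t.lr, decay_every=t.decay_every, decay_factor=t.decay_factor,
                          batch_train=t.batch_train, batch_eval=t.batch_eval, lam=t.lam,
                          epochs=t.epochs, grad_clip_norm=t.grad_clip_norm, seed=cfg.seed,
                          importance_mode=t.importance_mode, kd_enabled=t.kd_enabled,
                          tdm_enabled=t.tdm_enabled, train_teacher=t.train_teacher)
    t_params, s_params, history = tr.train_joint(train_ws, val_ws, seg,
                                                 student_cfg, teacher_cfg, tcfg, norm)
    if tcfg.train_teacher:
        md.save_checkpoint(out / "teacher.ckpt", t_params, teacher_cfg)
    md.save_checkpoint(out / "student.ckpt", s_params, student_cfg)
    history.epoch_frame().to_csv(out / "history_epochs.csv", index=False)
    history.step_frame().to_csv(out / "training_log.csv", index=False)
    manifest["stages"]["train"] = {
        "final_val_rmse_student": history.epochs[-1].val_rmse_student,
        "final_val_rmse_teacher": history.epochs[-1].val_rmse_teacher,
        "simplex_ok": history.simplex_ok,
    }

    # -- evaluate on the held-out test cases ------------------------------
    pred_rows = []
    eval_cases = []
    for clean in cleans["test"]:
        ws = pp.make_windows(clean, length, stride)
        if not len(ws):
            continue
        preds = tr.predict(norm.transform(ws), s_params, student_cfg, norm,
                           batch_size=t.batch_eval)
        labels = em.label_periods(ws.window_end_times, clean.infusion_start,
                                  clean.infusion_stop)
        eval_cases.append({"case_id": clean.case_id, "measured": ws.targets,
                           "predicted": preds, "labels": labels})
        for tt, pr in zip(ws.window_end_times, preds):
            pred_rows.append({"case_id": clean.case_id, "time_s": tt, "bis_pred": pr})
    pd.DataFrame(pred_rows).to_csv(out / "predictions.csv", index=False)
    report = em.report(eval_cases)
    report.to_csv(out / "report.csv", index=False)
    row = report[(report.metric == "RMSE") & (report.period == "All")].iloc[0]
    manifest["stages"]["evaluate"] = {"test_rmse_mean": float(row["mean"]),
                                      "n_test_cases": int(row["n_cases"])}

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["digests"][str(f.relative_to(out))] = _digest(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(report=report, manifest=manifest, history=history, out_dir=out)
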