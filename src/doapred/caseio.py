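"""Case CSV dialect (VitalDB-track-like) and cohort manifests.

One row per second with columns
``time_s, prop_cum_mg, remi_cum_ug, bis, age, sex, height_cm, weight_kg,
infusion_start_s, infusion_stop_s``; static columns are repeated on every
row and missing marks are empty cells (never zero).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthcase import CaseRecord

COLUMNS = [
    "time_s", "prop_cum_mg", "remi_cum_ug", "bis",
    "age", "sex", "height_cm", "weight_kg",
    "infusion_start_s", "infusion_stop_s",
]


def write_case_csv(case: CaseRecord, path) -> None:
    case.validate()
    df = pd.DataFrame({
        "time_s": case.t.astype(int),
        "prop_cum_mg": case.prop_cum,
        "remi_cum_ug": case.remi_cum,
        "bis": case.bis,
        "age": case.age,
        "sex": case.sex,
        "height_cm": case.height,
        "weight_kg": case.weight,
        "infusion_start_s": case.infusion_start,
        "infusion_stop_s": case.infusion_stop,
    })
    df.to_csv(path, index=False, float_format="%.10g", na_rep="")


def read_case_csv(path) -> CaseRecord:
    path = Path(path)
    df = pd.read_csv(path, dtype={"sex": str})
    if list(df.columns) != COLUMNS:
        raise ValueError(f"{path.name}: header does not match case dialect {COLUMNS}")
    t = df["time_s"].to_numpy(dtype=float)
    if np.any(np.isnan(t)) or not np.all(np.diff(t) > 0):
        raise ValueError(f"{path.name}: timestamps must be present and strictly increasing")
    case = CaseRecord(
        case_id=path.stem,
        t=t,
        prop_cum=df["prop_cum_mg"].to_numpy(dtype=float),
        remi_cum=df["remi_cum_ug"].to_numpy(dtype=float),
        bis=df["bis"].to_numpy(dtype=float),
        age=float(df["age"].iloc[0]),
        sex=str(df["sex"].iloc[0]),
        height=float(df["height_cm"].iloc[0]),
        weight=float(df["weight_kg"].iloc[0]),
        infusion_start=int(df["infusion_start_s"].iloc[0]),
        infusion_stop=int(df["infusion_stop_s"].iloc[0]),
    )
    case.validate()
    return case


def write_cohort(cases, metas, out_dir) -> Path:
    """Write per-case CSVs plus a manifest of planted-defect ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case, meta in zip(cases, metas):
        fname = f"{case.case_id}.csv"
        write_case_csv(case, out_dir / fname)
        rows.append({
            "case_id": case.case_id,
            "file": fname,
            "violation": meta.get("violation") or "",
            "gaps": json.dumps(meta.get("gaps", [])),
            "glitches": json.dumps(meta.get("glitches", [])),
        })
    manifest = out_dir / "cohort_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(in_dir):
    """Load cases listed in a cohort manifest; returns (cases, manifest df)."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "cohort_manifest.csv", keep_default_na=False)
    cases = [read_case_csv(in_dir / f) for f in manifest["file"]]
    return cases, manifest
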