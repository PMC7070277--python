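"""File formats: recording CSV, feature CSV, model and report documents.

The recording CSV holds one row per sEMG-clock sample with columns
``t_s, emg_rf, emg_bf, emg_st, p_toe, p_fore, p_heel, hip_deg, knee_deg,
ankle_deg, phase`` and ``#``-prefixed metadata lines carrying the
generator parameters as ``key=value`` pairs. All floats are written with
17 significant digits so write -> read round-trips are value-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .grnn import GRNN
from .model import EvaluationReport
from .synthetic import GaitParameters, GaitRecording

__all__ = [
    "ParseError",
    "read_recording",
    "write_recording",
    "write_feature_table",
    "save_model",
    "load_model",
    "write_report",
    "read_predictions",
]

RECORDING_COLUMNS = (
    "t_s",
    "emg_rf",
    "emg_bf",
    "emg_st",
    "p_toe",
    "p_fore",
    "p_heel",
    "hip_deg",
    "knee_deg",
    "ankle_deg",
    "phase",
)

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Raised when a file does not match its documented schema."""


def write_recording(recording: GaitRecording, path: str | Path) -> None:
    """Write a recording as CSV (requires a shared angle/sEMG clock)."""
    if recording.time_angle.size != recording.time_semg.size or not np.allclose(
        recording.time_angle, recording.time_semg
    ):
        raise ValueError(
            "recording CSV has one row per sEMG sample; the angle channels "
            "must share the sEMG clock to be written"
        )
    df = pd.DataFrame(
        {
            "t_s": recording.time_semg,
            "emg_rf": recording.semg["rf"],
            "emg_bf": recording.semg["bf"],
            "emg_st": recording.semg["st"],
            "p_toe": recording.pressure["toe"],
            "p_fore": recording.pressure["fore"],
            "p_heel": recording.pressure["heel"],
            "hip_deg": recording.angles["hip"],
            "knee_deg": recording.angles["knee"],
            "ankle_deg": recording.angles["ankle"],
            "phase": recording.phase,
        }
    )
    with open(path, "w") as fh:
        if recording.params is not None:
            for key, val in recording.params.to_dict().items():
                fh.write(f"# {key}={val!r}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_recording(path: str | Path) -> GaitRecording:
    """Read a recording CSV; column order is irrelevant (schema by name)."""
    path = Path(path)
    meta: dict[str, str] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip().strip("'\"")
    try:
        df = pd.read_csv(
            path, comment="#", skip_blank_lines=True, float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed CSV: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path}: no data rows")

    missing = set(RECORDING_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")

    for col in RECORDING_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + header_lines + 2
            raise ParseError(f"{path}: missing value in column {col!r} near line {row}")
        if bad.any():
            row = int(df.index[bad][0]) + header_lines + 2
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = numeric

    t = df["t_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        idx = int(np.argmax(np.diff(t) <= 0)) + header_lines + 3
        raise ParseError(f"{path}: t_s not strictly increasing at line {idx}")

    params = GaitParameters.from_dict(meta) if meta else None
    rec = GaitRecording(
        time_semg=t,
        semg={ch: df[f"emg_{ch}"].to_numpy() for ch in ("rf", "bf", "st")},
        time_angle=t.copy(),
        angles={ch: df[f"{ch}_deg"].to_numpy() for ch in ("hip", "knee", "ankle")},
        pressure={ch: df[f"p_{ch}"].to_numpy() for ch in ("toe", "fore", "heel")},
        phase=df["phase"].to_numpy(),
        params=params,
    )
    rec.validate()
    return rec


def write_feature_table(table, path: str | Path) -> None:
    """Write a feature table: inputs, next-step targets and cycle ids."""
    df = pd.DataFrame({"t_s": table.t})
    for col in table.inputs.columns:
        df[col] = table.inputs[col].to_numpy()
    for col in table.targets.columns:
        df[f"target_{col}"] = table.targets[col].to_numpy()
    df["cycle_id"] = table.cycle_id
    with open(path, "w") as fh:
        fh.write(f"# ablation={table.ablation}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def save_model(grnn: GRNN, path: str | Path, ablation: str, config: RunConfig) -> None:
    """Serialize a fitted GRNN with everything needed to re-apply it."""
    doc = grnn.to_dict()
    doc["ablation"] = ablation
    doc["config"] = config.to_dict()
    doc["created_from"] = config.hash()
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def load_model(path: str | Path) -> tuple[GRNN, str, RunConfig]:
    doc = json.loads(Path(path).read_text())
    grnn = GRNN.from_dict(doc)
    config = RunConfig(**doc["config"])
    return grnn, doc["ablation"], config


def write_report(report: EvaluationReport, path: str | Path, include_timing: bool = True) -> None:
    Path(path).write_text(report.to_json(include_timing=include_timing))


def write_predictions(predictions: pd.DataFrame, path: str | Path) -> None:
    """Long-format prediction CSV: ``t_s, joint, pred_deg, actual_deg``."""
    rows = []
    for col in ("hip_deg", "knee_deg", "ankle_deg"):
        rows.append(
            pd.DataFrame(
                {
                    "t_s": predictions["t_s"],
                    "joint": col.replace("_deg", ""),
                    "pred_deg": predictions[f"pred_{col}"],
                    "actual_deg": predictions[f"actual_{col}"],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a long-format prediction CSV produced here or externally."""
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed CSV: {exc}") from exc
    missing = {"t_s", "joint", "pred_deg", "actual_deg"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df
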