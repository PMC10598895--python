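"""Cohort/result file I/O.

Cohort CSV: UTF-8, comma-separated, "." decimal, one mandatory header row
whose columns are exactly the PatientRecord field names (cm units except
tmj_rom in mm; small_mandible as 0/1).  Malformed rows are rejected
individually and reported with their line number; counts are logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GadasError, ParseError
from .records import FIELD_NAMES, PatientRecord, validate_record

log = logging.getLogger("gadas")


@dataclass(frozen=True)
class CohortReadResult:
    records: list[PatientRecord]
    rejections: list[tuple[int, str]]  # (1-based data line number, reason)


def read_cohort_csv(path: str | Path, strict: bool = False) -> CohortReadResult:
    """Read a cohort CSV, validating every row.

    With ``strict`` any invalid row raises; otherwise invalid rows are
    collected in ``rejections`` and logged.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    missing = [c for c in FIELD_NAMES if c not in df.columns]
    if missing:
        raise ParseError(f"missing column(s): {', '.join(missing)}", column=missing[0])
    unknown = [c for c in df.columns if c not in FIELD_NAMES and c != "patient_id"]
    if unknown:
        raise ParseError(f"unknown column(s): {', '.join(unknown)}", column=unknown[0])

    records: list[PatientRecord] = []
    rejections: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            records.append(validate_record(row))
        except GadasError as exc:
            if strict:
                raise ParseError(f"line {i}: {exc}", line=i) from exc
            rejections.append((i, str(exc)))
            log.warning("rejected cohort row %d: %s", i, exc)
    log.info("read %d record(s), rejected %d from %s", len(records), len(rejections), path)
    return CohortReadResult(records=records, rejections=rejections)


def write_cohort_csv(path: str | Path, records: list[PatientRecord]) -> None:
    df = pd.DataFrame([r.to_dict() for r in records], columns=list(FIELD_NAMES))
    df.to_csv(path, index=False)
    log.info("wrote %d record(s) to %s", len(records), path)


def write_results_csv(path: str | Path, results: pd.DataFrame) -> None:
    """Write the per-patient simulation output (V to 0.1 mm, both calls)."""
    out = results.copy()
    out["visibility_mm"] = out["visibility_mm"].map(lambda v: f"{v:.1f}")
    out.to_csv(path, index=False)
    log.info("wrote %d result row(s) to %s", len(out), path)


def read_results_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "visibility_mm" not in df.columns:
        raise ParseError("missing column(s): visibility_mm", column="visibility_mm")
    return df


def write_labels_csv(path: str | Path, labels: np.ndarray) -> None:
    pd.DataFrame(
        {"patient_id": np.arange(len(labels)), "difficult_intubation": labels.astype(int)}
    ).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("difficult_intubation", "label", "labels"):
        if col in df.columns:
            return df[col].to_numpy().astype(bool)
    raise ParseError("missing column(s): difficult_intubation", column="difficult_intubation")


def results_frame(records, visibilities, screenings) -> pd.DataFrame:
    """Assemble the simulate-output table from parallel per-patient lists."""
    return pd.DataFrame(
        {
            "patient_id": range(len(records)),
            "visibility_mm": [v.visibility_mm for v in visibilities],
            "intersects_cords": [int(v.intersects_cords) for v in visibilities],
            "difficult_intubation_pred": [int(s.difficult_intubation_pred) for s in screenings],
            "difficult_laryngoscopy_pred": [int(s.difficult_laryngoscopy_pred) for s in screenings],
        }
    )


def write_report_json(path: str | Path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
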