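"""Reading and writing the package's external file formats.

Patient cases travel either as JSON (one object per case, labs carrying
explicit units) or as flat CSV (one row per case; lab columns are assumed to
be in the canonical units of the active reference-range table, and an empty
cell is a missing measurement).  Label files are CSV with columns
``rater_id, case_id, diagnosis_id, label`` (plus ``score`` for system
reports).  All tabular work goes through pandas.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .engine import DiagnosisReport
from .errors import NutriDSSError
from .knowledge import Intake, LabValue, PatientCase, ReferenceRanges, default_ranges
from .validation import GoldStandard, LabelSet

__all__ = [
    "read_cases",
    "write_cases_csv",
    "write_cases_json",
    "read_labels",
    "write_labels_csv",
    "read_gold",
    "write_gold_csv",
    "reports_to_frame",
    "write_reports",
    "system_labels_from_reports",
]

_BOOL_COLS = (
    "hair_loss",
    "nail_changes",
    "skin_changes",
    "paleness",
    "weakness",
    "paresthesia",
    "vomiting",
    "diarrhea",
    "blood_loss",
)
_SIGN_COLS = ("hair_loss", "nail_changes", "skin_changes", "paleness")


def _missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or value == ""


def _to_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return bool(int(value))
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("1", "true", "yes", "y"):
            return True
        if v in ("0", "false", "no", "n"):
            return False
    raise NutriDSSError(f"cannot interpret {value!r} as a presence flag")


def frame_to_cases(df: pd.DataFrame, ranges: ReferenceRanges | None = None) -> list[PatientCase]:
    """Flat CSV rows -> cases; lab units taken from the range table."""
    ranges = ranges if ranges is not None else default_ranges()
    cases = []
    for _, row in df.iterrows():
        labs = {}
        for marker, spec in ranges.markers.items():
            if marker in df.columns and not _missing(row[marker]):
                labs[marker] = LabValue(value=float(row[marker]), unit=spec.unit)
        intake = None
        energy = row.get("energy_kcal")
        portions = {
            c.removeprefix("portions_"): float(row[c])
            for c in df.columns
            if c.startswith("portions_") and not _missing(row[c])
        }
        if not _missing(energy) or portions:
            intake = Intake(
                energy_kcal=None if _missing(energy) else float(energy),
                portions=portions or None,
            )
        signs = {}
        symptoms = {}
        for col in _BOOL_COLS:
            if col in df.columns and not _missing(row[col]):
                (signs if col in _SIGN_COLS else symptoms)[col] = _to_bool(row[col])
        months = row.get("months_since_surgery")
        cases.append(
            PatientCase(
                patient_id=str(row["patient_id"]),
                gender=str(row["gender"]),
                age=float(row["age"]),
                months_since_surgery=None if _missing(months) else float(months),
                labs=labs,
                intake=intake,
                signs=signs,
                symptoms=symptoms,
            )
        )
    return cases


def cases_to_frame(cases: Sequence[PatientCase]) -> pd.DataFrame:
    rows = []
    for case in cases:
        row: dict = {
            "patient_id": case.patient_id,
            "gender": case.gender,
            "age": case.age,
            "months_since_surgery": case.months_since_surgery,
        }
        for marker, lab in case.labs.items():
            row[marker] = lab.value
        if case.intake is not None:
            row["energy_kcal"] = case.intake.energy_kcal
            for group, n in (case.intake.portions or {}).items():
                row[f"portions_{group}"] = n
        for col, flag in {**case.signs, **case.symptoms}.items():
            row[col] = int(flag)
        rows.append(row)
    return pd.DataFrame(rows)


def read_cases(path: str | Path, ranges: ReferenceRanges | None = None) -> list[PatientCase]:
    """Load patient cases from a ``.json`` or ``.csv`` file."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        if not isinstance(data, list):
            raise NutriDSSError("case JSON must be a list of case objects")
        return [PatientCase.model_validate(item) for item in data]
    if path.suffix.lower() == ".csv":
        return frame_to_cases(pd.read_csv(path), ranges)
    raise NutriDSSError(f"unsupported case file extension: {path.suffix!r}")


def write_cases_csv(cases: Sequence[PatientCase], path: str | Path):
    cases_to_frame(cases).to_csv(path, index=False)


def write_cases_json(cases: Sequence[PatientCase], path: str | Path):
    Path(path).write_text(json.dumps([c.model_dump(exclude_none=True) for c in cases], indent=1))


# ---- labels ----------------------------------------------------------------


def read_labels(path: str | Path) -> list[LabelSet]:
    """CSV (rater_id, case_id, diagnosis_id, label) -> one LabelSet per rater."""
    df = pd.read_csv(path)
    required = {"rater_id", "case_id", "diagnosis_id", "label"}
    if not required <= set(df.columns):
        raise NutriDSSError(f"label file needs columns {sorted(required)}; got {list(df.columns)}")
    out = []
    for rater_id, group in df.groupby("rater_id", sort=True):
        labels = {}
        for _, row in group.iterrows():
            key = (str(row["case_id"]), str(row["diagnosis_id"]))
            if key in labels:
                raise NutriDSSError(f"rater {rater_id!r}: duplicate key {key!r}")
            labels[key] = str(row["label"])
        out.append(LabelSet(str(rater_id), labels))
    return out


def labels_to_frame(label_sets: Iterable[LabelSet]) -> pd.DataFrame:
    rows = [
        {"rater_id": ls.rater_id, "case_id": c, "diagnosis_id": d, "label": label}
        for ls in label_sets
        for (c, d), label in sorted(ls.labels.items())
    ]
    return pd.DataFrame(rows)


def write_labels_csv(label_sets: Iterable[LabelSet], path: str | Path):
    labels_to_frame(label_sets).to_csv(path, index=False)


def write_gold_csv(gold: GoldStandard, path: str | Path):
    gold.require_complete()
    rows = [
        {
            "case_id": c,
            "diagnosis_id": d,
            "label": gold.labels[(c, d)],
            "provenance": gold.provenance.get((c, d), ""),
        }
        for (c, d) in sorted(gold.labels)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_gold(path: str | Path) -> GoldStandard:
    df = pd.read_csv(path)
    gold = GoldStandard()
    for _, row in df.iterrows():
        key = (str(row["case_id"]), str(row["diagnosis_id"]))
        gold.labels[key] = str(row["label"])
        gold.provenance[key] = str(row.get("provenance", "") or "unanimous")
    return gold


def read_adjudication(path: str | Path) -> dict[tuple[str, str], str]:
    df = pd.read_csv(path)
    return {
        (str(row["case_id"]), str(row["diagnosis_id"])): str(row["label"])
        for _, row in df.iterrows()
    }


# ---- diagnosis reports -----------------------------------------------------


def reports_to_frame(reports: Sequence[DiagnosisReport]) -> pd.DataFrame:
    """One row per case x diagnosis with the posterior triple, label and score."""
    rows = []
    for report in reports:
        for diag, result in report.results.items():
            post = result.posterior.distribution if result.posterior else {}
            rows.append(
                {
                    "patient_id": report.patient_id,
                    "diagnosis": diag,
                    "p_present": post.get("present"),
                    "p_at_risk": post.get("at_risk"),
                    "p_absent": post.get("absent"),
                    "label": result.label,
                    "score": result.score,
                    "error": result.error,
                }
            )
    return pd.DataFrame(rows)


def write_reports(reports: Sequence[DiagnosisReport], path: str | Path, fmt: str = "json"):
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps([r.to_dict() for r in reports], indent=1))
    elif fmt == "csv":
        reports_to_frame(reports).to_csv(path, index=False)
    else:
        raise NutriDSSError(f"unsupported report format {fmt!r}")


def system_labels_from_reports(
    reports: Sequence[DiagnosisReport], rater_id: str = "system"
) -> tuple[LabelSet, dict[tuple[str, str], float]]:
    """Collect the system's labels and scores for validation against a gold standard."""
    labels: dict[tuple[str, str], str] = {}
    scores: dict[tuple[str, str], float] = {}
    for report in reports:
        for diag, result in report.results.items():
            if result.label is None:
                continue
            key = (report.patient_id, diag)
            labels[key] = result.label
            scores[key] = float(result.score)
    return LabelSet(rater_id, labels), scores


def system_labels_from_frame(df: pd.DataFrame, rater_id: str = "system"):
    """Accept either a report CSV (patient_id/diagnosis) or a label CSV (case_id/diagnosis_id)."""
    if {"patient_id", "diagnosis"} <= set(df.columns):
        case_col, diag_col = "patient_id", "diagnosis"
    elif {"case_id", "diagnosis_id"} <= set(df.columns):
        case_col, diag_col = "case_id", "diagnosis_id"
    else:
        raise NutriDSSError(
            "system file needs columns patient_id/diagnosis or case_id/diagnosis_id"
        )
    labels, scores = {}, {}
    for _, row in df.iterrows():
        if _missing(row.get("label")):
            continue
        key = (str(row[case_col]), str(row[diag_col]))
        labels[key] = str(row["label"])
        if "score" in df.columns and not _missing(row["score"]):
            scores[key] = float(row["score"])
    return LabelSet(rater_id, labels), (scores or None)
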