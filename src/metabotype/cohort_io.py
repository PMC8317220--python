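"""Cohort and model I/O with strict unit and schema validation.

Canonical cohort format is delimited text (comma or tab, auto-detected) with a
header row. Expected columns::

    patient_id,sex,age,bmi,glu_0,glu_30,glu_60,glu_120,
    ins_0,ins_30,ins_60,ins_120,uric_acid,hba1c,<comorbidity>...

Units are fixed by the schema: glucose in mmol/L, insulin in mU/L, uric acid
in umol/L. No unit conversion is performed on input. Missing numeric cells
are an empty string or ``NA``; zeros are values, never missing. Any column
after the known set is read as a binary comorbidity flag (1 = present,
0 = absent, NA = unknown).

Fitted cluster models are serialized as JSON (see :func:`write_model`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .exceptions import (
    CohortValidationError,
    IntegrityError,
    ModelFormatError,
    SchemaError,
)

OGTT_GRID = (0, 30, 60, 120)
SEXES = ("male", "female")
COMORBIDITY_STATES = ("present", "absent", "unknown")

MODEL_FORMAT_VERSION = "1"

_CORE_COLUMNS = ("patient_id", "sex", "age", "bmi", "uric_acid")
_GLUCOSE_COLUMNS = tuple(f"glu_{t}" for t in OGTT_GRID)
_INSULIN_COLUMNS = tuple(f"ins_{t}" for t in OGTT_GRID)
_OPTIONAL_COLUMNS = ("hba1c", "cohort_id")
_KNOWN_COLUMNS = _CORE_COLUMNS + _GLUCOSE_COLUMNS + _INSULIN_COLUMNS + _OPTIONAL_COLUMNS

_MISSING_TOKENS = {"", "na", "nan", "none"}
_SEX_ALIASES = {
    "male": "male", "m": "male", "man": "male",
    "female": "female", "f": "female", "woman": "female",
}
_COMORBIDITY_TOKENS = {
    "1": "present", "present": "present", "yes": "present", "true": "present",
    "0": "absent", "absent": "absent", "no": "absent", "false": "absent",
}


@dataclass
class PatientRecord:
    """One subject: demographics, OGTT curves, uric acid, comorbidity flags.

    OGTT curves are mappings time (min) -> concentration over the grid
    {0, 30, 60, 120}; absent keys are missing measurements. ``comorbidities``
    maps a condition name to one of ``present``/``absent``/``unknown``.
    """

    patient_id: str
    sex: str
    age: float
    bmi: float
    ogtt_glucose: dict[int, float]
    ogtt_insulin: dict[int, float]
    uric_acid: float
    hba1c: float | None = None
    comorbidities: dict[str, str] = field(default_factory=dict)
    cohort_id: str = ""

    def validate(self) -> list[str]:
        """Return a list of violation messages (empty if valid)."""
        msgs = []
        pid = self.patient_id
        if self.sex not in SEXES:
            msgs.append(f"patient {pid!r}: sex must be one of {SEXES}, got {self.sex!r}")
        for name, curve, lo, hi in (
            ("glucose", self.ogtt_glucose, 0.0, 50.0),
            ("insulin", self.ogtt_insulin, 0.0, math.inf),
        ):
            for t, v in curve.items():
                if t not in OGTT_GRID:
                    msgs.append(f"patient {pid!r}: {name} time {t} not on grid {OGTT_GRID}")
                elif not (lo < v < hi) or not math.isfinite(v):
                    msgs.append(f"patient {pid!r}: {name} at {t} min out of range: {v}")
        if not (math.isfinite(self.uric_acid) and self.uric_acid > 0):
            msgs.append(f"patient {pid!r}: uric_acid must be > 0 umol/L, got {self.uric_acid}")
        if not (math.isfinite(self.age) and self.age > 0):
            msgs.append(f"patient {pid!r}: age must be a positive number, got {self.age}")
        for cname, state in self.comorbidities.items():
            if state not in COMORBIDITY_STATES:
                msgs.append(f"patient {pid!r}: comorbidity {cname!r} state {state!r} invalid")
        return msgs

    def has_complete_ogtt(self) -> bool:
        return all(t in self.ogtt_glucose for t in OGTT_GRID) and all(
            t in self.ogtt_insulin for t in OGTT_GRID
        )


@dataclass
class CohortTable:
    """Ordered collection of validated patient records plus a provenance tag."""

    records: list[PatientRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate(self) -> None:
        msgs = []
        seen: set[str] = set()
        for rec in self.records:
            if rec.patient_id in seen:
                raise IntegrityError(f"duplicate patient_id {rec.patient_id!r}")
            seen.add(rec.patient_id)
            msgs.extend(rec.validate())
        if msgs:
            raise CohortValidationError(msgs)

    def comorbidity_names(self) -> list[str]:
        names: list[str] = []
        for rec in self.records:
            for n in rec.comorbidities:
                if n not in names:
                    names.append(n)
        return names


def _parse_float(token: str, *, row: int, column: str, errors: list[str]) -> float | None:
    token = token.strip()
    if token.lower() in _MISSING_TOKENS:
        return None
    try:
        return float(token)
    except ValueError:
        errors.append(f"row {row}: column {column!r}: malformed numeric value {token!r}")
        return None


def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None) -> CohortTable:
    """Read a delimited cohort table into a validated :class:`CohortTable`.

    Parameters
    ----------
    path
        Comma- or tab-delimited text file with a header row.
    schema
        Optional mapping from semantic field names (the canonical column
        names above) to the actual column names in the file.

    Raises
    ------
    SchemaError
        if a mandatory column is absent.
    CohortValidationError
        listing every malformed or out-of-range cell with row context.
    IntegrityError
        on duplicate patient ids.
    """
    path = Path(path)
    head = path.open().readline()
    sep = "\t" if head.count("\t") > head.count(",") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    rename = dict(schema) if schema else {}
    colmap = {sem: rename.get(sem, sem) for sem in _KNOWN_COLUMNS}
    mandatory = _CORE_COLUMNS + _GLUCOSE_COLUMNS + _INSULIN_COLUMNS
    missing = [colmap[c] for c in mandatory if colmap[c] not in frame.columns]
    # OGTT cells may be entirely absent as columns only if declared via schema;
    # the canonical layout requires all four time points per analyte.
    if missing:
        raise SchemaError(f"mandatory column(s) missing from {path.name}: {missing}")

    mapped = set(colmap.values())
    comorbidity_cols = [c for c in frame.columns if c not in mapped]

    errors: list[str] = []
    records: list[PatientRecord] = []
    for i, row in frame.iterrows():
        rownum = int(i) + 2  # 1-based line number incl. header
        pid = row[colmap["patient_id"]].strip()
        sex = _SEX_ALIASES.get(row[colmap["sex"]].strip().lower(), row[colmap["sex"]].strip())
        age = _parse_float(row[colmap["age"]], row=rownum, column="age", errors=errors)
        bmi = _parse_float(row[colmap["bmi"]], row=rownum, column="bmi", errors=errors)
        ua = _parse_float(row[colmap["uric_acid"]], row=rownum, column="uric_acid", errors=errors)
        hba1c = None
        if colmap["hba1c"] in frame.columns:
            hba1c = _parse_float(row[colmap["hba1c"]], row=rownum, column="hba1c", errors=errors)
        glucose: dict[int, float] = {}
        insulin: dict[int, float] = {}
        for t in OGTT_GRID:
            g = _parse_float(row[colmap[f"glu_{t}"]], row=rownum, column=f"glu_{t}", errors=errors)
            if g is not None:
                glucose[t] = g
            ins = _parse_float(row[colmap[f"ins_{t}"]], row=rownum, column=f"ins_{t}", errors=errors)
            if ins is not None:
                insulin[t] = ins
        comorbidities: dict[str, str] = {}
        for c in comorbidity_cols:
            token = row[c].strip().lower()
            if token in _MISSING_TOKENS:
                comorbidities[c] = "unknown"
            elif token in _COMORBIDITY_TOKENS:
                comorbidities[c] = _COMORBIDITY_TOKENS[token]
            else:
                errors.append(f"row {rownum}: column {c!r}: unrecognized comorbidity flag {row[c]!r}")
        cohort_id = ""
        if colmap["cohort_id"] in frame.columns:
            cohort_id = row[colmap["cohort_id"]].strip()
        rec = PatientRecord(
            patient_id=pid,
            sex=sex,
            age=math.nan if age is None else age,
            bmi=math.nan if bmi is None else bmi,
            ogtt_glucose=glucose,
            ogtt_insulin=insulin,
            uric_acid=math.nan if ua is None else ua,
            hba1c=hba1c,
            comorbidities=comorbidities,
            cohort_id=cohort_id,
        )
        for msg in rec.validate():
            errors.append(f"row {rownum}: {msg}")
        records.append(rec)
    if errors:
        raise CohortValidationError(errors)
    cohort = CohortTable(records=records, provenance=str(path))
    seen: set[str] = set()
    for rec in records:
        if rec.patient_id in seen:
            raise IntegrityError(f"duplicate patient_id {rec.patient_id!r} in {path.name}")
        seen.add(rec.patient_id)
    return cohort


def cohort_to_frame(cohort: CohortTable) -> pd.DataFrame:
    """Flatten a cohort into the canonical column layout (strings, NA-coded)."""
    comorbidity_names = cohort.comorbidity_names()
    rows = []
    for rec in cohort:
        row: dict[str, object] = {
            "patient_id": rec.patient_id,
            "sex": rec.sex,
            "age": rec.age,
            "bmi": rec.bmi,
        }
        for t in OGTT_GRID:
            row[f"glu_{t}"] = rec.ogtt_glucose.get(t, "")
            row[f"ins_{t}"] = rec.ogtt_insulin.get(t, "")
        row["uric_acid"] = rec.uric_acid
        row["hba1c"] = "" if rec.hba1c is None else rec.hba1c
        for name in comorbidity_names:
            state = rec.comorbidities.get(name, "unknown")
            row[name] = {"present": 1, "absent": 0, "unknown": "NA"}[state]
        row["cohort_id"] = rec.cohort_id
        rows.append(row)
    columns = (
        ["patient_id", "sex", "age", "bmi"]
        + [f"glu_{t}" for t in OGTT_GRID]
        + [f"ins_{t}" for t in OGTT_GRID]
        + ["uric_acid", "hba1c"]
        + comorbidity_names
        + ["cohort_id"]
    )
    return pd.DataFrame(rows, columns=columns)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort as CSV; ``read_cohort`` reproduces it field-for-field."""
    cohort_to_frame(cohort).to_csv(path, index=False)


# --- model serialization -----------------------------------------------------

def write_model(model, path: str | Path) -> None:
    """Serialize a fitted :class:`~metabotype.subtype_clustering.ClusterModel`
    (optionally bundled with an imputation suite) as human-readable JSON."""
    payload = model.to_dict()
    payload["format_version"] = MODEL_FORMAT_VERSION
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_model(path: str | Path):
    """Load a model JSON written by :func:`write_model`.

    Raises :class:`ModelFormatError` on parse failure, version mismatch, or a
    missing sex stratum.
    """
    from .subtype_clustering import ClusterModel  # deferred to avoid cycle

    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"cannot parse model file {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model format version {version!r} incompatible with {MODEL_FORMAT_VERSION!r}"
        )
    strata = payload.get("strata", {})
    for sex in SEXES:
        if sex not in strata:
            raise ModelFormatError(f"model is missing the {sex!r} stratum")
    return ClusterModel.from_dict(payload)
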