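"""OGTT feature derivation: clustering variables and insulin-sensitivity indices.

The three clustering variables are the trapezoidal areas under the four-point
(0, 30, 60, 120 min) OGTT glucose and insulin curves plus serum uric acid.
Secondary indices (HOMA-IR, HOMA-beta, IGI, WBISI and the two disposition
indices) follow the standard literature definitions; pole cases (e.g. fasting
glucose at the HOMA-beta singularity) are flagged as NaN per record rather
than aborting a cohort run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_io import OGTT_GRID, CohortTable, PatientRecord
from .exceptions import IncompleteCurveError

#: trapezoid quadrature weights for the grid (0, 30, 60, 120) min
TRAPEZOID_WEIGHTS = (15.0, 30.0, 45.0, 30.0)

#: mmol/L -> mg/dL conversion for glucose (used by WBISI only)
_MGDL_PER_MMOL = 18.0

FEATURE_NAMES = ("glucose_auc", "insulin_auc", "uric_acid")


@dataclass(frozen=True)
class FeatureVector:
    """The three clustering variables, in raw units.

    glucose_auc in mmol/L*min, insulin_auc in mU/L*min, uric_acid in umol/L.
    """

    glucose_auc: float
    insulin_auc: float
    uric_acid: float

    def as_array(self) -> np.ndarray:
        return np.array([self.glucose_auc, self.insulin_auc, self.uric_acid], dtype=float)

    @staticmethod
    def from_array(a) -> "FeatureVector":
        g, i, u = (float(x) for x in a)
        return FeatureVector(g, i, u)


@dataclass(frozen=True)
class MetabolicIndices:
    """Secondary OGTT indices; undefined (pole-case) entries are NaN."""

    homa_ir: float
    homa_beta: float
    igi: float
    wbisi: float
    di_homa: float   # homa_beta / homa_ir
    di_igi: float    # igi * wbisi

    def undefined(self) -> tuple[str, ...]:
        return tuple(
            name for name in ("homa_ir", "homa_beta", "igi", "wbisi", "di_homa", "di_igi")
            if math.isnan(getattr(self, name))
        )


def trapezoid_auc(values: Mapping[int, float]) -> float:
    """Trapezoidal area under a four-point OGTT curve, in concentration*min.

    Equals ``15*y0 + 30*y30 + 45*y60 + 30*y120``. Raises
    :class:`IncompleteCurveError` if any grid point is absent; incomplete
    curves must be routed through the imputation suite instead.
    """
    missing = [t for t in OGTT_GRID if t not in values]
    if missing:
        raise IncompleteCurveError(f"OGTT curve missing grid points {missing}")
    y = np.array([values[t] for t in OGTT_GRID], dtype=float)
    return float(np.trapezoid(y, x=np.array(OGTT_GRID, dtype=float)))


def compute_features(record: PatientRecord) -> FeatureVector:
    """Derive the clustering variables from a record with complete OGTT data."""
    return FeatureVector(
        glucose_auc=trapezoid_auc(record.ogtt_glucose),
        insulin_auc=trapezoid_auc(record.ogtt_insulin),
        uric_acid=record.uric_acid,
    )


def homa_ir(g0: float, i0: float) -> float:
    """HOMA insulin resistance: g0*i0/22.5 (g0 mmol/L, i0 mU/L)."""
    if not (g0 > 0 and i0 > 0):
        raise ValueError(f"HOMA-IR requires positive inputs, got g0={g0}, i0={i0}")
    return g0 * i0 / 22.5


def homa_beta(g0: float, i0: float) -> float:
    """HOMA beta-cell function: 20*i0/(g0 - 3.5); NaN at/below the g0=3.5 pole."""
    if g0 <= 3.5:
        return math.nan
    return 20.0 * i0 / (g0 - 3.5)


def igi(g0: float, g30: float, i0: float, i30: float) -> float:
    """Insulinogenic index (i30 - i0)/(g30 - g0); NaN when the glucose increment is 0."""
    if g30 == g0:
        return math.nan
    return (i30 - i0) / (g30 - g0)


def wbisi(curve_g: Mapping[int, float], curve_i: Mapping[int, float]) -> float:
    """Matsuda whole-body insulin sensitivity index on the four-point grid.

    10000 / sqrt(g0[mg/dL] * i0 * mean_g[mg/dL] * mean_i), with the means taken
    over the four available grid points (0, 30, 60, 120 min).
    """
    for curve, name in ((curve_g, "glucose"), (curve_i, "insulin")):
        missing = [t for t in OGTT_GRID if t not in curve]
        if missing:
            raise IncompleteCurveError(f"WBISI needs the full {name} curve; missing {missing}")
    g = np.array([curve_g[t] for t in OGTT_GRID], dtype=float)
    i = np.array([curve_i[t] for t in OGTT_GRID], dtype=float)
    g0_mgdl = g[0] * _MGDL_PER_MMOL
    gbar_mgdl = g.mean() * _MGDL_PER_MMOL
    return 10000.0 / math.sqrt(g0_mgdl * i[0] * gbar_mgdl * i.mean())


def compute_indices(record: PatientRecord) -> MetabolicIndices:
    """All six secondary indices for a record with complete OGTT curves.

    The disposition identities di_homa = homa_beta/homa_ir and
    di_igi = igi*wbisi hold exactly whenever both factors are defined.
    """
    g, i = record.ogtt_glucose, record.ogtt_insulin
    w = wbisi(g, i)  # also validates completeness
    ir = homa_ir(g[0], i[0])
    beta = homa_beta(g[0], i[0])
    insulinogenic = igi(g[0], g[30], i[0], i[30])
    return MetabolicIndices(
        homa_ir=ir,
        homa_beta=beta,
        igi=insulinogenic,
        wbisi=w,
        di_homa=beta / ir,
        di_igi=insulinogenic * w,
    )


def features_frame(cohort: CohortTable) -> pd.DataFrame:
    """Feature export: one row per patient with documented units.

    Columns: glucose_auc (mmol/L*min), insulin_auc (mU/L*min),
    uric_acid (umol/L). Records with incomplete OGTT raise; use the
    imputation suite for those.
    """
    rows = []
    for rec in cohort:
        fv = compute_features(rec)
        rows.append(
            {"patient_id": rec.patient_id, "sex": rec.sex,
             "glucose_auc": fv.glucose_auc, "insulin_auc": fv.insulin_auc,
             "uric_acid": fv.uric_acid}
        )
    return pd.DataFrame(rows, columns=["patient_id", "sex", *FEATURE_NAMES])


def indices_frame(cohort: CohortTable) -> pd.DataFrame:
    """Secondary-index export, one row per patient (NaN = undefined index)."""
    rows = []
    for rec in cohort:
        idx = compute_indices(rec)
        rows.append({"patient_id": rec.patient_id, "homa_ir": idx.homa_ir,
                     "homa_beta": idx.homa_beta, "igi": idx.igi, "wbisi": idx.wbisi,
                     "di_homa": idx.di_homa, "di_igi": idx.di_igi})
    return pd.DataFrame(rows)
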