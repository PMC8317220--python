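"""Synthetic cohort generator calibrated to the published subtype geometry.

Patients are drawn from a per-sex four-component Gaussian mixture over
(glucose AUC, insulin AUC, uric acid) whose component means default to the
published k-means cluster centers and whose weights default to the published
subtype prevalences (MHO 44%, HMO-U 33%, HMO-I 8%, LMO 15%). OGTT curves are
constructed so their four-point trapezoid AUCs equal the drawn feature values
exactly; comorbidity flags follow a per-subtype logistic model; optional
missingness removes OGTT time points so the imputation path is exercisable.
Everything is reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .auc_imputation import AvailabilityPattern
from .cohort_io import OGTT_GRID, CohortTable, PatientRecord
from .exceptions import ConfigError
from .metabolic_features import TRAPEZOID_WEIGHTS, FeatureVector, trapezoid_auc
from .subtype_clustering import SUBTYPE_ORDER

#: published per-sex cluster centers (glucose_auc, insulin_auc, uric_acid)
MALE_CENTERS = {
    "MHO": FeatureVector(993.0, 17089.0, 405.0),
    "HMO-U": FeatureVector(982.0, 19951.0, 585.0),
    "HMO-I": FeatureVector(1008.0, 50543.0, 489.0),
    "LMO": FeatureVector(1845.0, 9477.0, 404.0),
}
FEMALE_CENTERS = {
    "MHO": FeatureVector(928.0, 12894.0, 331.0),
    "HMO-U": FeatureVector(1100.0, 21895.0, 454.0),
    "HMO-I": FeatureVector(1094.0, 54645.0, 392.0),
    "LMO": FeatureVector(1829.0, 9320.0, 356.0),
}
#: published subtype prevalences, same order as SUBTYPE_ORDER
DEFAULT_WEIGHTS = (0.44, 0.33, 0.08, 0.15)

#: fixed OGTT shape templates over (0, 30, 60, 120) min; template(0) = 0.
#: insulin peaks later than glucose and decays more slowly.
GLUCOSE_TEMPLATE = (0.0, 1.0, 1.0, 0.5)
INSULIN_TEMPLATE = (0.0, 0.7, 1.0, 0.45)

#: per-subtype fasting glucose means (mmol/L); LMO is overtly hyperglycemic
_FASTING_GLUCOSE = {"MHO": 5.2, "HMO-U": 5.4, "HMO-I": 5.4, "LMO": 7.8}
_HBA1C = {"MHO": 5.6, "HMO-U": 5.7, "HMO-I": 5.7, "LMO": 8.0}


@dataclass(frozen=True)
class ComorbidityEffect:
    """Logistic generating model for one comorbidity.

    probability = sigmoid(baseline + shift[subtype] + female*female_effect +
    age_effect*(age - 29)).
    """

    baseline_logodds: float
    subtype_shift: dict[str, float]
    female_effect: float = 0.0
    age_effect: float = 0.0


def _default_comorbidities() -> dict[str, ComorbidityEffect]:
    # Shifts chosen to echo the direction of the published AORs: diabetes
    # concentrated in LMO, hyperuricemia in HMO-U (and moderately HMO-I),
    # metabolic syndrome elevated everywhere but worst in LMO.
    return {
        "diabetes": ComorbidityEffect(
            -3.0, {"MHO": 0.0, "HMO-U": 0.3, "HMO-I": 0.0, "LMO": 4.0},
            female_effect=-0.2, age_effect=0.02,
        ),
        "hyperuricemia": ComorbidityEffect(
            -2.5, {"MHO": 0.0, "HMO-U": 4.0, "HMO-I": 1.7, "LMO": 0.5},
            female_effect=-0.5,
        ),
        "metabolic_syndrome": ComorbidityEffect(
            -1.5, {"MHO": 0.0, "HMO-U": 1.0, "HMO-I": 0.6, "LMO": 2.6},
            age_effect=0.01,
        ),
    }


@dataclass
class SyntheticConfig:
    """Generating parameters for a synthetic cohort.

    Defaults reproduce the published geometry: Table-of-centers means,
    published mixture weights, and within-cluster SDs small enough that
    nearest centers sit >= 2.5 within-SDs apart (a generator assumption, not
    a published estimate).
    """

    n: int = 882
    sex_ratio: float = 0.55                      # fraction female
    mixture_weights: tuple[float, float, float, float] = DEFAULT_WEIGHTS
    male_means: dict[str, FeatureVector] = field(default_factory=lambda: dict(MALE_CENTERS))
    female_means: dict[str, FeatureVector] = field(default_factory=lambda: dict(FEMALE_CENTERS))
    feature_sds: tuple[float, float, float] = (70.0, 3500.0, 35.0)
    curve_noise_glucose: float = 0.03            # SD of multiplicative noise per point
    curve_noise_insulin: float = 0.20            # insulin assays/pulsatility are much noisier
    comorbidity_spec: dict[str, ComorbidityEffect] = field(default_factory=_default_comorbidities)
    missingness_pattern: AvailabilityPattern | None = None
    missingness_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.mixture_weights) - 1.0) > 1e-12 or any(
            w < 0 for w in self.mixture_weights
        ):
            raise ConfigError("mixture weights must be non-negative and sum to 1")
        if any(sd <= 0 for sd in self.feature_sds):
            raise ConfigError("within-cluster SDs must be positive")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigError("sex_ratio must lie in [0, 1]")
        if not 0.0 <= self.missingness_fraction <= 1.0:
            raise ConfigError("missingness_fraction must lie in [0, 1]")
        for means in (self.male_means, self.female_means):
            for subtype, fv in means.items():
                if min(fv.as_array()) < 3.0 * max(self.feature_sds):
                    pass  # truncation handles moderate cases; hard failure below
                if np.any(fv.as_array() <= 0):
                    raise ConfigError(f"non-positive component mean for {subtype!r}")


def default_config() -> SyntheticConfig:
    """The study-calibrated generator configuration."""
    cfg = SyntheticConfig()
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    """Generating subtype and exact features per patient, plus the config."""

    subtype: dict[str, str]
    features: dict[str, FeatureVector]
    config: SyntheticConfig


def build_curve(
    target_auc: float,
    fasting: float,
    template: tuple[float, float, float, float],
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[int, float]:
    """Four-point OGTT curve whose trapezoid AUC equals ``target_auc`` exactly.

    curve = fasting + s*template with s solved in closed form from the
    trapezoid weights (15, 30, 45, 30); multiplicative per-point noise is then
    applied and the whole curve rescaled so the AUC constraint is preserved.
    """
    if template[0] != 0.0 or any(v < 0 for v in template):
        raise ConfigError("template must be non-negative with template(0) = 0")
    w = np.asarray(TRAPEZOID_WEIGHTS)
    tmpl = np.asarray(template, dtype=float)
    denom = float(w @ tmpl)
    s = (target_auc - 120.0 * fasting) / denom
    if s < 0:
        raise ConfigError(
            f"target AUC {target_auc} below the flat-curve floor 120*fasting = {120 * fasting}"
        )
    curve = fasting + s * tmpl
    if noise_sd > 0:
        if rng is None:
            raise ConfigError("noise requires an rng")
        noisy = curve * np.clip(1.0 + rng.normal(0.0, noise_sd, size=4), 0.05, None)
        noisy *= target_auc / float(w @ noisy)
        curve = noisy
    return dict(zip(OGTT_GRID, (float(v) for v in curve)))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_cohort(
    config: SyntheticConfig | None = None,
    seed: int | None = None,
    cohort_id: str = "synthetic",
) -> tuple[CohortTable, GroundTruth]:
    """Draw a cohort from the configured mixture, fully seeded.

    Per patient: sex ~ Bernoulli(sex_ratio), subtype ~ mixture weights,
    features ~ Normal(per-sex subtype mean, diagonal SDs) truncated positive,
    age ~ log-normal with median ~29 y, OGTT curves built to integrate to the
    drawn AUCs exactly, comorbidities from the logistic spec.
    """
    cfg = config or default_config()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    records: list[PatientRecord] = []
    truth_subtype: dict[str, str] = {}
    truth_features: dict[str, FeatureVector] = {}
    sds = np.asarray(cfg.feature_sds)
    for i in range(cfg.n):
        pid = f"{cohort_id}-{i:05d}"
        female = rng.random() < cfg.sex_ratio
        sex = "female" if female else "male"
        subtype = SUBTYPE_ORDER[int(rng.choice(4, p=cfg.mixture_weights))]
        mean = (cfg.female_means if female else cfg.male_means)[subtype].as_array()
        if np.any(mean - 3.0 * sds <= 0) and np.any(mean <= 0):
            raise ConfigError(f"component mean for {subtype!r} makes truncation impossible")
        for _ in range(1000):
            feats = rng.normal(mean, sds)
            if np.all(feats > 0):
                break
        else:
            raise ConfigError(f"cannot draw positive features for subtype {subtype!r}")
        g_auc, i_auc, ua = (float(v) for v in feats)

        age = float(rng.lognormal(math.log(29.0), 0.25))
        bmi = float(np.clip(rng.normal(35.0, 3.5), 30.0, 60.0))
        fasting_g = float(
            np.clip(rng.normal(_FASTING_GLUCOSE[subtype], 0.4), 3.6, g_auc / 120.0 * 0.95)
        )
        fasting_i = float(i_auc / 120.0 * rng.uniform(0.20, 0.35))
        glucose = build_curve(g_auc, fasting_g, GLUCOSE_TEMPLATE, cfg.curve_noise_glucose, rng)
        insulin = build_curve(i_auc, fasting_i, INSULIN_TEMPLATE, cfg.curve_noise_insulin, rng)
        hba1c = float(max(rng.normal(_HBA1C[subtype], 0.3), 4.0))

        comorbidities = {}
        for name, eff in cfg.comorbidity_spec.items():
            logit = (
                eff.baseline_logodds
                + eff.subtype_shift.get(subtype, 0.0)
                + (eff.female_effect if female else 0.0)
                + eff.age_effect * (age - 29.0)
            )
            comorbidities[name] = "present" if rng.random() < _sigmoid(logit) else "absent"

        records.append(
            PatientRecord(
                patient_id=pid, sex=sex, age=age, bmi=bmi,
                ogtt_glucose=glucose, ogtt_insulin=insulin,
                uric_acid=ua, hba1c=hba1c, comorbidities=comorbidities,
                cohort_id=cohort_id,
            )
        )
        truth_subtype[pid] = subtype
        truth_features[pid] = FeatureVector(g_auc, i_auc, ua)

    cohort = CohortTable(records=records, provenance=f"synthetic(seed={seed or cfg.seed})")
    truth = GroundTruth(subtype=truth_subtype, features=truth_features, config=cfg)
    if cfg.missingness_pattern is not None and cfg.missingness_fraction > 0:
        cohort = apply_missingness(
            cohort, cfg.missingness_pattern, cfg.missingness_fraction,
            seed=(cfg.seed if seed is None else seed) + 1,
        )
    return cohort, truth


def apply_missingness(
    cohort: CohortTable,
    pattern: AvailabilityPattern,
    fraction: float,
    seed: int = 0,
) -> CohortTable:
    """Remove the OGTT time points absent from ``pattern`` in a seeded random
    ``fraction`` of records. Ground-truth AUCs (kept by the caller in
    :class:`GroundTruth`) allow imputation scoring afterwards."""
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_affected = int(round(fraction * len(cohort)))
    affected = set(rng.choice(len(cohort), size=n_affected, replace=False).tolist())
    new_records = []
    for i, rec in enumerate(cohort):
        if i in affected:
            rec = PatientRecord(
                patient_id=rec.patient_id, sex=rec.sex, age=rec.age, bmi=rec.bmi,
                ogtt_glucose={t: v for t, v in rec.ogtt_glucose.items()
                              if t in pattern.glucose_times},
                ogtt_insulin={t: v for t, v in rec.ogtt_insulin.items()
                              if t in pattern.insulin_times},
                uric_acid=rec.uric_acid, hba1c=rec.hba1c,
                comorbidities=dict(rec.comorbidities), cohort_id=rec.cohort_id,
            )
        new_records.append(rec)
    return CohortTable(records=new_records, provenance=cohort.provenance + "+missingness")


def verify_curve_consistency(cohort: CohortTable, truth: GroundTruth) -> float:
    """Max relative error between regenerated trapezoid AUCs and the drawn
    feature values, over complete records (should be ~1e-12)."""
    worst = 0.0
    for rec in cohort:
        if not rec.has_complete_ogtt():
            continue
        fv = truth.features[rec.patient_id]
        g = abs(trapezoid_auc(rec.ogtt_glucose) - fv.glucose_auc) / fv.glucose_auc
        i = abs(trapezoid_auc(rec.ogtt_insulin) - fv.insulin_auc) / fv.insulin_auc
        worst = max(worst, g, i)
    return worst
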