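"""Stepwise-regression estimation of OGTT AUCs from partial sampling.

Some cohorts measure only one to three of the four OGTT time points. For each
availability pattern, a linear model predicting the full four-point trapezoid
AUC from the concentrations at the present time points is trained on the
complete-data records (70/30 train/test split, stratified by sex) with
forward/backward stepwise selection: a predictor enters when its partial-F
p-value is below ``p_in`` (0.05) and leaves when it rises above ``p_out``
(0.10). Held-out fit quality is recorded as adjusted R-squared (and its
square root) on the 30% test split.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort_io import OGTT_GRID, CohortTable, PatientRecord
from .exceptions import NoImputationModelError, PatternError, SizeError
from .metabolic_features import FeatureVector, compute_features, trapezoid_auc

TARGETS = ("glucose_auc", "insulin_auc")


@dataclass(frozen=True)
class AvailabilityPattern:
    """Which OGTT time points are measured, per analyte."""

    glucose_times: frozenset[int]
    insulin_times: frozenset[int]

    def __post_init__(self):
        for name, times in (("glucose", self.glucose_times), ("insulin", self.insulin_times)):
            if not times:
                raise PatternError(f"{name} availability pattern is empty")
            bad = set(times) - set(OGTT_GRID)
            if bad:
                raise PatternError(f"{name} pattern has off-grid times {sorted(bad)}")

    @staticmethod
    def of(glucose_times, insulin_times=None) -> "AvailabilityPattern":
        g = frozenset(glucose_times)
        return AvailabilityPattern(g, g if insulin_times is None else frozenset(insulin_times))

    @staticmethod
    def of_record(record: PatientRecord) -> "AvailabilityPattern":
        return AvailabilityPattern(
            frozenset(t for t in OGTT_GRID if t in record.ogtt_glucose),
            frozenset(t for t in OGTT_GRID if t in record.ogtt_insulin),
        )

    def is_complete(self) -> bool:
        return self.glucose_times == set(OGTT_GRID) and self.insulin_times == set(OGTT_GRID)


def default_patterns() -> list[AvailabilityPattern]:
    """All availability patterns that retain the fasting sample (clinically
    always drawn), from fasting-only up to the full four-point curve."""
    pats = []
    rest = [t for t in OGTT_GRID if t != 0]
    for r in range(0, len(rest) + 1):
        for combo in itertools.combinations(rest, r):
            pats.append(AvailabilityPattern.of({0, *combo}))
    return pats


@dataclass
class StepwiseResult:
    """Outcome of one stepwise OLS fit."""

    selected: list[int]          # indices into the candidate columns, entry order
    intercept: float
    coef: np.ndarray             # aligned with ``selected``
    r2_train: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not self.selected:
            return np.full(X.shape[0], self.intercept)
        return self.intercept + X[:, self.selected] @ self.coef


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with intercept; returns (beta, p-values of slopes, r2, rank_ok)."""
    n = len(y)
    D = np.column_stack([np.ones(n), X])
    p = D.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    dof = n - p
    if dof <= 0 or rank < p:
        return beta, np.full(p - 1, np.nan), r2, False
    sigma2 = rss / dof
    XtX_inv = np.linalg.pinv(D.T @ D)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals[1:]), dof)
    return beta, pvals, r2, True


def stepwise_fit(
    X: np.ndarray,
    y: np.ndarray,
    p_in: float = 0.05,
    p_out: float = 0.10,
    max_steps: int = 100,
) -> StepwiseResult:
    """Forward-inclusion / backward-elimination OLS by partial F tests.

    At each forward step the candidate with the smallest partial-F p-value
    enters if that p-value is < ``p_in``; at each backward step the included
    predictor with the largest p-value leaves if it is > ``p_out``. With
    ``p_in < p_out`` the procedure cannot cycle; a step cap guards the
    boundary case. A rank-deficient selected set drops the later-entering
    collinear predictor with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if n <= m + 2:
        raise SizeError(f"stepwise fit needs n > candidates + 2, got n={n}, candidates={m}")
    selected: list[int] = []
    saturated_tol = 1e-12  # relative residual variance below which the fit is exact
    for _ in range(max_steps):
        changed = False
        # forward (skipped once the fit is numerically exact)
        _, _, r2_cur, _ = _ols(X[:, selected], y)
        candidates = [j for j in range(m) if j not in selected]
        best_j, best_p = None, np.inf
        if r2_cur < 1.0 - saturated_tol:
            for j in candidates:
                _, pvals, _, ok = _ols(X[:, selected + [j]], y)
                pj = pvals[-1]
                if not ok or np.isnan(pj):
                    continue
                if pj < best_p:
                    best_j, best_p = j, pj
        if best_j is not None and best_p < p_in:
            selected.append(best_j)
            changed = True
        # backward
        while selected:
            _, pvals, _, ok = _ols(X[:, selected], y)
            if np.all(np.isnan(pvals)):
                break  # exact fit: no meaningful tests, keep the model
            if not ok:
                dropped = selected.pop()  # later-entering collinear predictor
                warnings.warn(f"dropping collinear predictor column {dropped}", stacklevel=2)
                changed = True
                continue
            worst = int(np.nanargmax(pvals))
            if pvals[worst] > p_out:
                selected.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break
    beta, _, r2, _ = _ols(X[:, selected], y)
    return StepwiseResult(
        selected=list(selected),
        intercept=float(beta[0]),
        coef=np.asarray(beta[1:], dtype=float),
        r2_train=r2,
    )


@dataclass
class ImputationModel:
    """A trained AUC estimator for one (target, availability) combination."""

    target: str                      # "glucose_auc" | "insulin_auc"
    times: tuple[int, ...]           # present time points, sorted
    predictor_times: tuple[int, ...] # selected subset, entry order
    intercept: float
    coef: tuple[float, ...]          # per predictor_times entry
    adjusted_r2_test: float
    adjusted_r_test: float           # sqrt of max(adjusted_r2_test, 0)
    n_train: int
    n_test: int

    def predict(self, concentrations: dict[int, float]) -> float:
        val = self.intercept
        for t, c in zip(self.predictor_times, self.coef):
            val += c * concentrations[t]
        return float(val)

    def to_dict(self) -> dict:
        return {
            "target": self.target, "times": list(self.times),
            "predictor_times": list(self.predictor_times),
            "intercept": self.intercept, "coef": list(self.coef),
            "adjusted_r2_test": self.adjusted_r2_test,
            "adjusted_r_test": self.adjusted_r_test,
            "n_train": self.n_train, "n_test": self.n_test,
        }

    @staticmethod
    def from_dict(d: dict) -> "ImputationModel":
        return ImputationModel(
            target=d["target"], times=tuple(d["times"]),
            predictor_times=tuple(d["predictor_times"]),
            intercept=float(d["intercept"]), coef=tuple(float(c) for c in d["coef"]),
            adjusted_r2_test=float(d["adjusted_r2_test"]),
            adjusted_r_test=float(d["adjusted_r_test"]),
            n_train=int(d["n_train"]), n_test=int(d["n_test"]),
        )


@dataclass
class ImputationSuite:
    """One model per (target, present-times) pattern."""

    models: dict[tuple[str, tuple[int, ...]], ImputationModel] = field(default_factory=dict)

    def get(self, target: str, times) -> ImputationModel:
        key = (target, tuple(sorted(times)))
        if key not in self.models:
            trained = sorted({k[1] for k in self.models if k[0] == target})
            raise NoImputationModelError(
                f"no {target} model for present times {key[1]}; trained patterns: {trained}"
            )
        return self.models[key]

    def to_dict(self) -> dict:
        return {"models": [m.to_dict() for m in self.models.values()]}

    @staticmethod
    def from_dict(d: dict) -> "ImputationSuite":
        suite = ImputationSuite()
        for md in d["models"]:
            m = ImputationModel.from_dict(md)
            suite.models[(m.target, tuple(sorted(m.times)))] = m
        return suite


def _adjusted_r2(y_true: np.ndarray, y_pred: np.ndarray, n_params: int) -> float:
    n = len(y_true)
    rss = float(((y_true - y_pred) ** 2).sum())
    tss = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    dof = n - n_params - 1
    if dof <= 0:
        return math.nan
    return 1.0 - (1.0 - r2) * (n - 1) / dof


def train_imputation_suite(
    cohort: CohortTable,
    patterns: list[AvailabilityPattern] | None = None,
    test_fraction: float = 0.30,
    seed: int = 0,
    p_in: float = 0.05,
    p_out: float = 0.10,
) -> ImputationSuite:
    """Train the per-pattern AUC models on the complete-OGTT records.

    The split is 70/30 train/test, stratified by sex (clustering downstream is
    sex-stratified). The response is the exact four-point trapezoid AUC;
    candidate predictors are the raw concentrations at the pattern's present
    time points.
    """
    if patterns is None:
        patterns = default_patterns()
    complete = [rec for rec in cohort if rec.has_complete_ogtt()]
    if len(complete) < 20:
        raise SizeError(f"need >= 20 complete-OGTT records for a 70/30 split, got {len(complete)}")

    rng = np.random.default_rng(seed)
    test_mask = np.zeros(len(complete), dtype=bool)
    for sex in ("male", "female"):
        idx = np.array([i for i, r in enumerate(complete) if r.sex == sex])
        if idx.size == 0:
            continue
        n_test = int(round(test_fraction * idx.size))
        test_mask[rng.choice(idx, size=n_test, replace=False)] = True

    curves = {
        "glucose_auc": np.array(
            [[r.ogtt_glucose[t] for t in OGTT_GRID] for r in complete], dtype=float),
        "insulin_auc": np.array(
            [[r.ogtt_insulin[t] for t in OGTT_GRID] for r in complete], dtype=float),
    }
    aucs = {
        target: np.array(
            [trapezoid_auc(dict(zip(OGTT_GRID, row))) for row in mat], dtype=float)
        for target, mat in curves.items()
    }

    suite = ImputationSuite()
    time_col = {t: j for j, t in enumerate(OGTT_GRID)}
    for pattern in patterns:
        for target, times in (
            ("glucose_auc", pattern.glucose_times),
            ("insulin_auc", pattern.insulin_times),
        ):
            key = (target, tuple(sorted(times)))
            if key in suite.models:
                continue
            cols = [time_col[t] for t in key[1]]
            X = curves[target][:, cols]
            y = aucs[target]
            fit = stepwise_fit(X[~test_mask], y[~test_mask], p_in=p_in, p_out=p_out)
            pred_test = fit.predict(X[test_mask])
            adj_r2 = _adjusted_r2(y[test_mask], pred_test, len(fit.selected))
            suite.models[key] = ImputationModel(
                target=target,
                times=key[1],
                predictor_times=tuple(key[1][j] for j in fit.selected),
                intercept=fit.intercept,
                coef=tuple(float(c) for c in fit.coef),
                adjusted_r2_test=adj_r2,
                adjusted_r_test=math.sqrt(max(adj_r2, 0.0)),
                n_train=int((~test_mask).sum()),
                n_test=int(test_mask.sum()),
            )
    return suite


@dataclass(frozen=True)
class ImputedFeatures:
    """Feature vector plus provenance flags for estimated AUCs."""

    features: FeatureVector
    glucose_imputed: bool
    insulin_imputed: bool
    glucose_r2: float | None = None   # held-out adjusted R2 of the model used
    insulin_r2: float | None = None


def impute_features(record: PatientRecord, suite: ImputationSuite) -> ImputedFeatures:
    """Features for a record with possibly incomplete OGTT sampling.

    Complete records bypass the suite entirely and return the exact trapezoid
    features; otherwise the matching per-pattern model estimates each missing
    AUC and the result is flagged as imputed.
    """
    pattern = AvailabilityPattern.of_record(record)
    if pattern.is_complete():
        return ImputedFeatures(compute_features(record), False, False)
    g_complete = pattern.glucose_times == set(OGTT_GRID)
    i_complete = pattern.insulin_times == set(OGTT_GRID)
    g_r2 = i_r2 = None
    if g_complete:
        g_auc = trapezoid_auc(record.ogtt_glucose)
    else:
        m = suite.get("glucose_auc", pattern.glucose_times)
        g_auc = m.predict(record.ogtt_glucose)
        g_r2 = m.adjusted_r2_test
    if i_complete:
        i_auc = trapezoid_auc(record.ogtt_insulin)
    else:
        m = suite.get("insulin_auc", pattern.insulin_times)
        i_auc = m.predict(record.ogtt_insulin)
        i_r2 = m.adjusted_r2_test
    return ImputedFeatures(
        FeatureVector(g_auc, i_auc, record.uric_acid),
        glucose_imputed=not g_complete,
        insulin_imputed=not i_complete,
        glucose_r2=g_r2,
        insulin_r2=i_r2,
    )
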