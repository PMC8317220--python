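"""Comorbidity statistics across subtypes.

Adjusted odds ratios (AOR) come from binary logistic regression of each
comorbidity on subtype (MHO as the reference category) plus sex and age, with
Wald 95% confidence intervals — matching the convention of mainstream
clinical statistics software. Categorical contrasts use Pearson chi-square;
continuous variables are compared by ANOVA/ANCOVA on optionally transformed
values with Bonferroni-corrected pairwise contrasts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .cohort_io import CohortTable
from .exceptions import ConfigError, DegenerateTableError, TransformError
from .subtype_clustering import SUBTYPE_ORDER, Partition

_Z975 = 1.959963984540054
_SEPARATION_COEF = 15.0   # |log-odds| beyond this flags (quasi-)separation


def _safe_exp(x: float) -> float:
    try:
        return math.exp(x)
    except OverflowError:
        return math.inf


@dataclass
class LogisticFit:
    """Coefficients and covariance of a logistic maximum-likelihood fit."""

    names: tuple[str, ...]
    coef: np.ndarray
    cov: np.ndarray
    converged: bool
    separation: bool

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def fit_logistic(outcome: np.ndarray, design: pd.DataFrame) -> LogisticFit:
    """Binary logistic regression by iteratively reweighted least squares.

    ``design`` holds the non-intercept columns; an intercept is prepended.
    (Quasi-)separation is flagged — huge coefficients or exploding standard
    errors — rather than raised, so a cohort run survives a comorbidity with
    zero cases in some subtype.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ConfigError("outcome must be binary 0/1")
    X = sm.add_constant(design.astype(float), has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = model.fit(maxiter=50, tol=1e-8)
    coef = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    separation = bool(
        np.any(np.abs(coef[1:]) > _SEPARATION_COEF) or not np.all(np.isfinite(cov))
    )
    return LogisticFit(
        names=tuple(X.columns),
        coef=coef,
        cov=cov,
        converged=bool(res.converged),
        separation=separation,
    )


@dataclass
class ComorbidityResult:
    """AOR of one comorbidity per subtype versus MHO, adjusted for covariates."""

    comorbidity: str
    subtype: str
    aor: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted_for: tuple[str, ...]
    separation: bool = False


def aor_table(
    cohort: CohortTable,
    partition: Partition,
    comorbidities: list[str] | None = None,
    reference: str = "MHO",
) -> list[ComorbidityResult]:
    """Sex- and age-adjusted odds ratios of each comorbidity per subtype.

    One logistic model per comorbidity: outcome ~ subtype dummies + female +
    age, fit on records whose comorbidity state is known. AOR = exp(beta)
    with Wald 95% CI exp(beta +/- 1.96*SE). The reference subtype's AOR is 1
    by construction and is included for table completeness.
    """
    label_of = partition.label_of()
    if comorbidities is None:
        comorbidities = cohort.comorbidity_names()
    subtypes = [s for s in SUBTYPE_ORDER if s in partition.label_set()]
    if reference not in subtypes:
        raise ConfigError(f"reference subtype {reference!r} absent from partition")
    non_ref = [s for s in subtypes if s != reference]

    results: list[ComorbidityResult] = []
    for name in comorbidities:
        rows, ys = [], []
        for rec in cohort:
            state = rec.comorbidities.get(name, "unknown")
            if state == "unknown" or rec.patient_id not in label_of:
                continue
            subtype = label_of[rec.patient_id]
            row = {f"subtype_{s}": float(subtype == s) for s in non_ref}
            row["female"] = float(rec.sex == "female")
            row["age"] = rec.age
            rows.append(row)
            ys.append(1.0 if state == "present" else 0.0)
        design = pd.DataFrame(rows)
        fit = fit_logistic(np.array(ys), design)
        se = fit.se()
        results.append(
            ComorbidityResult(name, reference, 1.0, 1.0, 1.0, math.nan,
                              ("sex", "age"), False)
        )
        for s in non_ref:
            j = fit.names.index(f"subtype_{s}")
            beta, sej = fit.coef[j], se[j]
            z = beta / sej if sej > 0 else math.inf
            p = 2.0 * stats.norm.sf(abs(z))
            lo, hi = _safe_exp(beta - _Z975 * sej), _safe_exp(beta + _Z975 * sej)
            if fit.separation and (not math.isfinite(hi) or hi > 1e6):
                lo, hi = 0.0, math.inf
            results.append(
                ComorbidityResult(name, s, _safe_exp(beta), lo, hi, p,
                                  ("sex", "age"), fit.separation)
            )
    return results


def aor_frame(results: list[ComorbidityResult]) -> pd.DataFrame:
    """Long-format AOR table (one row per comorbidity x subtype)."""
    return pd.DataFrame(
        [
            {"comorbidity": r.comorbidity, "subtype": r.subtype, "aor": r.aor,
             "ci_low": r.ci_low, "ci_high": r.ci_high, "p_value": r.p_value,
             "separation": r.separation}
            for r in results
        ]
    )


def chi_square(contingency: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square test on an r x c count table; returns (statistic, p)."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or np.any(table < 0) or table.sum() == 0:
        raise ConfigError("contingency must be a non-negative 2-D table with n > 0")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateTableError("contingency table has a zero marginal")
    statistic, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(statistic), float(p)


def _transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return values
    if transform == "log":
        bad = np.flatnonzero(values <= 0)
        if bad.size:
            raise TransformError(f"log transform undefined at rows {bad.tolist()}")
        return np.log(values)
    if transform == "sqrt":
        bad = np.flatnonzero(values < 0)
        if bad.size:
            raise TransformError(f"sqrt transform undefined at rows {bad.tolist()}")
        return np.sqrt(values)
    raise ConfigError(f"unknown transform {transform!r}")


@dataclass
class GroupComparison:
    """Omnibus ANOVA/ANCOVA p-value plus Bonferroni-adjusted pairwise p's."""

    omnibus_f: float
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float]
    transform: str
    covariates: tuple[str, ...]


def group_compare(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: pd.DataFrame | None = None,
    transform: str = "none",
) -> GroupComparison:
    """Compare a continuous variable across subtypes.

    One-way ANOVA (or ANCOVA when ``covariates`` are given, entering as
    linear terms) on the transformed values; pairwise contrasts are refit per
    subtype pair with raw p multiplied by the number of pairs (capped at 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(set(groups.tolist()))
    if len(names) < 2 or any((groups == g).sum() < 2 for g in names):
        raise ConfigError("need >= 2 groups with >= 2 members each")
    y = _transform(values, transform)
    data = pd.DataFrame({"y": y, "group": groups})
    cov_terms = ""
    cov_names: tuple[str, ...] = ()
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        for c in covariates.columns:
            data[c] = np.asarray(covariates[c], dtype=float)
        cov_names = tuple(covariates.columns)
        cov_terms = " + " + " + ".join(cov_names)
    fit = smf.ols(f"y ~ C(group){cov_terms}", data=data).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    omnibus_f = float(anova.loc["C(group)", "F"])
    omnibus_p = float(anova.loc["C(group)", "PR(>F)"])

    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    pairwise: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        sub = data[data["group"].isin([a, b])]
        pfit = smf.ols(f"y ~ C(group){cov_terms}", data=sub).fit()
        panova = sm.stats.anova_lm(pfit, typ=2)
        raw = float(panova.loc["C(group)", "PR(>F)"])
        pairwise[(a, b)] = min(1.0, raw * m)
    return GroupComparison(
        omnibus_f=omnibus_f, omnibus_p=omnibus_p, pairwise_p=pairwise,
        transform=transform, covariates=cov_names,
    )
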