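"""Assignment of external cohorts to a fitted model and agreement metrics.

A verification cohort is (a) clustered independently with the same algorithm
(the reference partition) and (b) assigned patient-by-patient to the main
model's nearest center in its normalized space — Euclidean distance for
k-means models, the log-likelihood distance increment for two-step models.
After optimally matching the two partitions' cluster labels, per-cluster
one-vs-rest accuracy/sensitivity/specificity and Jaccard coefficients
quantify agreement; a mean Jaccard above 0.750 is conventionally read as a
stable clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .cohort_io import CohortTable
from .exceptions import MatchingError, SizeError
from .metabolic_features import compute_features
from .subtype_clustering import (
    ClusterConfig,
    ClusterModel,
    FitResult,
    Partition,
    fit_sex_stratified,
    zscore_apply,
)


def _twostep_point_distance(z: np.ndarray, stratum) -> np.ndarray:
    """Log-likelihood distance increment from adding one point to each cluster.

    Uses the stored per-cluster summary statistics (count and within-cluster
    variances) in normalized space: d(x, c) = xi_c + xi_x - xi_{c + x}.
    """
    n_c = stratum.cluster_n
    within = stratum.cluster_within_var
    overall = stratum.overall_var
    centers = stratum.centers_normalized()
    k, _ = centers.shape
    dist = np.empty(k)
    xi_x = -0.5 * np.log(overall).sum()  # singleton: zero within-variance
    for j in range(k):
        xi_c = -n_c[j] * 0.5 * np.log(overall + within[j]).sum()
        n_m = n_c[j] + 1.0
        mean_m = (n_c[j] * centers[j] + z) / n_m
        # combined sum of squares from cluster moments + the new point
        q = n_c[j] * (within[j] + centers[j] ** 2) + z**2
        var_m = np.maximum(q / n_m - mean_m**2, 0.0)
        xi_m = -n_m * 0.5 * np.log(overall + var_m).sum()
        dist[j] = xi_c + xi_x - xi_m
    return dist


def assign_to_model(
    model: ClusterModel, cohort: CohortTable, imputation_suite=None
) -> Partition:
    """Assign every patient to the nearest cluster of the fitted model.

    The patient's sex selects the stratum whose stored normalization and
    centers apply (the main model's parameters, so the model stays portable
    across cohorts). Deterministic; ties break toward the lower-index center.
    """
    from .auc_imputation import impute_features

    ids: list[str] = []
    labels: list[str] = []
    sexes: list[str] = []
    for rec in cohort:
        stratum = model.strata[rec.sex]
        if rec.has_complete_ogtt() or imputation_suite is None:
            fv = compute_features(rec)
        else:
            fv = impute_features(rec, imputation_suite).features
        z = zscore_apply(stratum.normalization, fv.as_array())
        if model.algorithm == "twostep" and stratum.cluster_n is not None:
            dist = _twostep_point_distance(z, stratum)
        else:
            dist = cdist(z[None, :], stratum.centers_normalized(), "euclidean")[0]
        ids.append(rec.patient_id)
        labels.append(model.labels[int(np.argmin(dist))])
        sexes.append(rec.sex)
    return Partition(tuple(ids), tuple(labels), tuple(sexes))


def _contingency(reference: Partition, assigned: Partition):
    if set(reference.patient_ids) != set(assigned.patient_ids):
        raise MatchingError("partitions cover different patients")
    ref_labels = reference.label_set()
    asg_labels = assigned.label_set()
    asg_of = assigned.label_of()
    table = np.zeros((len(ref_labels), len(asg_labels)), dtype=int)
    ri = {l: i for i, l in enumerate(ref_labels)}
    ai = {l: i for i, l in enumerate(asg_labels)}
    for pid, rl in zip(reference.patient_ids, reference.labels):
        table[ri[rl], ai[asg_of[pid]]] += 1
    return table, ref_labels, asg_labels


def match_clusters(reference: Partition, assigned: Partition) -> dict[str, str]:
    """Optimal one-to-one matching of assigned labels onto reference labels.

    Maximizes total agreement over the k x k contingency table (Hungarian
    assignment). Returns {assigned label -> reference label}.
    """
    table, ref_labels, asg_labels = _contingency(reference, assigned)
    if len(ref_labels) != len(asg_labels):
        raise MatchingError(
            f"partitions have different cluster counts "
            f"({len(ref_labels)} vs {len(asg_labels)})",
            contingency=table,
        )
    rows, cols = linear_sum_assignment(-table)
    return {asg_labels[c]: ref_labels[r] for r, c in zip(rows, cols)}


@dataclass
class AssignmentReport:
    """Per-cluster agreement metrics between a reference and an assigned
    partition, after label matching.

    ``confusion`` rows are reference clusters, columns assigned clusters, in
    ``cluster_labels`` order. Accuracy/sensitivity/specificity are one-vs-rest
    per cluster; Jaccard is on matched member sets. Zero-denominator metrics
    are NaN and listed in ``flags``.
    """

    cluster_labels: tuple[str, ...]
    confusion: np.ndarray
    accuracy: dict[str, float]
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    jaccard: dict[str, float]
    mean_accuracy: float
    mean_sensitivity: float
    mean_specificity: float
    mean_jaccard: float
    matching: dict[str, str]
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "clusters": list(self.cluster_labels),
            "confusion": self.confusion.tolist(),
            "per_cluster": {
                l: {
                    "accuracy": self.accuracy[l],
                    "sensitivity": self.sensitivity[l],
                    "specificity": self.specificity[l],
                    "jaccard": self.jaccard[l],
                }
                for l in self.cluster_labels
            },
            "mean": {
                "accuracy": self.mean_accuracy,
                "sensitivity": self.mean_sensitivity,
                "specificity": self.mean_specificity,
                "jaccard": self.mean_jaccard,
            },
            "matching": self.matching,
            "flags": self.flags,
        }


def agreement_report(
    reference: Partition, assigned: Partition, matching: dict[str, str] | None = None
) -> AssignmentReport:
    """Confusion-based agreement metrics after cluster matching."""
    if matching is None:
        matching = match_clusters(reference, assigned)
    relabeled = Partition(
        assigned.patient_ids,
        tuple(matching[l] for l in assigned.labels),
        assigned.strata,
    )
    ref_labels = reference.label_set()
    n = len(reference)
    rel_of = relabeled.label_of()
    idx = {l: i for i, l in enumerate(ref_labels)}
    confusion = np.zeros((len(ref_labels), len(ref_labels)), dtype=int)
    for pid, rl in zip(reference.patient_ids, reference.labels):
        al = rel_of[pid]
        if al in idx:
            confusion[idx[rl], idx[al]] += 1
    acc, sen, spe, jac = {}, {}, {}, {}
    flags: list[str] = []
    for l in ref_labels:
        i = idx[l]
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        tn = n - tp - fn - fp
        acc[l] = (tp + tn) / n
        sen[l] = tp / (tp + fn) if tp + fn > 0 else float("nan")
        spe[l] = tn / (tn + fp) if tn + fp > 0 else float("nan")
        if tp + fn == 0:
            flags.append(f"cluster {l!r}: empty in reference (sensitivity undefined)")
        a_members = reference.members(l)
        b_members = relabeled.members(l)
        union = a_members | b_members
        jac[l] = len(a_members & b_members) / len(union) if union else float("nan")
        if not union:
            flags.append(f"cluster {l!r}: empty in both partitions (Jaccard undefined)")
    return AssignmentReport(
        cluster_labels=ref_labels,
        confusion=confusion,
        accuracy=acc,
        sensitivity=sen,
        specificity=spe,
        jaccard=jac,
        mean_accuracy=float(np.nanmean(list(acc.values()))),
        mean_sensitivity=float(np.nanmean(list(sen.values()))),
        mean_specificity=float(np.nanmean(list(spe.values()))),
        mean_jaccard=float(np.nanmean(list(jac.values()))),
        matching=matching,
        flags=flags,
    )


@dataclass
class VerificationResult:
    report: AssignmentReport
    reference: Partition      # independent clustering of the verification cohort
    assigned: Partition       # nearest-center assignment to the main model
    reference_fit: FitResult


def verification_run(
    model: ClusterModel,
    verification_cohort: CohortTable,
    config: ClusterConfig | None = None,
    seed: int = 0,
    imputation_suite=None,
) -> VerificationResult:
    """Full cross-cohort validation of a fitted model on a new cohort.

    Clusters the verification cohort independently with the model's own
    algorithm (reference), assigns its patients to the main model's centers
    (assigned), and reports per-cluster agreement after optimal matching.
    """
    if len(verification_cohort) <= 40:
        raise SizeError(
            f"verification cohort too small to cluster independently "
            f"(n={len(verification_cohort)}, need > 40)"
        )
    fit = fit_sex_stratified(
        verification_cohort, algorithm=model.algorithm, config=config, seed=seed,
        imputation_suite=imputation_suite,
    )
    assigned = assign_to_model(model, verification_cohort, imputation_suite)
    report = agreement_report(fit.partition, assigned)
    return VerificationResult(
        report=report, reference=fit.partition, assigned=assigned, reference_fit=fit
    )
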