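"""Sex-stratified discovery of the four metabolic obesity subtypes.

The clustering variables (glucose AUC, insulin AUC, uric acid) are
z-normalized per sex stratum, then clustered either by k-means (Lloyd
iterations from k-means++ starts, best of ``n_init`` restarts, cluster count
chosen by maximum mean silhouette width) or by a two-step-style agglomeration
(log-likelihood inter-cluster distance, cluster count chosen by minimum
Schwarz BIC). The two sex sub-models are pooled into one partition and the
four clusters are named by a deterministic rule on the de-normalized centers:
highest glucose AUC = LMO, then highest insulin AUC = HMO-I, then highest
uric acid = HMO-U, remainder = MHO.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .cohort_io import SEXES, CohortTable
from .exceptions import (
    ConfigError,
    DegenerateVariableError,
    LabelingError,
    SizeError,
    StratumError,
)
from .metabolic_features import FEATURE_NAMES, FeatureVector, compute_features

SUBTYPE_ORDER = ("MHO", "HMO-U", "HMO-I", "LMO")

#: two-step BIC parameter count per cluster: mean + variance per variable
_PARAMS_PER_CLUSTER_FACTOR = 2


# --- normalization -----------------------------------------------------------

@dataclass
class NormalizationParams:
    """Per-variable mean and SD (sample SD, ddof=1) of the clustering variables."""

    mean: np.ndarray
    sd: np.ndarray

    def to_dict(self) -> dict:
        return {"mean": list(map(float, self.mean)), "sd": list(map(float, self.sd))}

    @staticmethod
    def from_dict(d: dict) -> "NormalizationParams":
        return NormalizationParams(np.asarray(d["mean"], float), np.asarray(d["sd"], float))


def zscore_fit(features: np.ndarray) -> NormalizationParams:
    """Fit per-variable z-normalization (mean 0, SD 1) on a feature matrix."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise SizeError("z-normalization needs at least 2 observations")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = [FEATURE_NAMES[j] for j in np.flatnonzero(sd <= 0)]
        raise DegenerateVariableError(f"zero spread in variable(s) {bad}")
    return NormalizationParams(mean=mean, sd=sd)


def zscore_apply(params: NormalizationParams, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - params.mean) / params.sd


def zscore_invert(params: NormalizationParams, Z: np.ndarray) -> np.ndarray:
    return np.asarray(Z, dtype=float) * params.sd + params.mean


# --- k-means -----------------------------------------------------------------

@dataclass
class KMeansResult:
    centers: np.ndarray
    labels: np.ndarray
    wcss: float
    n_iter: int


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    idx = [int(rng.integers(n))]
    d2 = ((X - X[idx[0]]) ** 2).sum(axis=1)
    for _ in range(1, k):
        total = d2.sum()
        if total > 0:
            j = int(rng.choice(n, p=d2 / total))
        else:  # all remaining distances zero (duplicates / k == n)
            remaining = [i for i in range(n) if i not in idx]
            j = int(rng.choice(remaining))
        idx.append(j)
        d2 = np.minimum(d2, ((X - X[j]) ** 2).sum(axis=1))
    return X[idx].copy()


def kmeans_cluster(
    points: np.ndarray,
    k: int,
    *,
    n_init: int = 20,
    max_iter: int = 30,
    tol: float = 1e-5,
    seed: int = 0,
) -> KMeansResult:
    """Lloyd's k-means: best of ``n_init`` k-means++ starts by WCSS.

    Iterations stop when the largest center movement drops below ``tol`` or
    after ``max_iter`` sweeps; an emptied cluster is re-seeded at the point
    farthest from its nearest center.
    """
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ConfigError("k must be >= 2")
    if n < k:
        raise SizeError(f"need at least k={k} points, got n={n}")
    rng = np.random.default_rng(seed)
    best: KMeansResult | None = None
    for _ in range(n_init):
        centers = _kmeanspp_init(X, k, rng)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            d2 = cdist(X, centers, "sqeuclidean")
            labels = d2.argmin(axis=1)
            new_centers = centers.copy()
            for j in range(k):
                mask = labels == j
                if mask.any():
                    new_centers[j] = X[mask].mean(axis=0)
                else:
                    new_centers[j] = X[d2.min(axis=1).argmax()]
            shift = float(np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max())
            centers = new_centers
            if shift < tol:
                break
        d2 = cdist(X, centers, "sqeuclidean")
        labels = d2.argmin(axis=1)
        wcss = float(d2[np.arange(n), labels].sum())
        if best is None or wcss < best.wcss:
            best = KMeansResult(centers=centers, labels=labels, wcss=wcss, n_iter=n_iter)
    assert best is not None
    return best


def mean_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width (b - a)/max(a, b), Euclidean metric.

    Members of singleton clusters contribute 0.
    """
    X = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ConfigError("silhouette is undefined for a single cluster")
    D = squareform(pdist(X))
    n = X.shape[0]
    s = np.zeros(n)
    masks = {c: labels == c for c in uniq}
    for i in range(n):
        own = masks[labels[i]]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, masks[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def select_k(
    points: np.ndarray,
    k_range=range(2, 9),
    *,
    n_init: int = 20,
    max_iter: int = 30,
    tol: float = 1e-5,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Pick the cluster count maximizing mean silhouette width over ``k_range``.

    Returns ``(best_k, {k: silhouette})``; ties break toward smaller k. A low
    best silhouette (reported in the map) signals absence of structure.
    """
    X = np.asarray(points, dtype=float)
    sils: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k < X.shape[0]:
            raise ConfigError(f"k={k} outside (2, n)")
        res = kmeans_cluster(X, k, n_init=n_init, max_iter=max_iter, tol=tol, seed=seed + k)
        sils[k] = mean_silhouette(X, res.labels)
    best_k = max(sorted(sils), key=lambda k: sils[k])
    return best_k, sils


# --- two-step (log-likelihood agglomeration + Schwarz BIC) -------------------

@dataclass
class TwoStepResult:
    centers: np.ndarray
    labels: np.ndarray
    k: int
    bic: dict[int, float]
    merge_sequence: list[tuple[tuple[int, ...], tuple[int, ...]]]
    cluster_n: np.ndarray
    cluster_within_var: np.ndarray   # (k, d), biased within-cluster variances
    overall_var: np.ndarray          # (d,), biased variance of the full stratum


def _xi(N, S, Q, overall_var):
    """Log-likelihood term xi of a cluster from its count/sum/sum-of-squares.

    xi = -N * sum_d 0.5*log(sigma_d^2 + s_d^2) with sigma_d^2 the stratum-wide
    variance (regularizer, keeps singletons finite) and s_d^2 the biased
    within-cluster variance.
    """
    N = np.asarray(N, dtype=float)
    mean = S / N[..., None]
    var = Q / N[..., None] - mean**2
    var = np.maximum(var, 0.0)
    return -N * 0.5 * np.log(overall_var + var).sum(axis=-1)


def twostep_cluster(
    points: np.ndarray, max_k: int = 8, force_k: int | None = None
) -> TwoStepResult:
    """Agglomerative clustering with the log-likelihood merge distance.

    Starting from singletons, repeatedly merge the pair (j, s) minimizing
    d(j, s) = xi_j + xi_s - xi_{j union s}; the cluster count is the k <= max_k
    minimizing Schwarz BIC(k) = -2*sum_clusters(xi) + 2*d*k*log(n)
    (2 parameters, mean and variance, per variable per cluster), unless
    ``force_k`` pins it.
    """
    X = np.asarray(points, dtype=float)
    n, d = X.shape
    if n < 4:
        raise SizeError(f"two-step clustering needs n >= 4, got {n}")
    overall_var = X.var(axis=0, ddof=0)
    if np.any(overall_var <= 0):
        raise DegenerateVariableError("a variable has zero overall variance")

    N = np.ones(n)
    S = X.copy()
    Q = X**2
    xi = _xi(N, S, Q, overall_var)
    active = np.ones(n, dtype=bool)
    members: list[list[int]] = [[i] for i in range(n)]
    labels = np.arange(n)

    # pairwise merge distances, inf where inactive/diagonal
    D = np.full((n, n), np.inf)
    for i in range(n):
        Nm = N[i] + N
        Sm = S[i] + S
        Qm = Q[i] + Q
        xim = _xi(Nm, Sm, Qm, overall_var)
        D[i] = xi[i] + xi - xim
    np.fill_diagonal(D, np.inf)

    merge_sequence: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    snapshots: dict[int, tuple[np.ndarray, float]] = {}
    n_active = n
    cap = max_k if force_k is None else max(max_k, force_k)
    if n_active <= cap:
        snapshots[n_active] = (labels.copy(), float(xi[active].sum()))
    while n_active > 1:
        flat = int(np.argmin(D))
        j, s = divmod(flat, n)
        if j > s:
            j, s = s, j
        merge_sequence.append((tuple(members[j]), tuple(members[s])))
        N[j] += N[s]
        S[j] += S[s]
        Q[j] += Q[s]
        xi[j] = _xi(N[j], S[j], Q[j], overall_var)
        members[j] = members[j] + members[s]
        labels[labels == s] = j
        active[s] = False
        D[s, :] = np.inf
        D[:, s] = np.inf
        idx = np.flatnonzero(active)
        idx = idx[idx != j]
        if idx.size:
            Nm = N[j] + N[idx]
            Sm = S[j] + S[idx]
            Qm = Q[j] + Q[idx]
            xim = _xi(Nm, Sm, Qm, overall_var)
            dist = xi[j] + xi[idx] - xim
            D[j, idx] = dist
            D[idx, j] = dist
        D[j, j] = np.inf
        n_active -= 1
        if n_active <= cap:
            snapshots[n_active] = (labels.copy(), float(xi[active].sum()))

    bic = {
        k: -2.0 * xi_total + _PARAMS_PER_CLUSTER_FACTOR * d * k * np.log(n)
        for k, (_, xi_total) in snapshots.items()
        if k <= max_k
    }
    if force_k is not None:
        if force_k not in snapshots:
            raise SizeError(f"cannot cut the merge tree at k={force_k} (n={n})")
        k = force_k
    else:
        k = min(sorted(bic), key=lambda kk: bic[kk])
    raw_labels, _ = snapshots[k]
    uniq = np.unique(raw_labels)
    relabel = {c: j for j, c in enumerate(uniq)}
    final = np.array([relabel[c] for c in raw_labels])
    centers = np.vstack([X[final == j].mean(axis=0) for j in range(k)])
    cluster_n = np.array([(final == j).sum() for j in range(k)], dtype=float)
    within = np.vstack([X[final == j].var(axis=0, ddof=0) for j in range(k)])
    return TwoStepResult(
        centers=centers, labels=final, k=k, bic=bic, merge_sequence=merge_sequence,
        cluster_n=cluster_n, cluster_within_var=within, overall_var=overall_var,
    )


# --- labeling ----------------------------------------------------------------

def label_subtypes(centers: np.ndarray) -> list[str]:
    """Name four cluster centers (raw units, columns = glucose_auc,
    insulin_auc, uric_acid) by the deterministic rule: highest glucose AUC =
    LMO; of the rest, highest insulin AUC = HMO-I; of the remaining two,
    highest uric acid = HMO-U; the last is MHO."""
    C = np.asarray(centers, dtype=float)
    if C.shape != (4, 3):
        raise LabelingError(f"subtype labeling needs exactly 4 centers, got shape {C.shape}")
    labels = [""] * 4
    order = list(range(4))

    def _take(rows, col, name):
        vals = [C[r, col] for r in rows]
        top = max(vals)
        winners = [r for r, v in zip(rows, vals) if v == top]
        if len(winners) > 1:
            raise LabelingError(f"tie in deciding variable for {name}")
        labels[winners[0]] = name
        return [r for r in rows if r != winners[0]]

    order = _take(order, 0, "LMO")
    order = _take(order, 1, "HMO-I")
    order = _take(order, 2, "HMO-U")
    labels[order[0]] = "MHO"
    return labels


# --- model / partition containers -------------------------------------------

@dataclass
class StratumModel:
    """One sex sub-model: normalization plus centers in raw units.

    ``cluster_n``/``cluster_within_var``/``overall_var`` (normalized space)
    are carried for two-step models so new points can be assigned by the
    log-likelihood distance; they are None for k-means models.
    """

    normalization: NormalizationParams
    centers_raw: np.ndarray
    cluster_n: np.ndarray | None = None
    cluster_within_var: np.ndarray | None = None
    overall_var: np.ndarray | None = None

    def centers_normalized(self) -> np.ndarray:
        return zscore_apply(self.normalization, self.centers_raw)

    def to_dict(self) -> dict:
        def opt(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "normalization": self.normalization.to_dict(),
            "centers": np.asarray(self.centers_raw).tolist(),
            "cluster_n": opt(self.cluster_n),
            "cluster_within_var": opt(self.cluster_within_var),
            "overall_var": opt(self.overall_var),
        }

    @staticmethod
    def from_dict(d: dict) -> "StratumModel":
        def opt(a):
            return None if a is None else np.asarray(a, dtype=float)

        return StratumModel(
            normalization=NormalizationParams.from_dict(d["normalization"]),
            centers_raw=np.asarray(d["centers"], dtype=float),
            cluster_n=opt(d.get("cluster_n")),
            cluster_within_var=opt(d.get("cluster_within_var")),
            overall_var=opt(d.get("overall_var")),
        )


@dataclass
class ClusterModel:
    """The portable main model: per-sex sub-models plus shared labels.

    Center row i in every stratum carries ``labels[i]``; for four-cluster
    models the order is the canonical (MHO, HMO-U, HMO-I, LMO).
    """

    algorithm: str                   # "kmeans" | "twostep"
    strata: dict[str, StratumModel]
    labels: tuple[str, ...]
    k: int
    mean_silhouette: float

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "k": self.k,
            "labels": list(self.labels),
            "mean_silhouette": self.mean_silhouette,
            "strata": {sex: sm.to_dict() for sex, sm in self.strata.items()},
        }

    @staticmethod
    def from_dict(d: dict) -> "ClusterModel":
        return ClusterModel(
            algorithm=d["algorithm"],
            strata={sex: StratumModel.from_dict(sd) for sex, sd in d["strata"].items()},
            labels=tuple(d["labels"]),
            k=int(d["k"]),
            mean_silhouette=float(d["mean_silhouette"]),
        )


@dataclass
class Partition:
    """Cluster membership of a cohort: one label per patient, plus sex tags."""

    patient_ids: tuple[str, ...]
    labels: tuple[str, ...]
    strata: tuple[str, ...]

    def __post_init__(self):
        if not (len(self.patient_ids) == len(self.labels) == len(self.strata)):
            raise ConfigError("partition fields must be equal length")

    def __len__(self) -> int:
        return len(self.patient_ids)

    def label_of(self) -> dict[str, str]:
        return dict(zip(self.patient_ids, self.labels))

    def members(self, label: str) -> frozenset[str]:
        return frozenset(p for p, l in zip(self.patient_ids, self.labels) if l == label)

    def label_set(self) -> tuple[str, ...]:
        seen: list[str] = []
        for l in self.labels:
            if l not in seen:
                seen.append(l)
        return tuple(sorted(seen))

    def shares(self) -> dict[str, float]:
        n = len(self)
        return {l: len(self.members(l)) / n for l in self.label_set()}


# --- sex-stratified fit ------------------------------------------------------

@dataclass
class ClusterConfig:
    """Tunables for the sex-stratified fit.

    ``k_range`` bounds the silhouette search (k-means) and BIC search
    (two-step); ``fixed_k`` pins the cluster count instead. Normalization is
    per sex stratum unless ``pooled_normalization``.
    """

    k_range: tuple[int, int] = (2, 8)
    n_init: int = 20
    max_iter: int = 30
    tol: float = 1e-5
    fixed_k: int | None = None
    pooled_normalization: bool = False


@dataclass
class FitResult:
    model: ClusterModel
    partition: Partition
    stratum_silhouette: dict[str, float] = field(default_factory=dict)
    stratum_k: dict[str, int] = field(default_factory=dict)


def _stratum_features(cohort: CohortTable, imputation_suite=None):
    """Per-sex (patient_ids, feature matrix); imputes incomplete records if a
    suite is supplied, else requires complete OGTT curves."""
    from .auc_imputation import impute_features  # local import avoids cycle at import time

    out = {sex: ([], []) for sex in SEXES}
    for rec in cohort:
        if rec.sex not in out:
            raise StratumError(f"unknown sex {rec.sex!r} for patient {rec.patient_id!r}")
        if rec.has_complete_ogtt():
            fv = compute_features(rec)
        elif imputation_suite is not None:
            fv = impute_features(rec, imputation_suite).features
        else:
            fv = compute_features(rec)  # raises IncompleteCurveError
        ids, feats = out[rec.sex]
        ids.append(rec.patient_id)
        feats.append(fv.as_array())
    result = {}
    for sex, (ids, feats) in out.items():
        # sort by patient id so the fit is invariant to input record order
        order = np.argsort(np.asarray(ids, dtype=object))
        result[sex] = ([ids[j] for j in order], np.array(feats)[order] if feats else np.empty((0, 3)))
    return result


def fit_sex_stratified(
    cohort: CohortTable,
    algorithm: str = "kmeans",
    config: ClusterConfig | None = None,
    seed: int = 0,
    imputation_suite=None,
) -> FitResult:
    """Fit the full sex-stratified model and pool the sub-model partitions.

    Each sex stratum is z-normalized and clustered separately; if the two
    strata select different cluster counts, the larger stratum's k is imposed
    on both with a warning. De-normalized centers are subtype-labeled and
    re-ordered canonically, so center row i means the same subtype in both
    strata.
    """
    if algorithm not in ("kmeans", "twostep"):
        raise ConfigError(f"unknown algorithm {algorithm!r}")
    cfg = config or ClusterConfig()
    strata_feats = _stratum_features(cohort, imputation_suite)
    for sex in SEXES:
        ids, _ = strata_feats[sex]
        if len(ids) <= 10:
            raise StratumError(f"stratum {sex!r} has n={len(ids)} (need > 10)")

    pooled_params = None
    if cfg.pooled_normalization:
        pooled_params = zscore_fit(np.vstack([strata_feats[s][1] for s in SEXES]))

    def _cluster(X, params, k_forced, sex_seed):
        Z = zscore_apply(params, X)
        if algorithm == "kmeans":
            if k_forced is not None:
                k = k_forced
            elif cfg.fixed_k is not None:
                k = cfg.fixed_k
            else:
                k, _ = select_k(
                    Z, range(cfg.k_range[0], cfg.k_range[1] + 1),
                    n_init=cfg.n_init, max_iter=cfg.max_iter, tol=cfg.tol, seed=sex_seed,
                )
            res = kmeans_cluster(
                Z, k, n_init=cfg.n_init, max_iter=cfg.max_iter, tol=cfg.tol, seed=sex_seed
            )
            extras = (None, None, None)
            return Z, res.centers, res.labels, k, extras
        res = twostep_cluster(
            Z, max_k=cfg.k_range[1],
            force_k=k_forced if k_forced is not None else cfg.fixed_k,
        )
        extras = (res.cluster_n, res.cluster_within_var, res.overall_var)
        return Z, res.centers, res.labels, res.k, extras

    interim: dict[str, tuple] = {}
    for i, sex in enumerate(SEXES):
        ids, X = strata_feats[sex]
        params = pooled_params if pooled_params is not None else zscore_fit(X)
        interim[sex] = (ids, X, params, _cluster(X, params, None, seed + 1000 * i))

    k_by_sex = {sex: interim[sex][3][3] for sex in SEXES}
    if len(set(k_by_sex.values())) > 1:
        larger = max(SEXES, key=lambda s: len(interim[s][0]))
        k_common = k_by_sex[larger]
        warnings.warn(
            f"sex strata selected different cluster counts {k_by_sex}; "
            f"imposing k={k_common} from the larger ({larger}) stratum",
            stacklevel=2,
        )
        for i, sex in enumerate(SEXES):
            if k_by_sex[sex] != k_common:
                ids, X, params, _ = interim[sex]
                interim[sex] = (ids, X, params, _cluster(X, params, k_common, seed + 1000 * i))

    strata_models: dict[str, StratumModel] = {}
    all_ids: list[str] = []
    all_labels: list[str] = []
    all_sex: list[str] = []
    sil: dict[str, float] = {}
    model_labels: tuple[str, ...] | None = None
    for sex in SEXES:
        ids, X, params, (Z, centers_z, lab, k, extras) = interim[sex]
        centers_raw = zscore_invert(params, centers_z)
        if k == 4:
            names = label_subtypes(centers_raw)
            order = [names.index(s) for s in SUBTYPE_ORDER]
            canonical = list(SUBTYPE_ORDER)
        else:
            order = list(np.lexsort((centers_raw[:, 1], centers_raw[:, 0])))
            canonical = [f"C{j + 1}" for j in range(k)]
        remap = {old: new for new, old in enumerate(order)}
        cluster_n, within, overall = extras
        strata_models[sex] = StratumModel(
            normalization=params,
            centers_raw=centers_raw[order],
            cluster_n=None if cluster_n is None else cluster_n[order],
            cluster_within_var=None if within is None else within[order],
            overall_var=overall,
        )
        if model_labels is None:
            model_labels = tuple(canonical)
        elif model_labels != tuple(canonical):
            raise LabelingError(
                f"inconsistent labels across strata: {model_labels} vs {tuple(canonical)}"
            )
        sil[sex] = mean_silhouette(Z, lab)
        all_ids.extend(ids)
        all_labels.extend(canonical[remap[c]] for c in lab)
        all_sex.extend([sex] * len(ids))

    n_total = len(all_ids)
    weighted_sil = sum(sil[s] * len(interim[s][0]) for s in SEXES) / n_total
    assert model_labels is not None
    model = ClusterModel(
        algorithm=algorithm,
        strata=strata_models,
        labels=model_labels,
        k=len(model_labels),
        mean_silhouette=float(weighted_sil),
    )
    partition = Partition(tuple(all_ids), tuple(all_labels), tuple(all_sex))
    return FitResult(
        model=model,
        partition=partition,
        stratum_silhouette=sil,
        stratum_k={s: interim[s][3][3] for s in SEXES},
    )
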