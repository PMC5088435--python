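"""Dynamic profiling: staged clustering of a TBI cohort into risk groups.

The cohort is re-partitioned into k clusters (default 3) at a sequence of
stages that mirrors information accrual during acute care:

* stage −1 — initial Glasgow Coma Scale score only;
* stage 0 — GCS plus clinical/demographic variables;
* stage i ≥ 1 — GCS, the retained clinical variables, orthogonal
  polynomial trends of each mediator over rounds 1..i−1, and the raw
  mediator readings of round i.

Trend degree is capped at d irrespective of the stage, so the feature
dimension stops growing once enough history exists — the clustering space
stays bounded no matter how long a patient is sampled.

Every cluster carries a "weight": the count of red flags (members with
GOS = 1, i.e. deaths), the mean GOS, and the GOS standard deviation.  The
red-flag fraction is the cluster's empirical probability of death; tracing
it along a patient's clusters across stages yields their risk curve.  A
Beta prior over the death probability turns each cluster estimate into a
conjugate posterior blending observed red flags with prior expertise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .cohort import CLINICAL_FLAGS, Cohort, Patient
from .trends import DEGREE_SUFFIX, extract_trends

DEFAULT_K = 3
DEFAULT_RESTARTS = 25

#: clinical/demographic columns used at stage 0 (GCS is always first).
DEFAULT_CLINICAL_VARS = ("age", "sex", *CLINICAL_FLAGS)


@dataclass
class ClusterWeight:
    """Outcome summary of one cluster.

    ``prob_death`` is red_flags / size — the fraction of members whose
    GOS is 1.
    """

    size: int
    red_flags: int
    gos_mean: float
    gos_sd: float
    prob_death: float


def cluster_weight(gos_values) -> ClusterWeight:
    """Weight triple + death probability from the members' GOS scores."""
    g = np.asarray(list(gos_values), dtype=float)
    if g.size == 0:
        raise ValueError("cluster must have at least one member")
    if np.any((g < 1) | (g > 5)):
        raise ValueError("GOS scores must lie in [1, 5]")
    red = int(np.sum(g == 1))
    sd = float(np.std(g, ddof=1)) if g.size > 1 else 0.0
    return ClusterWeight(
        size=int(g.size),
        red_flags=red,
        gos_mean=float(g.mean()),
        gos_sd=sd,
        prob_death=red / g.size,
    )


@dataclass
class BetaPrior:
    """Beta(alpha, beta) prior over a cluster's probability of death."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def bayes_update(prior: BetaPrior, weight: ClusterWeight) -> tuple[BetaPrior, float]:
    """Conjugate Beta-Binomial update by the cluster's red-flag count.

    Posterior = Beta(alpha + red_flags, beta + size − red_flags); its mean
    is a convex combination of the prior mean and the empirical death rate.
    """
    post = BetaPrior(prior.alpha + weight.red_flags,
                     prior.beta + weight.size - weight.red_flags)
    return post, post.mean


@dataclass
class StageFeatureTable:
    """Standardized stage features plus the moments needed to standardize
    a new patient's raw row the same way."""

    stage: int
    frame: pd.DataFrame  # standardized, one row per included patient
    means: pd.Series
    sds: pd.Series
    excluded: dict[str, str] = field(default_factory=dict)


@dataclass
class StagePartition:
    stage: int
    k: int
    assignment: dict[str, int]  # patient id -> canonical cluster label (0-based)
    weights: dict[int, ClusterWeight]
    features_used: list[str]
    centroids: np.ndarray  # (k, n_features), in standardized space
    seed: int
    method: str
    means: pd.Series
    sds: pd.Series
    inertia: float


@dataclass
class RiskCurve:
    """A patient's cluster death probability at each stage they appear in."""

    patient_id: str
    stages: list[int]
    probs: list[float]


# ---------------------------------------------------------------------------
# Stage features


def _clinical_value(p: Patient, var: str) -> float:
    if var == "age":
        return float(p.clinical.age)
    if var == "sex":
        return 1.0 if p.clinical.sex == "male" else 0.0
    if var in CLINICAL_FLAGS:
        return float(getattr(p.clinical, var))
    if var in p.clinical.extra_covariates:
        return float(p.clinical.extra_covariates[var])
    raise KeyError(f"unknown clinical variable {var!r}")


def _trend_block(p: Patient, panel, degree: int, up_to_round: int) -> dict[str, float]:
    """Trend coefficients from rounds 1..up_to_round, zero-padded.

    With fewer than j+1 available readings the degree-j coefficient is
    undefined; it is set to 0 (the value of a flat series) so the feature
    dimension is identical for every patient and stage.
    """
    out: dict[str, float] = {}
    for m in panel:
        values = p.series[m].values_up_to_round(up_to_round)
        eff = min(degree, max(values.size - 1, 0))
        coeffs = np.zeros(degree + 1)
        if values.size:
            tc = extract_trends(values, eff, mediator=m)
            coeffs[: eff + 1] = tc.coefficients
        for j in range(degree + 1):
            out[f"{m}.{DEGREE_SUFFIX[j]}"] = float(coeffs[j])
    return out


def patient_stage_row(
    p: Patient,
    stage: int,
    degree: int = 2,
    clinical_vars=DEFAULT_CLINICAL_VARS,
    trend_terms: list[str] | None = None,
    panel=None,
) -> pd.Series | None:
    """Raw (unstandardized) feature row for one patient at one stage.

    Returns ``None`` when the patient has no readings in round ``stage``
    (stages >= 1), i.e. the patient drops out of that stage's partition.
    """
    from .cohort import MEDIATOR_PANEL

    panel = panel or MEDIATOR_PANEL
    row: dict[str, float] = {"gcs": float(p.clinical.gcs)}
    if stage == -1:
        return pd.Series(row)
    for var in clinical_vars:
        row[var] = _clinical_value(p, var)
    if stage == 0:
        return pd.Series(row)
    if not p.has_round(stage):
        return None
    if stage >= 2:
        trends = _trend_block(p, panel, degree, up_to_round=stage - 1)
        if trend_terms is not None:
            trends = {k: v for k, v in trends.items() if k in trend_terms}
        row.update(trends)
    for m in panel:
        v = p.series[m].value_at_round(stage)
        row[f"{m}.r{stage}"] = np.nan if v is None else v
    return pd.Series(row)


def stage_features(
    cohort: Cohort,
    stage: int,
    degree: int = 2,
    clinical_vars=DEFAULT_CLINICAL_VARS,
    trend_terms: list[str] | None = None,
) -> StageFeatureTable:
    """Standardized clustering features for one stage.

    Patients lacking round ``stage`` are excluded and reported.  Missing
    individual readings within an included patient's round are imputed at
    the column median before standardization.  Zero-variance columns
    standardize to all-zeros rather than dividing by zero.
    """
    if stage < -1:
        raise ValueError("stage must be >= -1")
    if stage > cohort.max_round:
        raise ValueError(
            f"stage {stage} exceeds the maximum observed round {cohort.max_round}"
        )
    rows: dict[str, pd.Series] = {}
    excluded: dict[str, str] = {}
    for p in cohort:
        row = patient_stage_row(p, stage, degree, clinical_vars, trend_terms,
                                cohort.mediator_panel)
        if row is None:
            excluded[p.id] = f"no readings in round {stage}"
        else:
            rows[p.id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "patient_id"
    if len(frame):
        frame = frame.fillna(frame.median()).fillna(0.0)
    means = frame.mean()
    sds = frame.std(ddof=0).replace(0.0, 1.0)
    standardized = (frame - means) / sds
    return StageFeatureTable(stage, standardized, means, sds, excluded)


# ---------------------------------------------------------------------------
# Clustering


def _spectral_embedding(X: np.ndarray, k: int) -> np.ndarray:
    """k-dimensional spectral embedding from a Gaussian-affinity graph.

    Bandwidth = median pairwise distance; symmetric-normalized Laplacian;
    rows of the bottom-k eigenvector matrix are length-normalized.
    """
    dists = pdist(X)
    sigma = np.median(dists[dists > 0]) if np.any(dists > 0) else 1.0
    D2 = squareform(dists) ** 2
    A = np.exp(-D2 / (2.0 * sigma**2))
    np.fill_diagonal(A, 0.0)
    deg = A.sum(axis=1)
    deg[deg == 0] = 1.0
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(len(A)) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
    _, vecs = eigh(L, subset_by_index=[0, k - 1])
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vecs / norms


def cluster_stage(
    table: StageFeatureTable,
    k: int = DEFAULT_K,
    method: str = "kmeans",
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
) -> StagePartition:
    """Partition a stage's patients into k clusters (weights attached later).

    ``kmeans`` keeps the best of ``n_restarts`` k-means++ runs by
    within-cluster sum of squares; ``spectral`` first embeds via the
    normalized graph Laplacian and clusters the embedding.  Labels are
    canonicalized by ascending cluster mean GCS (the first feature) so
    cluster identity is reproducible.
    """
    if method not in ("kmeans", "spectral"):
        raise ValueError(f"unknown clustering method {method!r}")
    frame = table.frame
    if len(frame) < k:
        raise ValueError(f"cannot form {k} clusters from {len(frame)} patients")
    X = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in clustering features")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate stage: all patients have identical features")

    embed = _spectral_embedding(X, k) if method == "spectral" else X
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(embed)
    labels = km.labels_

    # WCSS of the partition in the original feature space.
    inertia = 0.0
    centroids = np.zeros((k, X.shape[1]))
    for c in range(k):
        members = X[labels == c]
        centroids[c] = members.mean(axis=0)
        inertia += float(np.sum((members - centroids[c]) ** 2))

    gcs_col = frame.columns.get_loc("gcs")
    order = np.argsort([centroids[c, gcs_col] for c in range(k)], kind="stable")
    relabel = {int(old): new for new, old in enumerate(order)}
    labels = np.array([relabel[int(c)] for c in labels])
    centroids = centroids[order]

    return StagePartition(
        stage=table.stage,
        k=k,
        assignment={pid: int(c) for pid, c in zip(frame.index, labels)},
        weights={},
        features_used=list(frame.columns),
        centroids=centroids,
        seed=seed,
        method=method,
        means=table.means,
        sds=table.sds,
        inertia=inertia,
    )


def attach_weights(partition: StagePartition, cohort: Cohort) -> StagePartition:
    """Compute each cluster's weight triple from its members' GOS scores."""
    by_cluster: dict[int, list[int]] = {c: [] for c in range(partition.k)}
    for pid, c in partition.assignment.items():
        gos = cohort.get(pid).gos
        if gos is not None:
            by_cluster[c].append(gos)
    partition.weights = {
        c: cluster_weight(g) for c, g in by_cluster.items() if g
    }
    return partition


def build_partitions(
    cohort: Cohort,
    degree: int = 2,
    k: int = DEFAULT_K,
    method: str = "kmeans",
    seed: int = 0,
    n_restarts: int = DEFAULT_RESTARTS,
    clinical_vars=DEFAULT_CLINICAL_VARS,
    trend_terms: list[str] | None = None,
    max_stage: int | None = None,
) -> tuple[list[StagePartition], dict[int, str]]:
    """Cluster every stage from −1 up to the last observed round.

    Stages where fewer than k patients remain (or features are degenerate)
    are skipped and reported in the second return value.
    """
    last = cohort.max_round if max_stage is None else min(max_stage, cohort.max_round)
    partitions: list[StagePartition] = []
    skipped: dict[int, str] = {}
    for stage in range(-1, last + 1):
        table = stage_features(cohort, stage, degree, clinical_vars, trend_terms)
        try:
            part = cluster_stage(table, k=k, method=method, seed=seed,
                                 n_restarts=n_restarts)
        except ValueError as exc:
            skipped[stage] = str(exc)
            continue
        partitions.append(attach_weights(part, cohort))
    return partitions, skipped


# ---------------------------------------------------------------------------
# Risk curves and new-patient assignment


def risk_curve(patient_id: str, partitions: list[StagePartition]) -> RiskCurve:
    """Trace a patient's cluster death probability across stages.

    Stages where the patient was excluded (no readings that round) are
    simply absent from the curve.
    """
    stages: list[int] = []
    probs: list[float] = []
    seen = False
    for part in sorted(partitions, key=lambda p: p.stage):
        if patient_id in part.assignment:
            seen = True
            c = part.assignment[patient_id]
            if c in part.weights:
                stages.append(part.stage)
                probs.append(part.weights[c].prob_death)
    if not seen:
        raise KeyError(f"patient {patient_id!r} appears in no partition")
    return RiskCurve(patient_id, stages, probs)


def assign_new_patient(
    partition: StagePartition, raw_row: pd.Series
) -> tuple[int, float]:
    """Place a new patient into the nearest cluster (Euclidean, tie to the
    lower canonical label) and return that cluster's death probability.

    The raw feature row is standardized with the partition's stored
    moments; values the partition never saw raise, missing (NaN) entries
    are imputed at the training mean.
    """
    missing = [c for c in partition.features_used if c not in raw_row.index]
    if missing:
        raise ValueError(f"new patient row lacks features: {missing}")
    row = raw_row[partition.features_used].astype(float)
    z = ((row - partition.means) / partition.sds).fillna(0.0).to_numpy()
    d2 = np.sum((partition.centroids - z) ** 2, axis=1)
    label = int(np.argmin(d2))  # argmin returns the lowest index on ties
    if label not in partition.weights:
        label = min(partition.weights)  # fall back to a weighted cluster
    return label, partition.weights[label].prob_death
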