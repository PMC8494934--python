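"""Temporally informed clustering of regulator and target profiles.

Regulators (TF protein abundance or phosphosite intensity) and targets
(transcript abundance) are clustered together on per-feature temporal
profiles so that network inference can later be restricted to within-cluster
regulator-target pairs.  For temporal designs the elastic dynamic-time-
warping (DTW) distance drives hierarchical agglomeration; for non-temporal
designs features are assigned to independent components (ICA) by maximal
absolute loading.

Profiles are log2(treated/mock) per timepoint, z-scored across timepoints,
so that profile *shape* rather than layer-specific amplitude determines
cluster membership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datamodel import OmicsMatrix, SampleInfo, ValidationError


@dataclass
class ClusterAssignment:
    """feature_id -> cluster id (contiguous 1..k), plus the method used."""

    assignment: pd.Series  # index: feature ids, values: int cluster ids
    k: int
    method: str

    def __post_init__(self) -> None:
        ids = set(self.assignment.unique())
        if ids and ids != set(range(1, self.k + 1)):
            raise ValidationError(
                f"cluster ids must be contiguous 1..{self.k}, got {sorted(ids)}"
            )

    def members(self, cluster_id: int) -> set:
        return set(self.assignment.index[self.assignment == cluster_id])

    def cluster_of(self, feature_id) -> int:
        return int(self.assignment.loc[feature_id])


def temporal_profiles(matrix, sample_info: SampleInfo) -> pd.DataFrame:
    """Per-feature log2(treated/mock) profile over timepoints, z-scored.

    ``matrix`` is an OmicsMatrix or a bare feature-by-sample DataFrame.
    Condition means are taken over replicates per timepoint; a constant
    profile z-scores to all zeros (guarded division).
    """
    values = matrix.values if isinstance(matrix, OmicsMatrix) else matrix
    tps = sample_info.timepoints
    prof = np.full((len(values), len(tps)), np.nan)
    for j, tp in enumerate(tps):
        t_cols = [c for c in sample_info.samples_for("treated", tp) if c in values.columns]
        m_cols = [c for c in sample_info.samples_for("mock", tp) if c in values.columns]
        if not t_cols or not m_cols:
            raise ValidationError(f"timepoint {tp}: missing a condition")
        t_mean = values[t_cols].mean(axis=1, skipna=True).to_numpy()
        m_mean = values[m_cols].mean(axis=1, skipna=True).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            prof[:, j] = np.log2(t_mean / m_mean)
    prof = np.where(np.isfinite(prof), prof, 0.0)
    mu = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (prof - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=values.index, columns=tps)


def build_clustering_matrix(
    regulator_profiles: pd.DataFrame, target_profiles: pd.DataFrame
) -> pd.DataFrame:
    """Stack regulator and target profiles into one clustering matrix.

    A feature appearing in both inputs (e.g. a TF quantified at both the
    protein and transcript level) keeps two rows, disambiguated with
    ``::reg`` / ``::tgt`` suffixes.
    """
    if list(regulator_profiles.columns) != list(target_profiles.columns):
        raise ValidationError(
            "regulator and target profiles must share the sample design "
            f"(timepoints {list(regulator_profiles.columns)} vs "
            f"{list(target_profiles.columns)})"
        )
    overlap = set(regulator_profiles.index) & set(target_profiles.index)
    reg = regulator_profiles.copy()
    tgt = target_profiles.copy()
    if overlap:
        reg.index = [f"{i}::reg" if i in overlap else i for i in reg.index]
        tgt.index = [f"{i}::tgt" if i in overlap else i for i in tgt.index]
    return pd.concat([reg, tgt], axis=0)


def dtw_distance(x, y) -> float:
    """Classic dynamic-time-warping distance.

    Absolute-difference local cost, unconstrained warping window,
    boundary-matched path.  Symmetric; zero for identical series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) == 0 or len(y) == 0:
        raise ValidationError("dtw_distance requires two non-empty 1-D series")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("dtw_distance does not accept missing values")
    n, m = len(x), len(y)
    cost = np.abs(x[:, None] - y[None, :])
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        row = acc[i]
        prev = acc[i - 1]
        ci = cost[i - 1]
        for j in range(1, m + 1):
            row[j] = ci[j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    return float(acc[n, m])


def dtw_distance_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """Symmetric pairwise DTW distance matrix over profile rows."""
    X = profiles.to_numpy(dtype=float)
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(X[i], X[j])
    return D


def dtw_cluster(profiles: pd.DataFrame, k: int | None = None) -> ClusterAssignment:
    """Cluster temporal profiles by DTW distance.

    Pairwise DTW distances feed average-linkage hierarchical agglomeration;
    the tree is cut into ``k`` clusters.  When ``k`` is None it is chosen to
    maximize the mean silhouette over k in [2, min(15, n-1)].
    """
    n = len(profiles)
    if n < 2:
        raise ValidationError("need at least 2 profiles to cluster")
    if k is not None and (k < 1 or k > n):
        raise ValidationError(f"k={k} out of range for {n} profiles")
    if k == 1:
        assignment = pd.Series(1, index=profiles.index)
        return ClusterAssignment(assignment, k=1, method="dtw")

    D = dtw_distance_matrix(profiles)
    Z = linkage(squareform(D, checks=False), method="average")
    if k is None:
        k = _silhouette_best_k(D, Z, k_max=min(15, n - 1))
    labels = fcluster(Z, t=k, criterion="maxclust")
    assignment = pd.Series(_relabel_contiguous(labels), index=profiles.index)
    return ClusterAssignment(assignment, k=int(assignment.max()), method="dtw")


def ica_cluster(matrix: pd.DataFrame, n_components: int, seed: int = 0) -> ClusterAssignment:
    """Assign features to independent components by maximal |loading|.

    ICA decomposes the feature-by-sample matrix; each feature goes to the
    component on which its loading has the largest absolute value (component
    signs are arbitrary, hence sign-agnostic).  Deterministic for a fixed
    seed.
    """
    from sklearn.decomposition import FastICA

    n_feat, n_samp = matrix.shape
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    if n_components > min(n_feat, n_samp):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_features, n_samples)="
            f"{min(n_feat, n_samp)}"
        )
    if n_components == 1:
        assignment = pd.Series(1, index=matrix.index)
        return ClusterAssignment(assignment, k=1, method="ica")

    X = matrix.to_numpy(dtype=float)
    X = np.where(np.isfinite(X), X, 0.0)
    # samples are observations of feature "channels"; the mixing matrix then
    # holds each feature's loading on every independent source signal
    ica = FastICA(n_components=n_components, random_state=seed, max_iter=1000, tol=1e-4)
    ica.fit(X.T)
    loadings = ica.mixing_  # features x components
    raw = np.abs(loadings).argmax(axis=1)
    assignment = pd.Series(_relabel_contiguous(raw + 1), index=matrix.index)
    return ClusterAssignment(assignment, k=int(assignment.max()), method="ica")


def _silhouette_best_k(D: np.ndarray, Z: np.ndarray, k_max: int) -> int:
    from sklearn.metrics import silhouette_score

    best_k, best_score = 2, -np.inf
    for k in range(2, k_max + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(D, labels, metric="precomputed")
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    return best_k


def _relabel_contiguous(labels) -> np.ndarray:
    """Map arbitrary labels to contiguous 1..k preserving first-seen order."""
    labels = np.asarray(labels)
    mapping: dict = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out
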