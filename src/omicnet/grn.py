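"""Cluster-restricted, timepoint-specific tree-ensemble GRN inference.

Regulators (TFs) and targets (transcripts) come from *separate* matrices so
that regulatory evidence can be protein abundance or phosphosite intensity
while targets stay at the transcript level.  For every target, a random
forest regresses the target's profile on candidate regulator profiles and
each regulator's total variance-reduction importance (normalized to sum to 1
per target) becomes the edge weight — higher weight, higher confidence.

Restrictions applied per timepoint-specific subnetwork:

* regulators limited to TFs differentially expressed at the timepoint;
* targets limited to transcripts differentially expressed at the timepoint;
* a TF may only be predicted to regulate transcripts in its own temporal
  cluster;
* self-regulation (source gene == target gene) is excluded.

The regression itself always uses the full time-course sample set (all
timepoints, conditions and replicates): the per-timepoint restriction
selects *which genes participate*, not which samples, since a handful of
samples per timepoint cannot support a tree ensemble.

The six per-timepoint subnetworks are combined as a union, each edge keeping
its timepoint label.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .datamodel import FeatureAnnotation, Network, OmicsMatrix, ValidationError

DEFAULT_N_TREES = 1000
DEFAULT_SEED = 42
DEFAULT_THRESHOLD_SD = 1.0


@dataclass
class RegulatorMatrix:
    """Regulator rows (values) plus per-row provenance (row_meta).

    row_meta columns: row_id, gene_id, source_layer, site_label.
    In abundance mode each TF contributes at most one row (protein if
    quantified, else transcript); in phosphosite mode a TF contributes one
    row per DE phosphosite, labeled ``GENE@S<pos>``.
    """

    values: pd.DataFrame
    row_meta: pd.DataFrame
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("abundance", "phosphosite"):
            raise ValidationError(f"unknown regulator mode {self.mode!r}")
        if list(self.values.index) != list(self.row_meta["row_id"]):
            raise ValidationError("regulator values and row_meta out of sync")
        if self.mode == "abundance":
            if self.row_meta["gene_id"].duplicated().any():
                raise ValidationError("abundance mode allows at most one row per TF")

    @property
    def row_ids(self) -> list:
        return list(self.values.index)

    def gene_of(self, row_id) -> str:
        return str(self.row_meta.set_index("row_id").loc[row_id, "gene_id"])


def build_regulator_matrix(
    tf_list: Sequence[str],
    protein_matrix: OmicsMatrix | None,
    transcript_matrix: OmicsMatrix | None,
    phospho_matrix: OmicsMatrix | None,
    annotations: FeatureAnnotation,
    mode: str,
    de_table: pd.DataFrame | None = None,
) -> RegulatorMatrix:
    """Assemble the regulator matrix for one inference mode.

    abundance mode: per TF, the protein row when quantified, else the
    transcript row, else the TF is excluded with a warning.  When several
    protein features map to one TF their mean profile is used.

    phosphosite mode: one row per DE phosphosite of each TF (``de_table``
    must be the phosphosite DE table); row ids are ``GENE@S<pos>``.
    """
    if not tf_list:
        raise ValidationError("tf_list is empty")
    ann = annotations.table
    rows, meta, excluded = [], [], []

    if mode == "abundance":
        for tf in tf_list:
            row = _gene_profile(tf, protein_matrix, ann, "protein")
            layer = "protein"
            if row is None:
                row = _gene_profile(tf, transcript_matrix, ann, "transcript")
                layer = "transcript"
            if row is None:
                excluded.append(tf)
                continue
            rows.append(row.rename(tf))
            meta.append((tf, tf, layer, ""))
    elif mode == "phosphosite":
        if phospho_matrix is None:
            raise ValidationError("phosphosite mode requires a phosphosite matrix")
        de_feats = set()
        if de_table is not None and len(de_table):
            de_feats = set(de_table.loc[de_table["is_de"], "feature_id"])
        phos_ann = ann.loc[ann["layer"] == "phosphosite"]
        for tf in tf_list:
            feats = phos_ann.loc[phos_ann["gene_id"] == tf]
            feats = feats.loc[feats["feature_id"].isin(de_feats)]
            feats = feats.loc[feats["feature_id"].isin(phospho_matrix.values.index)]
            if feats.empty:
                excluded.append(tf)
                continue
            for _, r in feats.sort_values("site_position").iterrows():
                site = f"S{int(r['site_position'])}"
                row_id = f"{tf}@{site}"
                rows.append(phospho_matrix.values.loc[r["feature_id"]].rename(row_id))
                meta.append((row_id, tf, "phosphosite", site))
    else:
        raise ValidationError(f"unknown regulator mode {mode!r}")

    if excluded:
        warnings.warn(f"TFs excluded from {mode} regulator matrix (no usable row): {sorted(excluded)}")
    if not rows:
        raise ValidationError(f"no usable regulator rows in {mode} mode")
    values = pd.DataFrame(rows)
    row_meta = pd.DataFrame(meta, columns=["row_id", "gene_id", "source_layer", "site_label"])
    return RegulatorMatrix(values=values, row_meta=row_meta, mode=mode)


def importance_scores(
    target_profile: pd.Series,
    regulator_matrix: RegulatorMatrix | pd.DataFrame,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = DEFAULT_SEED,
    exclude_gene: str | None = None,
) -> pd.Series:
    """Tree-ensemble importance of each regulator for one target.

    Random-forest regression of the target profile on regulator profiles;
    per-regulator weight is the total impurity (variance) reduction,
    normalized to sum to 1 across regulators.  Rows whose gene matches
    ``exclude_gene`` (the target's own gene) are removed first.  A constant
    target yields all-zero weights.
    """
    if isinstance(regulator_matrix, RegulatorMatrix):
        reg_values = regulator_matrix.values
        genes = dict(zip(regulator_matrix.row_meta["row_id"], regulator_matrix.row_meta["gene_id"]))
    else:
        reg_values = regulator_matrix
        genes = {rid: rid for rid in reg_values.index}
    if exclude_gene is not None:
        keep = [rid for rid in reg_values.index if genes.get(rid) != exclude_gene]
        reg_values = reg_values.loc[keep]
    if reg_values.empty:
        raise ValidationError("no candidate regulators after self-exclusion")
    # sorted internal ordering makes weights invariant to input row order
    reg_values = reg_values.sort_index(kind="mergesort")

    samples = [s for s in target_profile.index if s in reg_values.columns]
    if len(samples) < 8:
        raise ValidationError(f"need >=8 shared samples, got {len(samples)}")
    y = target_profile.loc[samples].to_numpy(dtype=float)
    X = reg_values[samples].to_numpy(dtype=float).T
    X = np.where(np.isfinite(X), X, 0.0)
    mask = np.isfinite(y)
    X, y = X[mask], y[mask]
    if len(y) < 8:
        raise ValidationError("need >=8 non-missing target observations")

    if np.ptp(y) == 0:
        return pd.Series(0.0, index=reg_values.index)

    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(X, y)
    imp = forest.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=reg_values.index)


def infer_subnetwork(
    regulator_matrix: RegulatorMatrix,
    target_matrix: OmicsMatrix,
    reg_clusters: Mapping,
    tgt_clusters: Mapping,
    de_regulator_rows: set,
    de_target_features: set,
    timepoint: int,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = DEFAULT_SEED,
    threshold_sd: float | None = DEFAULT_THRESHOLD_SD,
    top_n: int | None = None,
) -> Network:
    """Infer one timepoint-specific subnetwork.

    ``reg_clusters`` / ``tgt_clusters`` map regulator row ids and target
    feature ids to cluster ids; regulators and targets absent from the maps
    do not participate.  Retained edges have weight > mean + threshold_sd *
    sd of that target's candidate weights (``threshold_sd=None`` keeps the
    full ranking; ``top_n`` keeps the N best per target instead).
    """
    reg_rows = [r for r in regulator_matrix.row_ids if r in de_regulator_rows and r in reg_clusters]
    targets = [
        t
        for t in target_matrix.values.index
        if t in de_target_features and t in tgt_clusters
    ]
    if not reg_rows or not targets:
        warnings.warn(f"timepoint {timepoint}: no DE regulators or targets; empty subnetwork")
        return Network()

    gene_of = dict(zip(regulator_matrix.row_meta["row_id"], regulator_matrix.row_meta["gene_id"]))
    site_of = dict(zip(regulator_matrix.row_meta["row_id"], regulator_matrix.row_meta["site_label"]))
    edge_type = "abundance" if regulator_matrix.mode == "abundance" else "phosphosite"

    records = []
    for tgt in sorted(targets):
        tgt_cluster = tgt_clusters[tgt]
        cand = [
            r
            for r in reg_rows
            if reg_clusters[r] == tgt_cluster and gene_of[r] != tgt
        ]
        if not cand:
            continue
        tgt_seed = (int(seed) * 1000003 + zlib.crc32(str(tgt).encode())) % (2**31)
        weights = importance_scores(
            target_matrix.values.loc[tgt],
            RegulatorMatrix(
                values=regulator_matrix.values.loc[cand],
                row_meta=regulator_matrix.row_meta.set_index("row_id")
                .loc[cand]
                .reset_index(),
                mode=regulator_matrix.mode,
            ),
            n_trees=n_trees,
            seed=tgt_seed,
            exclude_gene=str(tgt),
        )
        kept = _retain(weights, threshold_sd, top_n)
        for rid, w in kept.items():
            records.append((gene_of[rid], tgt, float(w), edge_type, timepoint, site_of[rid]))

    if not records:
        return Network()
    return Network.from_records(records)


def merge_networks(networks: Iterable[Network]) -> Network:
    """Union of edge records across subnetworks.

    An edge present at several timepoints keeps one record per timepoint;
    exact-key duplicates collapse to a single record (idempotent,
    order-invariant).
    """
    frames = [n.edges for n in networks if len(n)]
    if not frames:
        return Network()
    merged = pd.concat(frames, ignore_index=True)
    merged = merged.sort_values(
        ["source", "target", "edge_type", "timepoint", "site_label", "weight"],
        kind="mergesort",
        ascending=[True, True, True, True, True, False],
    )
    merged = merged.drop_duplicates(
        subset=["source", "target", "edge_type", "timepoint", "site_label"], keep="first"
    ).reset_index(drop=True)
    return Network(merged)


def _retain(weights: pd.Series, threshold_sd: float | None, top_n: int | None) -> pd.Series:
    nonzero = weights[weights > 0]
    if top_n is not None:
        return nonzero.sort_values(ascending=False, kind="mergesort").head(top_n)
    if threshold_sd is None:
        return nonzero
    cut = weights.mean() + threshold_sd * weights.std(ddof=0)
    return nonzero[nonzero > cut]


def _gene_profile(gene: str, matrix: OmicsMatrix | None, ann: pd.DataFrame, layer: str):
    """Mean profile over a gene's quantified features in one layer, or None."""
    if matrix is None:
        return None
    feats = ann.loc[(ann["gene_id"] == gene) & (ann["layer"] == layer), "feature_id"]
    feats = [f for f in feats if f in matrix.values.index]
    if not feats:
        return None
    sub = matrix.values.loc[feats]
    if sub.isna().all(axis=None):
        return None
    return sub.mean(axis=0, skipna=True)
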