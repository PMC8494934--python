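"""Isobaric-label (TMT) reporter-intensity normalization.

Two-stage scheme for multi-run TMT experiments:

1. **Sample-loading normalization** (within run/batch): every channel in a
   batch is scaled so its column total equals the mean column total of that
   batch, correcting unequal peptide loading.
2. **Internal-reference scaling** (between runs): each batch carries pooled
   reference channels.  For every feature, its per-batch reference mean is
   driven to the geometric mean of those reference means across batches, so
   intensities become comparable across runs.  Features lacking reference
   quantification in any batch cannot be anchored and are dropped.

Missing values pass through untouched: scaling never imputes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import OmicsMatrix, SampleInfo, ValidationError


@dataclass
class NormalizationReport:
    """Bookkeeping from a normalization pass."""

    # sample-loading: per-sample column scaling factor
    column_factors: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    # internal-reference: per-feature, per-batch reference means (pre-scaling)
    reference_means: pd.DataFrame = field(default_factory=pd.DataFrame)
    dropped_features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.column_factors) and not (self.column_factors > 0).all():
            raise ValidationError("non-positive column scaling factor")


def sample_loading_normalize(
    matrix: OmicsMatrix, sample_info: SampleInfo
) -> tuple[OmicsMatrix, NormalizationReport]:
    """Equalize column totals within each batch.

    Each column is scaled by (mean column total of its batch) / (its total),
    leaving relative values within the column unchanged.
    """
    matrix.validate_against(sample_info)
    values = matrix.values.copy()
    meta = sample_info.table.set_index("sample_id")
    factors = {}
    for batch, cols in _batch_columns(values, meta).items():
        sums = values[cols].sum(axis=0, skipna=True)
        zero = sums.index[sums <= 0]
        if len(zero):
            raise ValidationError(f"zero column sum for sample(s) {list(zero)} in batch {batch!r}")
        target = sums.mean()
        f = target / sums
        values[cols] = values[cols].mul(f, axis=1)
        factors.update(f.to_dict())
    report = NormalizationReport(column_factors=pd.Series(factors).reindex(values.columns))
    return OmicsMatrix(matrix.layer, values), report


def internal_reference_normalize(
    matrix: OmicsMatrix, sample_info: SampleInfo
) -> tuple[OmicsMatrix, NormalizationReport]:
    """Anchor every feature to its cross-batch reference geometric mean.

    For feature *i* in batch *b* with reference-channel mean ``r[i, b]``, all
    of the feature's values in that batch are multiplied by
    ``gmean_b(r[i, :]) / r[i, b]``.  Afterwards the reference means agree
    across batches.  With several reference channels per batch their
    arithmetic mean per feature is the batch reference value.  Features with
    no reference quantification in some batch are dropped and reported.
    """
    matrix.validate_against(sample_info)
    values = matrix.values.copy()
    meta = sample_info.table.set_index("sample_id")
    batch_cols = _batch_columns(values, meta)
    batches = sorted(batch_cols)

    ref_means = {}
    for batch in batches:
        refs = [
            c
            for c in batch_cols[batch]
            if bool(meta.loc[c, "is_reference"])
        ]
        if not refs:
            raise ValidationError(f"batch {batch!r} has no reference channel")
        ref_means[batch] = values[refs].mean(axis=1, skipna=True)
    ref_df = pd.DataFrame(ref_means)  # features x batches

    quantified = ref_df.notna().all(axis=1) & (ref_df > 0).all(axis=1)
    dropped = sorted(ref_df.index[~quantified].tolist())
    kept = ref_df.index[quantified]
    values = values.loc[kept]
    ref_df = ref_df.loc[kept]

    gmeans = np.exp(np.log(ref_df).mean(axis=1))
    for batch in batches:
        factor = gmeans / ref_df[batch]
        values.loc[:, batch_cols[batch]] = values[batch_cols[batch]].mul(factor, axis=0)

    report = NormalizationReport(reference_means=ref_df, dropped_features=dropped)
    return OmicsMatrix(matrix.layer, values), report


def qc_summary(matrix: OmicsMatrix, sample_info: SampleInfo | None = None) -> dict:
    """Per-sample distribution summaries, sample correlations, 2-D projection.

    Returns quartiles per sample, the sample-sample Pearson correlation
    matrix, and 2-component PCA coordinates (zeros for a degenerate constant
    matrix).  Intended to feed boxplots / heatmaps / PCA plots.
    """
    values = matrix.values
    quartiles = values.quantile([0.25, 0.5, 0.75]).T
    quartiles.columns = ["q25", "median", "q75"]
    corr = values.corr(method="pearson")

    filled = values.to_numpy(dtype=float)
    col_means = np.nanmean(filled, axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    inds = np.where(np.isnan(filled))
    filled[inds] = np.take(col_means, inds[1])
    centered = filled - filled.mean(axis=1, keepdims=True)
    X = centered.T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        coords = np.zeros((X.shape[0], 2))
    else:
        from sklearn.decomposition import PCA

        ncomp = min(2, min(X.shape))
        pca = PCA(n_components=ncomp, random_state=0)
        coords = pca.fit_transform(X)
        if coords.shape[1] < 2:
            coords = np.hstack([coords, np.zeros((coords.shape[0], 1))])
    projection = pd.DataFrame(coords, index=values.columns, columns=["pc1", "pc2"])
    return {"quartiles": quartiles, "correlation": corr, "projection": projection}


def _batch_columns(values: pd.DataFrame, meta: pd.DataFrame) -> dict:
    missing = [c for c in values.columns if c not in meta.index]
    if missing:
        raise ValidationError(f"samples without batch assignment: {missing}")
    out: dict = {}
    for c in values.columns:
        out.setdefault(meta.loc[c, "batch"], []).append(c)
    return out
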