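"""Per-timepoint treated-vs-mock differential-expression calling.

Each omic layer carries its own thresholds, reflecting how count-based
transcriptomics and intensity-based (phospho)proteomics are conventionally
filtered in this kind of time course:

* transcripts:       q < 0.05 (Benjamini-Hochberg) and fold change > 1.25
* proteins:          p < 0.05 and fold change > 1.1
* phosphosites:      p < 0.05 and fold change > 1.1

Fold-change cutoffs are two-sided: a feature passes with FC > cutoff or
FC < 1/cutoff.  The two-sample test is pluggable; the default is the exact
rank-sum (Mann-Whitney) test.  Transcript counts are scaled to
counts-per-million before fold changes so library size does not masquerade
as regulation; reporter intensities are assumed already normalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import OmicsMatrix, SampleInfo, ValidationError

DE_COLUMNS = [
    "feature_id",
    "timepoint_min",
    "fold_change",
    "p",
    "q",
    "direction",
    "is_de",
]


@dataclass(frozen=True)
class Thresholds:
    fc_cutoff: float
    alpha: float
    use_q: bool


LAYER_THRESHOLDS: Mapping[str, Thresholds] = {
    "transcript": Thresholds(fc_cutoff=1.25, alpha=0.05, use_q=True),
    "protein": Thresholds(fc_cutoff=1.1, alpha=0.05, use_q=False),
    "phosphosite": Thresholds(fc_cutoff=1.1, alpha=0.05, use_q=False),
}

# skip a feature at a timepoint when more than this fraction of a condition's
# replicates is missing
MAX_MISSING_FRACTION = 0.5


def welch_t_test(treated: np.ndarray, mock: np.ndarray) -> float:
    """Welch's t on log2 intensities.

    At 3-4 replicates per condition an exact rank test cannot reach small
    p-values (its floor at n=4 is 2/70), which degenerates BH q-values; a
    parametric test on the log scale is the conventional choice for
    replicate-limited intensity data.
    """
    lt = np.log2(np.asarray(treated, dtype=float) + 1e-12)
    lm = np.log2(np.asarray(mock, dtype=float) + 1e-12)
    if np.ptp(lt) == 0 and np.ptp(lm) == 0:
        return 1.0
    res = stats.ttest_ind(lt, lm, equal_var=False)
    p = float(res.pvalue)
    return p if np.isfinite(p) else 1.0


def rank_sum_test(treated: np.ndarray, mock: np.ndarray) -> float:
    """Two-sided exact rank-sum p-value (asymptotic fallback under ties)."""
    try:
        res = stats.mannwhitneyu(treated, mock, alternative="two-sided", method="exact")
    except ValueError:
        res = stats.mannwhitneyu(treated, mock, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def call_de(
    matrix: OmicsMatrix,
    sample_info: SampleInfo,
    layer: str | None = None,
    test: Callable[[np.ndarray, np.ndarray], float] = rank_sum_test,
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Call differential expression per (feature, timepoint).

    Returns a DE table with one row per tested feature-timepoint pair:
    fold change (treated/mock on the analysis scale), p from ``test``,
    BH q within the timepoint, direction, and the layer-rule DE flag.
    Features with non-finite fold change (zero mock mean) or excessive
    missingness in a condition are skipped at that timepoint with a warning.
    """
    layer = layer or matrix.layer
    if thresholds is None:
        thresholds = LAYER_THRESHOLDS[layer]
    matrix.validate_against(sample_info)

    values = matrix.values
    if layer == "transcript":
        libsize = values.sum(axis=0, skipna=True)
        if (libsize <= 0).any():
            raise ValidationError("transcript sample with zero library size")
        values = values.div(libsize, axis=1) * 1e6  # counts per million

    rows = []
    for tp in sample_info.timepoints:
        treated_cols = [c for c in sample_info.samples_for("treated", tp) if c in values.columns]
        mock_cols = [c for c in sample_info.samples_for("mock", tp) if c in values.columns]
        if len(treated_cols) < 2 or len(mock_cols) < 2:
            raise ValidationError(
                f"timepoint {tp}: need >=2 replicates per condition "
                f"(treated={len(treated_cols)}, mock={len(mock_cols)})"
            )
        T = values[treated_cols].to_numpy(dtype=float)
        M = values[mock_cols].to_numpy(dtype=float)

        skipped_missing = 0
        skipped_fc = 0
        for i, fid in enumerate(values.index):
            t_obs = T[i][~np.isnan(T[i])]
            m_obs = M[i][~np.isnan(M[i])]
            if (
                len(t_obs) < len(treated_cols) * (1 - MAX_MISSING_FRACTION)
                or len(m_obs) < len(mock_cols) * (1 - MAX_MISSING_FRACTION)
                or len(t_obs) < 2
                or len(m_obs) < 2
            ):
                skipped_missing += 1
                continue
            mock_mean = m_obs.mean()
            if mock_mean <= 0:
                skipped_fc += 1
                continue
            fc = t_obs.mean() / mock_mean
            if not np.isfinite(fc):
                skipped_fc += 1
                continue
            p = test(t_obs, m_obs)
            rows.append((fid, tp, fc, p))
        if skipped_missing:
            warnings.warn(
                f"timepoint {tp}: skipped {skipped_missing} features with "
                f">{MAX_MISSING_FRACTION:.0%} missing replicates in a condition"
            )
        if skipped_fc:
            warnings.warn(
                f"timepoint {tp}: excluded {skipped_fc} features with "
                "zero mock mean (infinite fold change)"
            )

    table = pd.DataFrame(rows, columns=["feature_id", "timepoint_min", "fold_change", "p"])
    if table.empty:
        return pd.DataFrame(columns=DE_COLUMNS)

    # BH within timepoint, mirroring per-timepoint contrasts
    table["q"] = np.nan
    for tp, idx in table.groupby("timepoint_min").groups.items():
        table.loc[idx, "q"] = multipletests(table.loc[idx, "p"], method="fdr_bh")[1]

    table["direction"] = np.where(table["fold_change"] > 1, "up", "down")
    sig = table["q"] < thresholds.alpha if thresholds.use_q else table["p"] < thresholds.alpha
    cut = thresholds.fc_cutoff
    fc_pass = (table["fold_change"] > cut) | (table["fold_change"] < 1 / cut)
    table["is_de"] = sig & fc_pass
    return table[DE_COLUMNS].reset_index(drop=True)


def de_sets_by_timepoint(de_table: pd.DataFrame) -> dict[int, dict[str, set]]:
    """Partition DE features per timepoint into up and down sets."""
    out: dict[int, dict[str, set]] = {}
    if de_table.empty:
        return out
    de = de_table.loc[de_table["is_de"]]
    for tp, grp in de.groupby("timepoint_min"):
        out[int(tp)] = {
            "up": set(grp.loc[grp["direction"] == "up", "feature_id"]),
            "down": set(grp.loc[grp["direction"] == "down", "feature_id"]),
        }
    return out


def de_features(de_table: pd.DataFrame, timepoint: int | None = None) -> set:
    """All features DE at a given timepoint (or at any timepoint)."""
    if de_table.empty:
        return set()
    de = de_table.loc[de_table["is_de"]]
    if timepoint is not None:
        de = de.loc[de["timepoint_min"] == timepoint]
    return set(de["feature_id"])
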