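"""Correlation-based kinase-signaling network.

Phosphorylation of a kinase's activation loop (p-loop) reflects its
activity, so DE phosphosites falling inside a kinase's p-loop interval act
as the network's potential regulators; all DE phosphosites are potential
targets.  For every regulator-target pair, Pearson and Spearman
correlations are computed over the paired non-missing sample values and an
edge is kept when Pearson >= 0.5 or Spearman >= 0.6 (one-sided, positive
correlation, exactly as conventionally thresholded for this network type).
The edge weight is max(Pearson, Spearman).

Self-pairs and pairs of two sites on the same protein are excluded: a
kinase "regulating" its own phosphosites is not a signaling prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    FeatureAnnotation,
    Network,
    OmicsMatrix,
    PloopTable,
    SampleInfo,
    ValidationError,
)

DEFAULT_PEARSON_MIN = 0.5
DEFAULT_SPEARMAN_MIN = 0.6


@dataclass
class KinaseRegulator:
    """One activation-loop phosphosite acting as a kinase-activity proxy."""

    gene_id: str
    feature_id: str
    site_label: str
    profile: pd.Series  # intensity over the sample design


def select_ploop_regulators(
    de_table: pd.DataFrame,
    phospho_matrix: OmicsMatrix,
    annotations: FeatureAnnotation,
    ploop_table: PloopTable,
) -> list[KinaseRegulator]:
    """DE phosphosites inside their kinase's activation-loop interval.

    One regulator per qualifying site: the protein must be flagged a kinase,
    present in the p-loop table, the site position must fall inside
    [ploop_start, ploop_end] (1-based inclusive), and the site must be DE at
    >=1 timepoint.  Kinases absent from the p-loop table are skipped with a
    warning.
    """
    de_feats = set()
    if de_table is not None and len(de_table):
        de_feats = set(de_table.loc[de_table["is_de"], "feature_id"])
    ann = annotations.table
    phos = ann.loc[(ann["layer"] == "phosphosite") & ann["is_kinase"].astype(bool)]

    regulators: list[KinaseRegulator] = []
    missing_coords = set()
    for _, row in phos.sort_values(["gene_id", "site_position"]).iterrows():
        fid = row["feature_id"]
        if fid not in de_feats or fid not in phospho_matrix.values.index:
            continue
        interval = ploop_table.interval(row["gene_id"])
        if interval is None:
            missing_coords.add(row["gene_id"])
            continue
        lo, hi = interval
        pos = int(row["site_position"])
        if lo <= pos <= hi:
            regulators.append(
                KinaseRegulator(
                    gene_id=str(row["gene_id"]),
                    feature_id=str(fid),
                    site_label=f"S{pos}",
                    profile=phospho_matrix.values.loc[fid],
                )
            )
    if missing_coords:
        warnings.warn(
            f"kinases without p-loop coordinates excluded: {sorted(missing_coords)}"
        )
    return regulators


def correlation_edges(
    regulators: list[KinaseRegulator],
    target_profiles: pd.DataFrame,
    target_genes: dict | None = None,
    pearson_min: float = DEFAULT_PEARSON_MIN,
    spearman_min: float = DEFAULT_SPEARMAN_MIN,
    absolute: bool = False,
) -> Network:
    """Threshold regulator-target correlations into a kinase network.

    ``target_profiles`` holds one row per target phosphosite;
    ``target_genes`` maps target feature id -> gene (same-protein pairs are
    excluded; identity map when omitted).  Edges satisfy Pearson >=
    pearson_min OR Spearman >= spearman_min (on |r| with ``absolute=True``);
    weight = max of the two coefficients.  Pairs with <3 paired observations
    or a constant profile are skipped with a note.
    """
    if target_genes is None:
        target_genes = {t: t for t in target_profiles.index}

    records = []
    skipped_constant = 0
    for reg in regulators:
        r_vals = reg.profile
        for tgt in target_profiles.index:
            if tgt == reg.feature_id:
                continue
            if target_genes.get(tgt, tgt) == reg.gene_id:
                continue  # two sites on the same protein
            t_vals = target_profiles.loc[tgt]
            shared = r_vals.index.intersection(t_vals.index)
            x = r_vals.loc[shared].to_numpy(dtype=float)
            y = t_vals.loc[shared].to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            if mask.sum() < 3:
                continue
            x, y = x[mask], y[mask]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                skipped_constant += 1
                continue
            pear = float(stats.pearsonr(x, y).statistic)
            spear = float(stats.spearmanr(x, y).statistic)
            if absolute:
                pear_eff, spear_eff = abs(pear), abs(spear)
            else:
                pear_eff, spear_eff = pear, spear
            if pear_eff >= pearson_min or spear_eff >= spearman_min:
                tgt_gene = target_genes.get(tgt, tgt)
                records.append(
                    (
                        reg.gene_id,
                        str(tgt_gene),
                        max(pear_eff, spear_eff),
                        "kinase",
                        "all",
                        reg.site_label,
                    )
                )
    if skipped_constant:
        warnings.warn(
            f"{skipped_constant} pairs skipped: constant profile, correlation undefined"
        )
    if not records:
        return Network()
    df = pd.DataFrame(
        records, columns=["source", "target", "weight", "edge_type", "timepoint", "site_label"]
    )
    # several target sites on one gene can pass for the same regulator site;
    # collapse to the strongest record per (source, target, site_label)
    df = df.sort_values(
        ["source", "target", "site_label", "weight"],
        ascending=[True, True, True, False],
        kind="mergesort",
    ).drop_duplicates(subset=["source", "target", "edge_type", "timepoint", "site_label"])
    df = df.loc[df["source"] != df["target"]]
    return Network(df.reset_index(drop=True))


def activation_state_report(
    kinase_abundance: OmicsMatrix,
    phospho_matrix: OmicsMatrix,
    regulators: list[KinaseRegulator],
    annotations: FeatureAnnotation,
    sample_info: SampleInfo,
) -> pd.DataFrame:
    """Per-kinase, per-timepoint correlation of abundance vs p-loop intensity.

    Diagnostic for how well kinase protein abundance tracks activation state
    across replicates; entries with <3 paired replicates or a kinase missing
    from the abundance layer are flagged not-computable (NaN correlation).
    """
    ann = annotations.table
    prot = ann.loc[ann["layer"] == "protein"]
    rows = []
    for reg in regulators:
        prot_feats = prot.loc[prot["gene_id"] == reg.gene_id, "feature_id"]
        prot_feats = [f for f in prot_feats if f in kinase_abundance.values.index]
        for tp in sample_info.timepoints:
            cols = [
                c
                for c in sample_info.samples_for(timepoint_min=tp)
                if c in reg.profile.index
            ]
            if not prot_feats:
                rows.append((reg.gene_id, reg.site_label, tp, np.nan, "kinase not in abundance layer"))
                continue
            ab = kinase_abundance.values.loc[prot_feats, cols].mean(axis=0, skipna=True)
            site = reg.profile.loc[cols]
            mask = ab.notna() & site.notna()
            if mask.sum() < 3:
                rows.append((reg.gene_id, reg.site_label, tp, np.nan, "<3 paired replicates"))
                continue
            x = ab[mask].to_numpy(dtype=float)
            y = site[mask].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((reg.gene_id, reg.site_label, tp, np.nan, "constant profile"))
                continue
            r = float(stats.pearsonr(x, y).statistic)
            rows.append((reg.gene_id, reg.site_label, tp, r, ""))
    return pd.DataFrame(
        rows, columns=["gene_id", "site_label", "timepoint_min", "correlation", "note"]
    )
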