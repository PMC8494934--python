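"""Core data containers for the multi-omic network toolkit.

The toolkit moves three expression layers (transcript counts, protein-group
reporter intensities, phosphosite reporter intensities) through
normalization, differential-expression filtering, clustering and network
inference.  Everything is carried in pandas objects with thin validating
wrappers so that invariants are checked once, at construction, rather than
re-checked in every operation.

Coordinate convention: phosphosite positions and activation-loop (p-loop)
ranges are 1-based inclusive amino-acid coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

LAYERS = ("transcript", "protein", "phosphosite")
EDGE_TYPES = ("abundance", "phosphosite", "kinase")

SAMPLE_INFO_COLUMNS = [
    "sample_id",
    "treatment",
    "timepoint_min",
    "replicate",
    "batch",
    "channel",
    "is_reference",
]

EDGE_COLUMNS = ["source", "target", "weight", "edge_type", "timepoint", "site_label"]


class ValidationError(ValueError):
    """Raised when an input table violates the data model."""


@dataclass
class OmicsMatrix:
    """One layer's feature-by-sample matrix.

    values: DataFrame, rows = features, columns = samples; NaN marks a
    feature that was not quantified in a sample (never coerced to 0).
    """

    layer: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        self.values.index.name = "feature_id"
        idx = self.values.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate feature ids: {dups}")
        cols = self.values.columns
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy(dtype=float)
        neg = np.argwhere(arr < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative value at feature {idx[i]!r}, sample {cols[j]!r}: {arr[i, j]}"
            )

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.layer, self.values.loc[:, list(sample_ids)])

    def validate_against(self, sample_info: "SampleInfo") -> None:
        """Every column must resolve to a known sample."""
        known = set(sample_info.table["sample_id"])
        missing = [s for s in self.sample_ids if s not in known]
        if missing:
            raise ValidationError(
                f"samples absent from sample metadata: {missing}"
            )


@dataclass
class SampleInfo:
    """Per-sample design metadata.

    Non-reference samples are keyed by (treatment, timepoint_min, replicate);
    reference samples are the pooled internal-reference channels used for
    between-batch normalization.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_INFO_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample metadata missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dups = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"].tolist())
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        bad = set(t.loc[~t["is_reference"], "treatment"]) - {"mock", "treated"}
        if bad:
            raise ValidationError(f"unknown treatment labels: {sorted(bad)}")
        nonref = t.loc[~t["is_reference"]]
        key = nonref[["treatment", "timepoint_min", "replicate"]]
        if key.duplicated().any():
            raise ValidationError(
                "duplicate (treatment, timepoint, replicate) among non-reference samples"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    @property
    def timepoints(self) -> list[int]:
        tps = self.table.loc[~self.table["is_reference"], "timepoint_min"]
        return sorted(int(t) for t in tps.unique())

    def reference_samples(self, batch=None) -> list:
        t = self.table
        mask = t["is_reference"]
        if batch is not None:
            mask = mask & (t["batch"] == batch)
        return list(t.loc[mask, "sample_id"])

    def batches(self) -> list:
        return sorted(self.table["batch"].unique().tolist())

    def samples_for(self, treatment=None, timepoint_min=None, include_reference=False) -> list:
        t = self.table
        mask = pd.Series(True, index=t.index)
        if not include_reference:
            mask &= ~t["is_reference"]
        if treatment is not None:
            mask &= t["treatment"] == treatment
        if timepoint_min is not None:
            mask &= t["timepoint_min"] == timepoint_min
        return list(t.loc[mask, "sample_id"])


@dataclass
class FeatureAnnotation:
    """feature_id -> gene mapping plus TF/kinase flags and phosphosite position."""

    table: pd.DataFrame

    REQUIRED = ["feature_id", "gene_id", "layer", "site_position", "is_tf", "is_kinase"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"feature annotation missing columns: {missing}")
        t = self.table
        if t["feature_id"].duplicated().any():
            dups = sorted(t.loc[t["feature_id"].duplicated(), "feature_id"].tolist())
            raise ValidationError(f"duplicate feature ids in annotation: {dups}")
        if (t["gene_id"].astype(str).str.len() == 0).any():
            raise ValidationError("empty gene_id in annotation")
        is_phos = t["layer"] == "phosphosite"
        has_pos = t["site_position"].notna()
        if (is_phos & ~has_pos).any():
            bad = t.loc[is_phos & ~has_pos, "feature_id"].tolist()
            raise ValidationError(f"phosphosite features lacking site_position: {bad}")
        if (~is_phos & has_pos).any():
            bad = t.loc[~is_phos & has_pos, "feature_id"].tolist()
            raise ValidationError(f"non-phosphosite features carrying site_position: {bad}")

    def gene_of(self, feature_id) -> str:
        row = self.table.loc[self.table["feature_id"] == feature_id]
        if row.empty:
            raise KeyError(feature_id)
        return str(row["gene_id"].iloc[0])

    def tf_genes(self) -> set:
        t = self.table
        return set(t.loc[t["is_tf"].astype(bool), "gene_id"])

    def kinase_genes(self) -> set:
        t = self.table
        return set(t.loc[t["is_kinase"].astype(bool), "gene_id"])


@dataclass
class PloopTable:
    """Activation-loop (p-loop) coordinates per kinase, 1-based inclusive."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("protein_id", "ploop_start", "ploop_end"):
            if c not in self.table.columns:
                raise ValidationError(f"p-loop table missing column {c!r}")
        t = self.table
        if t["protein_id"].duplicated().any():
            dups = sorted(t.loc[t["protein_id"].duplicated(), "protein_id"].tolist())
            raise ValidationError(f"duplicate protein ids in p-loop table: {dups}")
        if (t["ploop_start"] > t["ploop_end"]).any():
            bad = t.loc[t["ploop_start"] > t["ploop_end"], "protein_id"].tolist()
            raise ValidationError(f"ploop_start > ploop_end for: {bad}")

    def interval(self, protein_id) -> Optional[tuple[int, int]]:
        row = self.table.loc[self.table["protein_id"] == protein_id]
        if row.empty:
            return None
        return int(row["ploop_start"].iloc[0]), int(row["ploop_end"].iloc[0])


@dataclass
class Network:
    """Directed weighted edge records.

    One record per (source, target, edge_type, timepoint); an edge predicted
    at several timepoints keeps one record per timepoint.  site_label records
    the phosphosite used to predict a regulation (e.g. ``GENE@S179``), empty
    otherwise.  No self-edges at gene level.
    """

    edges: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EDGE_COLUMNS))

    def __post_init__(self) -> None:
        if list(self.edges.columns) != EDGE_COLUMNS:
            missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
            if missing:
                raise ValidationError(f"edge table missing columns: {missing}")
            self.edges = self.edges[EDGE_COLUMNS]
        e = self.edges
        if len(e):
            if (e["source"] == e["target"]).any():
                bad = e.loc[e["source"] == e["target"], "source"].tolist()
                raise ValidationError(f"self-edges not allowed: {sorted(set(bad))}")
            bad_type = set(e["edge_type"]) - set(EDGE_TYPES)
            if bad_type:
                raise ValidationError(f"unknown edge types: {sorted(bad_type)}")
            w = e["weight"].to_numpy(dtype=float)
            if not np.isfinite(w).all():
                raise ValidationError("non-finite edge weight")
            # site_label is part of the record key: distinct phosphosites of
            # one TF predict distinct regulations of the same target
            key = e[["source", "target", "edge_type", "timepoint", "site_label"]]
            if key.duplicated().any():
                raise ValidationError(
                    "duplicate (source, target, edge_type, timepoint, site_label) records"
                )
        self.edges = self.edges.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.edges)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "Network":
        df = pd.DataFrame(list(records), columns=EDGE_COLUMNS)
        return cls(df)

    def sorted(self) -> "Network":
        e = self.edges.sort_values(
            ["source", "target", "timepoint", "edge_type"], kind="mergesort"
        ).reset_index(drop=True)
        return Network(e)

    def record_keys(self) -> set:
        return set(
            zip(
                self.edges["source"],
                self.edges["target"],
                self.edges["edge_type"],
                self.edges["timepoint"],
            )
        )
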