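"""Readers and writers for the delimited-text tables the toolkit consumes.

All inputs are TSV or CSV (delimiter auto-detected between tab and comma);
all outputs are TSV.  The edge-table writer produces the column layout that
Cytoscape's "import network from file" dialog expects.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    EDGE_COLUMNS,
    SAMPLE_INFO_COLUMNS,
    FeatureAnnotation,
    Network,
    OmicsMatrix,
    PloopTable,
    SampleInfo,
    ValidationError,
)


def _sniff_delimiter(path) -> str:
    with open(path, "r", newline="") as fh:
        head = fh.readline()
    if "\t" in head:
        return "\t"
    if "," in head:
        return ","
    return "\t"


def read_expression(path, layer: str) -> OmicsMatrix:
    """Read a feature-by-sample expression table.

    First column is the feature id, remaining columns are samples, header row
    required.  Empty cells become NaN (missing), never 0.
    """
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    values = df.apply(pd.to_numeric, errors="raise")
    return OmicsMatrix(layer=layer, values=values.astype(float))


def write_expression(matrix: OmicsMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id", na_rep="")


def read_sample_info(path) -> SampleInfo:
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    if "is_reference" in df.columns:
        df["is_reference"] = (
            df["is_reference"].astype(str).str.strip().str.lower().isin(["true", "1", "yes"])
        )
    for c in ("timepoint_min", "replicate"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c]).astype(int)
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleInfo(df[SAMPLE_INFO_COLUMNS])


def write_sample_info(info: SampleInfo, path) -> None:
    info.table.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> FeatureAnnotation:
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    for c in ("is_tf", "is_kinase"):
        df[c] = df[c].astype(str).str.strip().str.lower().isin(["true", "1", "yes"])
    df["site_position"] = pd.to_numeric(df.get("site_position"), errors="coerce")
    for c in ("feature_id", "gene_id", "layer"):
        df[c] = df[c].astype(str)
    return FeatureAnnotation(df[FeatureAnnotation.REQUIRED])


def write_annotations(ann: FeatureAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False, na_rep="")


def read_ploop_table(path) -> PloopTable:
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    df["protein_id"] = df["protein_id"].astype(str)
    df["ploop_start"] = pd.to_numeric(df["ploop_start"]).astype(int)
    df["ploop_end"] = pd.to_numeric(df["ploop_end"]).astype(int)
    return PloopTable(df[["protein_id", "ploop_start", "ploop_end"]])


def write_ploop_table(table: PloopTable, path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


def write_edge_table(network: Network, path) -> None:
    """Write a Cytoscape-compatible TSV edge table.

    Deterministic row order: sorted by source, target, timepoint.
    """
    e = network.edges.copy()
    e = e.sort_values(["source", "target", "timepoint", "edge_type"], kind="mergesort")
    e["site_label"] = e["site_label"].fillna("")
    e.to_csv(path, sep="\t", index=False, columns=EDGE_COLUMNS)


def read_edge_table(path) -> Network:
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={"source": str, "target": str, "site_label": str})
    if df.empty and list(df.columns) == EDGE_COLUMNS:
        return Network()
    df["weight"] = pd.to_numeric(df["weight"])
    # integer timepoints round-trip as ints; merged-set labels stay strings
    df["timepoint"] = [
        int(v) if str(v).lstrip("-").isdigit() else str(v) for v in df["timepoint"]
    ]
    df["site_label"] = df["site_label"].fillna("")
    return Network(df[EDGE_COLUMNS])


def validate_joint(matrices, sample_info: SampleInfo) -> None:
    """Check that every matrix's samples resolve in the metadata."""
    for m in matrices:
        m.validate_against(sample_info)
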