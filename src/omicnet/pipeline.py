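"""End-to-end orchestration: normalize -> DE -> cluster -> infer -> merge.

``run_all`` executes the full workflow on either user-supplied tables or a
freshly simulated dataset, writing every artifact as TSV plus a JSON
manifest recording versions, seeds and parameters.  All randomness fans out
deterministically from the single top-level seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import Network, OmicsMatrix, ValidationError
from . import io as onio
from .cluster import build_clustering_matrix, dtw_cluster, ica_cluster, temporal_profiles
from .diffexp import LAYER_THRESHOLDS, Thresholds, call_de, de_features, rank_sum_test, welch_t_test
from .grn import build_regulator_matrix, infer_subnetwork, merge_networks
from .kinase import correlation_edges, select_ploop_regulators
from .motifs import count_motifs, nms_rank
from .normalize import internal_reference_normalize, sample_loading_normalize
from .simulate import SimConfig, simulate_multiomics

log = logging.getLogger("omicnet")


@dataclass
class PipelineConfig:
    """Everything run_all needs; loadable from a YAML file."""

    # input paths; all None -> simulate a synthetic dataset instead
    transcript_path: str | None = None
    protein_path: str | None = None
    phospho_path: str | None = None
    sample_info_path: str | None = None
    annotations_path: str | None = None
    ploop_path: str | None = None
    # stage parameters
    cluster_method: str = "dtw"
    cluster_k: int | None = None
    n_trees: int = 1000
    threshold_sd: float | None = 1.0
    pearson_min: float = 0.5
    spearman_min: float = 0.6
    transcript_fc: float = 1.25
    proteomic_fc: float = 1.1
    alpha: float = 0.05
    de_test: str = "welch"  # "welch" (t on log2) or "ranksum" (exact)
    seed: int = 0
    sim: dict = field(default_factory=dict)
    out_dir: str = "omicnet_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def load_inputs(config: PipelineConfig):
    """Read user tables, or simulate when no paths are given."""
    paths = [
        config.transcript_path,
        config.protein_path,
        config.phospho_path,
        config.sample_info_path,
        config.annotations_path,
        config.ploop_path,
    ]
    if all(p is None for p in paths):
        sim_cfg = SimConfig(**{**config.sim, "seed": config.sim.get("seed", config.seed)})
        log.info("no input paths: simulating synthetic dataset (seed=%d)", sim_cfg.seed)
        t, p, ph, si, ann, ploop, truth = simulate_multiomics(sim_cfg)
        return t, p, ph, si, ann, ploop, truth
    required = {
        "transcript_path": config.transcript_path,
        "protein_path": config.protein_path,
        "phospho_path": config.phospho_path,
        "sample_info_path": config.sample_info_path,
        "annotations_path": config.annotations_path,
        "ploop_path": config.ploop_path,
    }
    missing = [k for k, v in required.items() if v is None or not Path(v).exists()]
    if missing:
        raise ValidationError(f"missing or nonexistent inputs: {missing}")
    t = onio.read_expression(config.transcript_path, "transcript")
    p = onio.read_expression(config.protein_path, "protein")
    ph = onio.read_expression(config.phospho_path, "phosphosite")
    si = onio.read_sample_info(config.sample_info_path)
    ann = onio.read_annotations(config.annotations_path)
    ploop = onio.read_ploop_table(config.ploop_path)
    onio.validate_joint([t, p, ph], si)
    return t, p, ph, si, ann, ploop, None


def normalize_layer(matrix: OmicsMatrix, sample_info):
    """Sample-loading then internal-reference normalization for one layer."""
    sl, sl_report = sample_loading_normalize(matrix, sample_info)
    ir, ir_report = internal_reference_normalize(sl, sample_info)
    return ir, {"column_factors": sl_report.column_factors, "dropped": ir_report.dropped_features}


def _de_row_lookup(annotations, de_tables):
    """(gene, layer, timepoint) DE evidence for regulator rows."""
    ann = annotations.table
    feat_gene = dict(zip(ann["feature_id"], ann["gene_id"]))
    feat_layer = dict(zip(ann["feature_id"], ann["layer"]))
    de_at: dict[tuple, set] = {}
    for layer, table in de_tables.items():
        if table is None or table.empty:
            continue
        de = table.loc[table["is_de"]]
        for fid, tp in zip(de["feature_id"], de["timepoint_min"]):
            g = feat_gene.get(fid, fid)
            de_at.setdefault((g, feat_layer.get(fid, layer), int(tp)), set()).add(fid)
    return de_at


def infer_tf_network(
    mode: str,
    regulator_matrix,
    target_matrix: OmicsMatrix,
    sample_info,
    de_tables: dict,
    annotations,
    config: PipelineConfig,
):
    """Cluster + per-timepoint inference + union merge for one mode.

    Returns (merged network, per-timepoint networks, cluster assignment).
    """
    reg_profiles = temporal_profiles(regulator_matrix.values, sample_info)
    # only transcripts that can enter the network (DE somewhere) are clustered
    de_any = de_features(de_tables.get("transcript"))
    tgt_feats = [t for t in target_matrix.values.index if t in de_any]
    tgt_profiles = temporal_profiles(target_matrix.values.loc[tgt_feats], sample_info)
    clust_matrix = build_clustering_matrix(reg_profiles, tgt_profiles)
    if config.cluster_method == "dtw":
        clusters = dtw_cluster(clust_matrix, k=config.cluster_k)
    elif config.cluster_method == "ica":
        k = config.cluster_k or min(6, min(clust_matrix.shape) - 1)
        clusters = ica_cluster(clust_matrix, n_components=k, seed=config.seed)
    else:
        raise ValidationError(f"unknown cluster method {config.cluster_method!r}")

    def cluster_of(rid, suffix):
        for key in (rid, f"{rid}{suffix}"):
            if key in clusters.assignment.index:
                return int(clusters.assignment.loc[key])
        return None

    reg_clusters = {
        r: c for r in regulator_matrix.row_ids if (c := cluster_of(r, "::reg")) is not None
    }
    tgt_clusters = {
        t: c for t in target_matrix.values.index if (c := cluster_of(t, "::tgt")) is not None
    }

    de_at = _de_row_lookup(annotations, de_tables)
    meta = regulator_matrix.row_meta
    subnetworks = []
    for tp in sample_info.timepoints:
        de_rows = set()
        for rid, gene, layer in zip(meta["row_id"], meta["gene_id"], meta["source_layer"]):
            if mode == "phosphosite":
                feats = de_at.get((gene, "phosphosite", tp), set())
                # the row is DE only if its own site is
                site_feat = rid  # row ids follow GENE@S<pos> like phospho features
                if site_feat in feats:
                    de_rows.add(rid)
            else:
                if de_at.get((gene, layer, tp)):
                    de_rows.add(rid)
        de_targets = de_features(de_tables.get("transcript"), tp)
        net = infer_subnetwork(
            regulator_matrix,
            target_matrix,
            reg_clusters,
            tgt_clusters,
            de_rows,
            de_targets,
            timepoint=tp,
            n_trees=config.n_trees,
            seed=config.seed,
            threshold_sd=config.threshold_sd,
        )
        log.info("%s subnetwork @%d min: %d edges", mode, tp, len(net))
        subnetworks.append(net)
    merged = merge_networks(subnetworks)
    return merged, subnetworks, clusters


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write TSV artifacts plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
    }

    def stage(name):
        log.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    transcripts, proteins, phosphos, sample_info, annotations, ploop, truth = load_inputs(config)
    s = stage("load")
    s["n_transcripts"], s["n_proteins"], s["n_phosphosites"] = (
        len(transcripts.values),
        len(proteins.values),
        len(phosphos.values),
    )

    # --- normalize (reporter-intensity layers only) ------------------------
    s = stage("normalize")
    proteins, prot_norm = normalize_layer(proteins, sample_info)
    phosphos, phos_norm = normalize_layer(phosphos, sample_info)
    s["proteins_dropped"] = len(prot_norm["dropped"])
    s["phosphosites_dropped"] = len(phos_norm["dropped"])
    onio.write_expression(proteins, out / "normalized_protein.tsv")
    onio.write_expression(phosphos, out / "normalized_phosphosite.tsv")

    # --- differential expression -------------------------------------------
    s = stage("diffexp")
    thresholds = {
        "transcript": Thresholds(config.transcript_fc, config.alpha, use_q=True),
        "protein": Thresholds(config.proteomic_fc, config.alpha, use_q=False),
        "phosphosite": Thresholds(config.proteomic_fc, config.alpha, use_q=False),
    }
    de_tables = {}
    for layer, matrix in (
        ("transcript", transcripts),
        ("protein", proteins),
        ("phosphosite", phosphos),
    ):
        test = welch_t_test if config.de_test == "welch" else rank_sum_test
        table = call_de(matrix, sample_info, layer=layer, test=test, thresholds=thresholds[layer])
        de_tables[layer] = table
        s[f"n_de_{layer}"] = int(table["is_de"].sum()) if len(table) else 0
        table.to_csv(out / f"de_{layer}.tsv", sep="\t", index=False)

    # --- TF-centered networks ----------------------------------------------
    tf_list = sorted(annotations.tf_genes())
    networks = {}
    for mode in ("abundance", "phosphosite"):
        s = stage(f"infer_{mode}")
        reg = build_regulator_matrix(
            tf_list,
            proteins,
            transcripts,
            phosphos,
            annotations,
            mode=mode,
            de_table=de_tables["phosphosite"],
        )
        merged, _, clusters = infer_tf_network(
            mode, reg, transcripts, sample_info, de_tables, annotations, config
        )
        networks[mode] = merged
        s["n_regulator_rows"] = len(reg.row_ids)
        s["k_clusters"] = clusters.k
        s["n_edges"] = len(merged)
        clusters.assignment.rename("cluster").to_csv(
            out / f"clusters_{mode}.tsv", sep="\t", index_label="feature_id"
        )
        onio.write_edge_table(merged, out / f"network_{mode}.tsv")

    # --- kinase-signaling network ------------------------------------------
    s = stage("kinase_net")
    # correlations run on log2 intensities over biological samples only:
    # reference channels carry no treatment signal, and log scale keeps
    # Pearson from being dominated by intensity skew
    bio_cols = sample_info.samples_for()
    phospho_log = OmicsMatrix("phosphosite", np.log2(phosphos.values[bio_cols] + 1e-12))
    regulators = select_ploop_regulators(
        de_tables["phosphosite"], phospho_log, annotations, ploop
    )
    ann = annotations.table
    de_phos = de_features(de_tables["phosphosite"])
    target_feats = [f for f in phosphos.values.index if f in de_phos]
    target_genes = dict(
        zip(ann["feature_id"], ann["gene_id"])
    )
    kinase_net = correlation_edges(
        regulators,
        phospho_log.values.loc[target_feats],
        target_genes=target_genes,
        pearson_min=config.pearson_min,
        spearman_min=config.spearman_min,
    )
    s["n_ploop_regulators"] = len(regulators)
    s["n_edges"] = len(kinase_net)
    onio.write_edge_table(kinase_net, out / "network_kinase.tsv")

    # --- merge + motif scoring ---------------------------------------------
    s = stage("merge")
    merged_all = merge_networks([networks["abundance"], networks["phosphosite"], kinase_net])
    s["n_edges"] = len(merged_all)
    onio.write_edge_table(merged_all, out / "network_merged.tsv")

    s = stage("nms")
    for mode in ("abundance", "phosphosite"):
        scored = nms_rank(count_motifs(networks[mode]))
        scored.to_csv(out / f"nms_{mode}.tsv", sep="\t", index_label="gene_id")
        s[f"top_{mode}"] = str(scored.index[0]) if len(scored) else ""

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    artifacts.update(
        networks=networks,
        kinase_network=kinase_net,
        merged_network=merged_all,
        de_tables=de_tables,
        truth=truth,
        manifest=manifest,
        out_dir=str(out),
    )
    return artifacts
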