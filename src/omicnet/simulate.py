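"""Synthetic multi-omic time course with a planted signaling cascade.

The generator emulates a hormone-treatment experiment: two conditions
(mock / treated), six timepoints, four replicates, profiled at three layers
(transcripts, proteins, phosphosites) with a TMT-style batch structure
(one 10-plex per timepoint: 8 biological samples plus 2 pooled internal-
reference channels).

Planted cascade, on a log2 scale around per-feature baselines:

* each kinase's activity follows a smooth saturating Hill-type activation
  curve over time in the treated condition and stays at baseline in mock;
  its activation-loop phosphosite intensity tracks that activity;
* each TF is driven by one upstream kinase: its phosphosite intensity —
  and, for a subset of TFs, protein and transcript abundance — responds
  log-linearly with a TF-specific activation shape (kinase-derived time
  constant jittered per TF, Hill coefficient, optional transient decay) so
  that TFs sharing a kinase remain distinguishable;
* target transcripts respond log-linearly to the mean activity of their
  1-3 planted TF regulators, delayed by ``lag_steps`` timepoints.  Edge
  signs are sign-coherent per target (each edge sign is the product of the
  target's response direction and its TF's direction) so planted effects
  never cancel and the ground truth stays verifiable.

Replicate variability has two coupled components, both scaled by
``noise_sd`` (a noiseless run is a biologically and technically perfect
experiment): *biological* fluctuations of kinase and TF activity per sample
that propagate down the cascade — a replicate pool with higher TF activity
shows higher (or lower, per sign) target expression, as in real biological
replicates — and independent multiplicative log-normal *measurement* noise.
Per-channel loading variation also scales with ``noise_sd``, and per-batch
multiplicative offsets exercise internal-reference normalization.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import (
    FeatureAnnotation,
    Network,
    OmicsMatrix,
    PloopTable,
    SampleInfo,
    ValidationError,
)

TMT_CHANNELS = ["126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131"]

# share of a TF's biological fluctuation inherited from its kinase
KINASE_COUPLING = 0.5
# biological activity fluctuation relative to technical measurement noise;
# biological replicate pools vary more than TMT quantification does
BIO_NOISE_RATIO = 1.0
# fraction of targets responding in the same direction their regulators move
# (cluster-restricted inference assumes co-varying regulator/target profiles,
# so the planted truth is predominantly coherent)
COHERENT_FRACTION = 0.8


@dataclass
class SimConfig:
    n_kinases: int = 5
    n_tfs: int = 10
    n_targets: int = 100
    n_null_targets: int = 1000
    n_decoy_tfs: int = 0  # annotated TFs with no treatment response
    n_null_proteins: int = 300
    n_null_phospho: int = 500
    regulators_per_target: tuple[int, int] = (1, 3)
    timepoints_min: tuple[int, ...] = (15, 30, 60, 120, 240, 480)
    replicates: int = 4
    noise_sd: float = 0.2
    lag_steps: int = 1
    seed: int = 0
    tf_protein_fraction: float = 0.6
    batch_effect_sd: float = 0.25

    def __post_init__(self) -> None:
        if min(self.n_kinases, self.n_tfs, self.n_targets, self.replicates) < 1:
            raise ValidationError("all counts must be >= 1")
        tps = list(self.timepoints_min)
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValidationError("timepoints must be strictly increasing")
        if self.noise_sd < 0 or self.lag_steps < 0:
            raise ValidationError("noise_sd and lag_steps must be non-negative")
        lo, hi = self.regulators_per_target
        if lo < 1 or hi < lo:
            raise ValidationError("invalid regulators_per_target range")


@dataclass
class SyntheticTruth:
    """Planted edges plus generative bookkeeping for recovery scoring."""

    edges: pd.DataFrame  # source, target, sign, edge_class, site_label
    tf_genes: list = field(default_factory=list)
    kinase_genes: list = field(default_factory=list)
    target_genes: list = field(default_factory=list)
    null_genes: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def positive_pairs(self, edge_class: str = "tf_target") -> set:
        e = self.edges.loc[self.edges["edge_class"] == edge_class]
        return set(zip(e["source"], e["target"]))

    def candidate_pairs(self, edge_class: str = "tf_target") -> list:
        if edge_class == "tf_target":
            sources = self.tf_genes
            targets = self.target_genes + self.null_genes
        elif edge_class == "kinase_tf":
            sources = self.kinase_genes
            targets = self.tf_genes
        else:
            raise ValidationError(f"unknown edge class {edge_class!r}")
        return [(s, t) for s in sources for t in targets if s != t]


def _hill(t: np.ndarray, tau: float, h: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return t**h / (t**h + tau**h)


def simulate_multiomics(config: SimConfig):
    """Generate (transcripts, proteins, phosphosites, sample_info,
    annotations, ploop_table, truth)."""
    rng = np.random.default_rng(config.seed)
    tps = list(config.timepoints_min)
    n_tp = len(tps)

    kinases = [f"KIN{i+1}" for i in range(config.n_kinases)]
    tfs = [f"TF{i+1}" for i in range(config.n_tfs)]
    targets = [f"G{i+1}" for i in range(config.n_targets)]
    nulls = [f"N{i+1}" for i in range(config.n_null_targets)]

    # --- sample design ------------------------------------------------------
    sample_rows = []
    for tp in tps:
        batch = f"TMT_{tp:03d}"
        ch = iter(TMT_CHANNELS)
        for treatment in ("mock", "treated"):
            for rep in range(1, config.replicates + 1):
                sample_rows.append(
                    (f"t{tp:03d}_{treatment}_r{rep}", treatment, tp, rep, batch, next(ch), False)
                )
        for ref in (1, 2):
            sample_rows.append(
                (f"t{tp:03d}_ref_{ref}", "reference", tp, ref, batch, next(ch, "131"), True)
            )
    sample_info = SampleInfo(
        pd.DataFrame(
            sample_rows,
            columns=[
                "sample_id",
                "treatment",
                "timepoint_min",
                "replicate",
                "batch",
                "channel",
                "is_reference",
            ],
        )
    )
    meta = sample_info.table
    nonref = meta.loc[~meta["is_reference"]].reset_index(drop=True)
    refrows = meta.loc[meta["is_reference"]].reset_index(drop=True)
    n_samples = len(nonref)
    samp_ids = list(nonref["sample_id"])
    tp_index = {tp: j for j, tp in enumerate(tps)}
    samp_tp = np.array([tp_index[t] for t in nonref["timepoint_min"]])
    samp_treated = (nonref["treatment"] == "treated").to_numpy()

    # --- kinase activation curves and per-sample activities ----------------
    bio_sd = BIO_NOISE_RATIO * config.noise_sd  # biological fluctuation of activities
    kin_tau = rng.uniform(20.0, 120.0, size=config.n_kinases)
    kin_amp = rng.uniform(1.5, 2.5, size=config.n_kinases)  # log2 at full activation
    kin_shape = {k: _hill(np.array(tps), kin_tau[i], 1.0) for i, k in enumerate(kinases)}
    kin_eta = {k: rng.normal(0, bio_sd, size=n_samples) for k in kinases}
    kin_act = {
        k: kin_shape[k][samp_tp] * samp_treated + kin_eta[k] for k in kinases
    }

    # --- TF activation shapes, driven by one kinase each -------------------
    truth_records = []
    tf_shape: dict[str, np.ndarray] = {}
    tf_sign: dict[str, int] = {}
    tf_kinase: dict[str, str] = {}
    tf_eta: dict[str, np.ndarray] = {}
    for i, tf in enumerate(tfs):
        k = kinases[i % config.n_kinases]
        tau = float(np.clip(kin_tau[kinases.index(k)] * np.exp(rng.normal(0, 0.35)), 10, 200))
        h = float(rng.choice([1.0, 2.0]))
        shape = _hill(np.array(tps), tau, h)
        if rng.random() < 0.25:  # transient responder
            shape = shape * np.exp(-np.array(tps, dtype=float) / 1000.0)
        shape = shape / shape.max()
        tf_shape[tf] = shape
        tf_sign[tf] = int(rng.choice([1, -1]))
        tf_kinase[tf] = k
        tf_eta[tf] = KINASE_COUPLING * kin_eta[k] + rng.normal(0, bio_sd, size=n_samples)

    # per-sample TF activity, contemporaneous and lagged views
    lag = config.lag_steps
    lag_shape = {
        tf: np.array([tf_shape[tf][j - lag] if j - lag >= 0 else 0.0 for j in range(n_tp)])
        for tf in tfs
    }
    tf_act = {tf: tf_shape[tf][samp_tp] * samp_treated + tf_eta[tf] for tf in tfs}
    tf_act_lag = {tf: lag_shape[tf][samp_tp] * samp_treated + tf_eta[tf] for tf in tfs}

    # --- planted TF -> target wiring ---------------------------------------
    # co-regulating TFs of one target act in the same direction, and most
    # targets respond in that direction (coherent regulation); the remainder
    # are repressed relative to their regulators' movement
    lo, hi = config.regulators_per_target
    sign_groups = {
        s: [tf for tf in tfs if tf_sign[tf] == s] for s in (1, -1)
    }
    sign_groups = {s: g for s, g in sign_groups.items() if g}
    group_signs = sorted(sign_groups)
    group_probs = np.array([len(sign_groups[s]) for s in group_signs], dtype=float)
    group_probs /= group_probs.sum()
    target_regs: dict[str, list] = {}
    target_sign: dict[str, int] = {}
    for g in targets:
        grp_sign = int(rng.choice(group_signs, p=group_probs))
        pool = sign_groups[grp_sign]
        n_reg = int(rng.integers(lo, hi + 1))
        target_regs[g] = list(rng.choice(pool, size=min(n_reg, len(pool)), replace=False))
        coherent = 1 if rng.random() < COHERENT_FRACTION else -1
        target_sign[g] = grp_sign * coherent

    # --- per-feature log2 response per sample ------------------------------
    transcript_resp: dict[str, np.ndarray] = {}
    protein_resp: dict[str, np.ndarray] = {}
    phospho_resp: dict[str, np.ndarray] = {}
    phospho_meta = []  # (feature_id, gene, position, is_kinase_gene, is_tf_gene)

    for i, k in enumerate(kinases):
        act = kin_act[k]
        ploop_pos, other_pos = 150, 30
        phospho_resp[f"{k}@S{ploop_pos}"] = kin_amp[i] * act
        phospho_meta.append((f"{k}@S{ploop_pos}", k, ploop_pos, True, False))
        phospho_resp[f"{k}@S{other_pos}"] = 0.6 * kin_amp[i] * act
        phospho_meta.append((f"{k}@S{other_pos}", k, other_pos, True, False))
        protein_resp[f"{k}_prot"] = 0.3 * act

    tf_with_protein = set(
        tfs[i] for i in range(len(tfs)) if rng.random() < config.tf_protein_fraction
    )
    for tf in tfs:
        act = tf_sign[tf] * tf_act[tf]
        site1 = int(rng.integers(170, 200))
        phospho_resp[f"{tf}@S{site1}"] = rng.uniform(1.5, 2.5) * act
        phospho_meta.append((f"{tf}@S{site1}", tf, site1, False, True))
        truth_records.append((tf_kinase[tf], tf, tf_sign[tf], "kinase_tf", f"S{site1}"))
        if rng.random() < 0.4:  # adjacent second site
            phospho_resp[f"{tf}@S{site1+1}"] = rng.uniform(1.5, 2.5) * act
            phospho_meta.append((f"{tf}@S{site1+1}", tf, site1 + 1, False, True))
        if tf in tf_with_protein:
            protein_resp[f"{tf}_prot"] = rng.uniform(1.5, 2.5) * act
        transcript_resp[tf] = rng.uniform(2.0, 3.0) * act

    for g in targets:
        regs = target_regs[g]
        drive = np.mean([tf_act_lag[f] for f in regs], axis=0)
        transcript_resp[g] = rng.uniform(2.5, 3.5) * target_sign[g] * drive
        for f in regs:
            truth_records.append((f, g, target_sign[g] * tf_sign[f], "tf_target", ""))
    decoy_tfs = [f"DTF{i+1}" for i in range(config.n_decoy_tfs)]
    for tf in decoy_tfs:
        transcript_resp[tf] = np.zeros(n_samples)
        if rng.random() < config.tf_protein_fraction:
            protein_resp[f"{tf}_prot"] = np.zeros(n_samples)
    for g in nulls:
        transcript_resp[g] = np.zeros(n_samples)
    # background (non-responsive) proteins and phosphosites keep column
    # totals stable, as in real (phospho)proteomes where most features do
    # not respond to the treatment
    for i in range(config.n_null_proteins):
        protein_resp[f"PBG{i+1}_prot"] = np.zeros(n_samples)
    bg_phospho = []
    for i in range(config.n_null_phospho):
        g = f"PBG{i % max(config.n_null_proteins, 1) + 1}"
        pos = 300 + i
        fid = f"{g}@S{pos}"
        phospho_resp[fid] = np.zeros(n_samples)
        phospho_meta.append((fid, g, pos, False, False))

    # --- technical structure: batches, loading, measurement noise ----------
    batch_factor = {
        b: float(np.exp(rng.normal(0, config.batch_effect_sd))) for b in sample_info.batches()
    }
    loading_sd = 0.5 * config.noise_sd
    loading = {
        s: float(np.exp(rng.normal(0, loading_sd))) if loading_sd > 0 else 1.0
        for s in meta["sample_id"]
    }

    def _intensity_matrix(responses: dict, baseline_log_mean, with_refs: bool, baseline_log_sd=0.8) -> pd.DataFrame:
        feats = list(responses)
        if callable(baseline_log_mean):
            mu = np.array([baseline_log_mean(f)[0] for f in feats])
            sd = np.array([baseline_log_mean(f)[1] for f in feats])
        else:
            mu = np.full(len(feats), float(baseline_log_mean))
            sd = np.full(len(feats), float(baseline_log_sd))
        baselines = np.exp(rng.normal(mu, sd))
        n_feat = len(feats)
        true_vals = np.empty((n_feat, n_samples))
        for fi, f in enumerate(feats):
            true_vals[fi] = baselines[fi] * 2.0 ** responses[f]
        pooled = true_vals.mean(axis=1)

        batch_vec = np.array([batch_factor[b] for b in nonref["batch"]])
        load_vec = np.array([loading[s] for s in samp_ids])
        obs = true_vals.copy()
        if with_refs:
            obs = obs * batch_vec[None, :]
        obs = obs * load_vec[None, :]
        if config.noise_sd > 0:
            obs = obs * np.exp(rng.normal(0, config.noise_sd, size=obs.shape))
        out = pd.DataFrame(obs, index=feats, columns=samp_ids)

        if with_refs:
            for _, row in refrows.iterrows():
                s = row["sample_id"]
                v = pooled * batch_factor[row["batch"]] * loading[s]
                if config.noise_sd > 0:
                    v = v * np.exp(rng.normal(0, config.noise_sd, size=n_feat))
                out[s] = v
            out = out[[s for s in meta["sample_id"]]]
        return out

    # strong responders are modest-expression regulatory genes; the stable
    # high-expression bulk (the nulls) dominates library size, keeping
    # counts-per-million scaling well behaved
    null_set = set(nulls)
    transcript_values = _intensity_matrix(
        transcript_resp,
        lambda f: (np.log(500.0), 1.0) if f in null_set else (np.log(80.0), 0.6),
        with_refs=False,
    )
    protein_values = _intensity_matrix(protein_resp, np.log(1e6), with_refs=True)
    phospho_values = _intensity_matrix(phospho_resp, np.log(1e6), with_refs=True)

    transcripts = OmicsMatrix("transcript", transcript_values)
    proteins = OmicsMatrix("protein", protein_values)
    phosphos = OmicsMatrix("phosphosite", phospho_values)

    # --- annotations and p-loop coordinates --------------------------------
    ann_rows = []
    all_tfs = set(tfs) | set(decoy_tfs)
    for g in list(transcript_values.index):
        ann_rows.append((g, g, "transcript", np.nan, g in all_tfs, g in set(kinases)))
    for f in list(protein_values.index):
        g = f.rsplit("_prot", 1)[0]
        ann_rows.append((f, g, "protein", np.nan, g in all_tfs, g in set(kinases)))
    for f, g, pos, is_kin, is_tf in phospho_meta:
        ann_rows.append((f, g, "phosphosite", float(pos), is_tf, is_kin))
    annotations = FeatureAnnotation(
        pd.DataFrame(
            ann_rows,
            columns=["feature_id", "gene_id", "layer", "site_position", "is_tf", "is_kinase"],
        )
    )
    ploop_table = PloopTable(
        pd.DataFrame({"protein_id": kinases, "ploop_start": 140, "ploop_end": 160})
    )

    truth = SyntheticTruth(
        edges=pd.DataFrame(
            truth_records, columns=["source", "target", "sign", "edge_class", "site_label"]
        ),
        tf_genes=tfs,
        kinase_genes=kinases,
        target_genes=targets,
        null_genes=nulls,
        params=asdict(config),
    )
    return transcripts, proteins, phosphos, sample_info, annotations, ploop_table, truth


def evaluate_recovery(
    network: Network,
    truth: SyntheticTruth,
    edge_class: str = "tf_target",
) -> dict:
    """Score an inferred network against the planted edges.

    All candidate regulator-target pairs for the edge class are ranked by
    the network's (maximum) edge weight, pairs absent from the network
    scoring 0; planted edges are the positives.  Returns AUPR, AUROC,
    planted-edge prevalence and the median rank of planted edges.
    """
    from sklearn.metrics import average_precision_score, roc_auc_score
    from scipy.stats import rankdata

    positives = truth.positive_pairs(edge_class)
    if not positives:
        raise ValidationError("no planted positives for this edge class")
    candidates = truth.candidate_pairs(edge_class)

    scores = {}
    for _, e in network.edges.iterrows():
        key = (e["source"], e["target"])
        scores[key] = max(scores.get(key, 0.0), float(e["weight"]))
    y_true = np.array([1 if pair in positives else 0 for pair in candidates])
    y_score = np.array([scores.get(pair, 0.0) for pair in candidates])
    if y_true.sum() == 0:
        raise ValidationError("planted edges fall outside the candidate universe")

    aupr = float(average_precision_score(y_true, y_score))
    auroc = float(roc_auc_score(y_true, y_score)) if 0 < y_true.sum() < len(y_true) else 1.0
    ranks = rankdata(-y_score, method="average")
    planted_ranks = ranks[y_true == 1]
    return {
        "aupr": aupr,
        "auroc": auroc,
        "prevalence": float(y_true.mean()),
        "median_planted_rank": float(np.median(planted_ranks)),
        "n_candidates": len(candidates),
        "n_positives": int(y_true.sum()),
    }
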