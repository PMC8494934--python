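"""Planted-cascade recovery: how well does inference find the true edges?

Simulates the default design (10 TFs, 100 targets, 6 timepoints x 2
conditions x 4 replicates), runs the cluster-restricted tree-ensemble
inference without an edge threshold (keeping the full ranking), and scores
the ranked TF->target list against the planted truth.
"""

import pandas as pd

from omicnet import (
    PipelineConfig,
    SimConfig,
    build_regulator_matrix,
    call_de,
    evaluate_recovery,
    simulate_multiomics,
)
from omicnet.diffexp import welch_t_test
from omicnet.pipeline import infer_tf_network, normalize_layer

t, p, ph, si, ann, ploop, truth = simulate_multiomics(SimConfig(seed=1))
p_norm, _ = normalize_layer(p, si)
de_tables = {
    "transcript": call_de(t, si, test=welch_t_test),
    "protein": call_de(p_norm, si, layer="protein", test=welch_t_test),
    "phosphosite": pd.DataFrame(),
}
reg = build_regulator_matrix(sorted(ann.tf_genes()), p_norm, t, ph, ann, mode="abundance")
config = PipelineConfig(seed=1, n_trees=100, threshold_sd=None)
merged, _, _ = infer_tf_network("abundance", reg, t, si, de_tables, ann, config)

metrics = evaluate_recovery(merged, truth)
print("recovery of the planted TF->target edges:")
for key in ("aupr", "auroc", "prevalence", "median_planted_rank"):
    print(f"  {key:<22} {metrics[key]:.3f}")
print(f"  aupr / prevalence      {metrics['aupr'] / metrics['prevalence']:.1f}x")
print("\nAUPR far above the planted-edge prevalence means the ranking")
print("concentrates true regulations at the top, despite only ~2% of all")
print("candidate pairs being real.")
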