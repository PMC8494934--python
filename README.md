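# omicnet

Integrative network inference for treated-vs-mock multi-omic time courses.

Systems-biology experiments increasingly profile the same perturbation at
several molecular layers — transcript counts, protein-group reporter
intensities from isobaric (TMT) labeling, and phosphosite intensities —
across a time series. `omicnet` turns such a dataset into predictive,
temporally resolved regulatory networks:

1. **TMT normalization** — sample-loading (within-run) followed by
   internal-reference scaling (between-run): each feature's pooled-reference
   mean in run *b*, r<sub>b</sub>, is driven to the geometric mean of the
   r<sub>b</sub> across runs, making intensities comparable between runs.
2. **Layer-specific differential expression** per timepoint — transcripts:
   *q* < 0.05 (Benjamini–Hochberg) and fold change > 1.25; proteins and
   phosphosites: *p* < 0.05 and fold change > 1.1 (two-sided: FC > c or
   FC < 1/c). The two-sample test is pluggable.
3. **Temporally informed clustering** — per-feature log₂(treated/mock)
   profiles, z-scored, clustered by dynamic-time-warping (DTW) distance with
   average-linkage agglomeration (silhouette-selected *k*); independent
   component analysis (ICA) assignment for non-temporal designs.
4. **Cluster-restricted tree-ensemble GRN inference** — for each target
   transcript, a random forest regresses the target on candidate TF
   regulators (protein abundance when quantified, else transcript; or
   phosphosite intensity), and the normalized variance-reduction importance
   w<sub>ij</sub> is the edge weight. TFs may only regulate transcripts in
   their own cluster; one subnetwork is inferred per timepoint using only
   the TFs and transcripts DE at that timepoint, and the six subnetworks are
   merged as a union, each edge keeping its timepoint label.
5. **Kinase-signaling network** — DE phosphosites inside a kinase's
   activation loop (p-loop) act as activity proxies; a kinase→site edge is
   kept when Pearson r ≥ 0.5 or Spearman ρ ≥ 0.6.
6. **Network Motif Score (NMS)** — per gene, participation counts in
   feed-forward loops, 2-node feedback loops, diamonds and bi-fans, each
   max-normalized to [0, 1] and summed (NMS ∈ [0, 4]); genes are ranked to
   nominate candidate regulators. A hypergeometric test checks enrichment of
   known genes among network regulators.

A first-class synthetic-data module generates the full study design
(6 timepoints × 2 treatments × 4 replicates, TMT 10-plex batches with
pooled reference channels) with a planted kinase → TF-phosphosite →
transcript cascade, so every stage can be validated against known ground
truth.

## Worked example

`examples/05_recovery_benchmark.py` simulates the default design, runs the
cluster-restricted inference keeping the full edge ranking, and scores it
against the planted truth:

```
recovery of the planted TF->target edges:
  aupr                   0.251
  auroc                  0.770
  prevalence             0.019
  median_planted_rank    296.000
  aupr / prevalence      13.4x
```

Only ~1.9% of the 11 000 candidate TF→target pairs are real, yet the ranked
edge list concentrates them strongly at the top (area under the
precision-recall curve 13× the random baseline). The other examples cover
normalization (`01`), DE filtering and the temporal cascade (`02`), the full
pipeline with motif ranking (`03`, where the planted TFs take the top NMS
ranks), and the kinase network (`04`).

The same pipeline runs from the shell:

```bash
omicnet run-all --out-dir out --seed 7          # simulated data
omicnet simulate --out-dir data --seed 1        # write the tables instead
omicnet normalize --matrix data/proteins.tsv --metadata data/sample_info.tsv \
    --layer protein --out-matrix norm.tsv --out-report report.tsv
```

All outputs are TSV; edge tables use the column layout Cytoscape imports
directly (`source  target  weight  edge_type  timepoint  site_label`).

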