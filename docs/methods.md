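# Methods

## Data model

Three expression layers share one sample design: transcript counts,
protein-group reporter intensities and phosphosite reporter intensities,
each a feature-by-sample matrix with missing values first-class (a feature
absent from a run stays NaN; nothing imputes). Sample metadata records
treatment (mock/treated), timepoint (minutes), replicate, TMT batch,
channel, and whether a channel is a pooled internal reference. Phosphosite
positions and activation-loop (p-loop) intervals are 1-based inclusive
amino-acid coordinates. Networks are directed weighted edge records keyed by
(source, target, edge_type, timepoint, site_label); the site label is part
of the key because two phosphosites of one TF are distinct regulatory
evidence for the same target.

## Normalization

Sample-loading normalization scales every channel in a batch so its column
total equals the batch's mean column total; it assumes roughly equal total
protein per channel, so relative values within a channel are untouched.
Internal-reference scaling then anchors each feature: with per-batch
reference means r_b (arithmetic mean over the batch's reference channels,
two in the default design), all of the feature's values in batch b are
multiplied by gmean(r)/r_b. The geometric mean is the natural center for
multiplicative batch effects and makes the anchored value independent of
batch order. Features lacking reference quantification in any batch cannot
be anchored and are dropped (reported). Invariants verified by the test
suite: within-batch column totals agree to 1e-12 relative; reference means
agree across batches to 1e-9 absolute on unit-scale data.

## Differential expression

Per timepoint, treated vs mock. Fold change is the ratio of condition means
on the analysis scale — counts-per-million for transcripts (library size
must not masquerade as regulation), normalized intensity for proteomics.
Layer rules: transcripts q < 0.05 (Benjamini–Hochberg within timepoint) and
FC > 1.25; proteins/phosphosites p < 0.05 and FC > 1.1; both two-sided
(FC > c or FC < 1/c). The two-sample test is a pluggable callable. The
module default is the exact rank-sum test; the orchestrated pipeline uses
Welch's t on log2 intensities (`de_test="welch"`), because at four
replicates per condition the exact rank-sum p-value floor is 2/70 ≈ 0.029,
which makes BH q < 0.05 unattainable unless the majority of features sit at
the floor — a degenerate regime for the transcript rule. A parametric test
on the log scale is the conventional choice at this replicate count.
Features missing more than half of a condition's replicates at a timepoint
are skipped there; a zero mock mean flags an infinite fold change and the
feature is excluded with a warning.

## Clustering

Profiles are log2(treated/mock) per timepoint, z-scored across timepoints,
so profile shape — not layer-specific amplitude — drives similarity.
Temporal designs use the classic DTW distance (absolute-difference local
cost, unconstrained window, boundary-matched path; with six-point series a
window constraint would be moot), pairwise distances feed average-linkage
agglomeration, and k maximizes the mean silhouette over k ∈ [2, min(15,
n−1)] unless the user fixes it. Non-temporal designs use FastICA: samples
are treated as observations of feature channels and each feature joins the
component with its maximum absolute mixing-matrix loading (component signs
are arbitrary, hence sign-agnostic); fixed seed, reproducible. Regulator
and target profiles are clustered together so that a TF can share a module
with its candidate targets; only transcripts that are DE somewhere enter
the clustering matrix, since only they can enter the networks.

## GRN inference

For each target, a random forest (default 1000 trees, sqrt(#regulators)
candidate predictors per split, fixed seed; all configurable) regresses the
target profile on candidate regulator profiles; the per-regulator
impurity-reduction importance, normalized to sum to one per target, is the
edge weight. Candidate regulators at a timepoint are the TFs DE at that
timepoint whose cluster matches the target's; targets are transcripts DE at
that timepoint; the target's own gene is excluded. The regression always
uses the full time-course sample set (48 columns in the default design) —
the per-timepoint restriction selects which genes participate, not which
samples, because eight samples cannot support a tree ensemble. Edge
retention defaults to weight > mean + 1 sd of the target's candidate
weights (an adaptive per-target cut that keeps hub targets from flooding
the network); alternatives are keep-top-N per target or no threshold (full
ranking, used for recovery benchmarking, where thresholding is a
presentation step). Regulator rows are sorted internally, and per-target
seeds derive from the top-level seed plus a CRC of the target id, so edge
weights are invariant to input row order and byte-identical across reruns.
Subnetworks from the six timepoints merge as a union of edge records,
idempotent and order-invariant, each record keeping its timepoint.

In abundance mode a TF's regulator row is its protein profile when
quantified, else its transcript profile, else the TF is excluded with a
warning; in phosphosite mode each DE phosphosite of a TF is its own
regulator row labeled `GENE@S<pos>`, and the predictive site travels on the
edge's site label.

## Kinase-signaling network

Regulators are DE phosphosites lying inside their kinase's p-loop interval
(inclusive ends; non-kinases and kinases without coordinates are excluded,
the latter with a warning). Targets are all DE phosphosites. For every
pair, Pearson and Spearman correlations over paired non-missing values; an
edge is kept when Pearson ≥ 0.5 or Spearman ≥ 0.6, one-sided positive as
conventionally thresholded for this network type (an `absolute` flag
enables |r| for exploration). The edge weight is the larger coefficient.
Self-pairs and pairs of sites on one protein are excluded — a kinase
"regulating" its own phosphosites is not a signaling prediction. The
module correlates whatever profiles it is given; the pipeline passes log2
intensities over biological samples only, because reference channels carry
no treatment contrast and raw-scale Pearson is dominated by intensity skew.
Correlations pool all 48 samples (both conditions), which maximizes power;
a treated-only restriction is a one-line configuration change.

## Network Motif Score

Motifs are matched non-induced on the unweighted distinct-pair view:
feed-forward loop (A→B, B→C, A→C), feedback loop (the 2-node mutual cycle;
longer cycles are not counted), diamond (A→B, A→C, B→D, C→D with {B, C}
unordered and A ≠ D) and bi-fan (A→C, A→D, B→C, B→D with {A, B} and {C, D}
unordered). A gene's count per motif type is the number of distinct
instances it participates in, in any role. NMS = Σ over types of count /
max count over genes (0 when the max is 0), dense-ranked descending with
ties sharing a rank. NMS is computed per merged TF network (abundance and
phosphosite separately), never across network types. Counts are validated
exactly against a brute-force enumerator over node tuples. Regulator
enrichment uses the upper-tail hypergeometric p for the overlap between the
network's source set and a supplied gene list within a universe.

## Synthetic data generator

The generator emulates the study design: 6 timepoints (15, 30, 60, 120,
240, 480 min) × 2 treatments × 4 replicates, with one TMT 10-plex per
timepoint (8 biological channels + 2 pooled references built from the grand
pooled mean) and per-batch multiplicative offsets (log-sd 0.25) for the
reference scaler to remove.

The planted cascade, on a log2 scale around per-feature baselines: each
kinase's activity follows a saturating Hill curve (time constants 20–120
min) in the treated condition; its p-loop site (amplitude 1.5–2.5 log2) and
a second, weaker non-p-loop site track that activity. Each TF is driven by
one kinase with a TF-specific activation shape (jittered time constant,
Hill coefficient 1 or 2, occasional transient decay) so TFs sharing a
kinase stay distinguishable; TF phosphosites (one or two adjacent sites),
protein abundance (a 60% subset, to exercise the protein-else-transcript
rule) and transcript abundance respond log-linearly with sign ±1. Targets
respond to the mean activity of 1–3 planted TFs delayed by one timepoint.
Two structural choices keep the ground truth verifiable: a target's
regulators are drawn from one sign group and 80% of targets respond
coherently with them (opposed planted effects would cancel, and
cluster-restricted inference assumes co-varying regulator/target
profiles); and replicate variability is split into propagated biological
activity fluctuations (sd = noise_sd, partially inherited from the kinase)
and independent log-normal measurement noise (sd = noise_sd) — in real
biological replicates a pool with higher TF activity shows correspondingly
shifted targets, and without that propagation planted and non-planted
pairs are statistically indistinguishable. Per-channel loading variation
scales with noise_sd, so a noiseless run is replicate-identical.

Background mass matters at desk scale: 1000 null transcripts, 300 null
proteins and 500 null phosphosites keep column totals stable (otherwise
sample-loading/CPM scaling converts the responders' aggregate shift into
spurious fold changes on the nulls), and responsive transcripts get modest
baselines while the stable bulk carries the library mass, as in real
transcriptomes where strong hormone responders are rarely the
highest-expressed genes. An optional pool of annotated but non-responsive
decoy TFs supports focused benchmarking scenarios.

What passing tests on this generator do not show: linear-with-lag
responses stand in for saturating/feedback ODE dynamics; missingness is not
simulated by default (the pipeline's missing-data paths are unit-tested
separately); true post-transcriptional decoupling of protein from
transcript is absent; and real TF collinearity is likely worse than the
generated shape diversity, so recovery numbers here are an upper bound on
real-data performance.

## Problem sizes and numerical choices

The default synthetic design (10 TFs, 5 kinases, 100 targets plus
background, 60 channels) runs the full pipeline in well under a minute with
100 trees; the test suite and the acceptance script use 30–150 trees, sizes
chosen so the whole validation runs comfortably on one CPU while leaving
the statistical conclusions unchanged (importance rankings stabilize well
below 1000 trees at ≤ 20 candidate regulators). Degenerate inputs are
defined, not special-cased: constant profiles z-score to zero and are
skipped by correlation with a note; a constant target yields all-zero
importances; an empty DE set yields an empty subnetwork with a warning; a
constant matrix projects to the origin in QC. Tie-breaks are deterministic
(stable sorts, dense ranks); all randomness fans out from a single seed.

## Known limitations

The DE caller tests each timepoint marginally (no time-course joint model).
The per-target mean+1sd edge threshold is a heuristic; when a target has
very few candidate regulators the strict inequality retains nothing, which
is intentional but means thresholded networks under-report sparse-candidate
targets — use the full ranking for benchmarking. One-sided kinase
correlation thresholds cannot recover negatively coupled kinase→site
pairs, capping recovery of sign-negative planted edges. ICA clustering is
offered for non-temporal designs but the temporal pipeline never invokes
it. Phosphosites mapping to multiple protein groups must be collapsed to a
single gene upstream; the data model requires one gene per feature.
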