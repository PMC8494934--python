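"""Network Motif Score (NMS): motif participation counts and gene ranking.

Four directed motifs are counted on the unweighted view of a network
(distinct (source, target) pairs, self-loops ignored):

* feed-forward loop (FFL): distinct A, B, C with A->B, B->C, A->C;
* feedback loop: distinct A, B with A->B and B->A (the 2-node mutual cycle);
* diamond: distinct A, B, C, D with A->B, A->C, B->D, C->D (B, C unordered);
* bi-fan: distinct A, B, C, D with A->C, A->D, B->C, B->D ({A,B} and {C,D}
  unordered).

Matching is non-induced: extra edges among the participating nodes do not
disqualify an instance.  A gene's count for a motif type is the number of
distinct instances it participates in, in any role.  The NMS is the sum over
motif types of the gene's count divided by the maximum count of that type
over all genes (0 when the max is 0), so it lies in [0, 4]; genes are then
dense-ranked descending, ties sharing a rank.
"""

from __future__ import annotations

from itertools import combinations

import pandas as pd
from scipy import stats

from .datamodel import Network, ValidationError

MOTIF_TYPES = ("ffl", "feedback", "diamond", "bifan")


def count_motifs(network: Network) -> pd.DataFrame:
    """Per-gene participation counts for the four motif types.

    Returns a DataFrame indexed by gene with columns ffl, feedback, diamond,
    bifan; genes are every node appearing in the network.
    """
    pairs = set(zip(network.edges["source"], network.edges["target"]))
    pairs = {(u, v) for u, v in pairs if u != v}
    nodes = sorted({u for u, _ in pairs} | {v for _, v in pairs})
    succ: dict = {n: set() for n in nodes}
    pred: dict = {n: set() for n in nodes}
    for u, v in pairs:
        succ[u].add(v)
        pred[v].add(u)

    counts = pd.DataFrame(0, index=pd.Index(nodes, name="gene_id"), columns=list(MOTIF_TYPES))

    # FFL: every edge A->B plus common successor C of A and B
    for a, b in pairs:
        for c in (succ[a] & succ[b]) - {a, b}:
            counts.loc[a, "ffl"] += 1
            counts.loc[b, "ffl"] += 1
            counts.loc[c, "ffl"] += 1

    # feedback: mutual 2-node cycles
    for a, b in pairs:
        if a < b and (b, a) in pairs:
            counts.loc[a, "feedback"] += 1
            counts.loc[b, "feedback"] += 1

    # diamond: source A, sink D (A != D), intermediates M = succ(A) & pred(D);
    # each unordered intermediate pair {B, C} is one instance
    for a in nodes:
        for d in nodes:
            if a == d:
                continue
            mids = (succ[a] & pred[d]) - {a, d}
            m = len(mids)
            if m < 2:
                continue
            n_inst = m * (m - 1) // 2
            counts.loc[a, "diamond"] += n_inst
            counts.loc[d, "diamond"] += n_inst
            for b in mids:
                counts.loc[b, "diamond"] += m - 1

    # bi-fan: unordered target pair {C, D}; sources S = pred(C) & pred(D);
    # each unordered source pair {A, B} in S is one instance
    for c, d in combinations(nodes, 2):
        sources = (pred[c] & pred[d]) - {c, d}
        s = len(sources)
        if s < 2:
            continue
        n_inst = s * (s - 1) // 2
        counts.loc[c, "bifan"] += n_inst
        counts.loc[d, "bifan"] += n_inst
        for a in sources:
            counts.loc[a, "bifan"] += s - 1

    return counts


def nms_rank(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize motif counts to [0, 1] per type, sum to the NMS, and rank.

    Per motif type, counts are divided by the maximum over genes (0 when the
    max is 0).  nms = sum of the four normalized scores (in [0, 4]).  Ranks
    are dense and descending by nms; ties share a rank.
    """
    out = counts.copy()
    nms = pd.Series(0.0, index=counts.index)
    for m in MOTIF_TYPES:
        mx = counts[m].max()
        nms += counts[m] / mx if mx > 0 else 0.0
    out["nms"] = nms
    out["rank"] = (
        (-nms).rank(method="dense").astype(int)
    )
    return out.sort_values(["rank", "nms"], kind="mergesort")


def regulator_enrichment(network: Network, gene_set: set, universe: set) -> dict:
    """Hypergeometric enrichment of a known-gene set among network regulators.

    Upper-tail p for the overlap between the network's regulator (source)
    set and ``gene_set``, drawing |regulators| genes from ``universe``.
    """
    if not universe:
        raise ValidationError("empty universe")
    regulators = set(network.edges["source"]) & universe
    gene_set = set(gene_set) & universe
    overlap = regulators & gene_set
    M = len(universe)
    n = len(gene_set)
    N = len(regulators)
    k = len(overlap)
    p = float(stats.hypergeom.sf(k - 1, M, n, N)) if N else 1.0
    return {
        "overlap": k,
        "n_regulators": N,
        "n_gene_set": n,
        "n_universe": M,
        "p": p,
    }
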