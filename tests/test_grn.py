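import numpy as np
import pandas as pd
import pytest

from omicnet import (
    Network,
    SimConfig,
    ValidationError,
    build_regulator_matrix,
    importance_scores,
    infer_subnetwork,
    merge_networks,
    simulate_multiomics,
)
from omicnet.grn import RegulatorMatrix, _retain


@pytest.fixture(scope="module")
def cascade():
    cfg = SimConfig(
        seed=11,
        n_kinases=3,
        n_tfs=6,
        n_targets=20,
        n_null_targets=150,
        n_null_phospho=80,
        n_null_proteins=50,
    )
    return simulate_multiomics(cfg)


class TestBuildRegulatorMatrix:
    def test_protein_preferred_over_transcript(self, cascade):
        transcripts, proteins, phosphos, si, ann, *_ = cascade
        reg = build_regulator_matrix(
            sorted(ann.tf_genes()), proteins, transcripts, phosphos, ann, mode="abundance"
        )
        meta = reg.row_meta.set_index("gene_id")
        with_protein = {
            g
            for g in ann.tf_genes()
            if any(
                (ann.table["gene_id"] == g) & (ann.table["layer"] == "protein")
            )
        }
        for tf in reg.row_meta["gene_id"]:
            expected = "protein" if tf in with_protein else "transcript"
            assert meta.loc[tf, "source_layer"] == expected

    def test_phosphosite_mode_one_row_per_de_site(self, cascade):
        transcripts, proteins, phosphos, si, ann, *_ = cascade
        # declare exactly two sites of one TF as DE
        tf = "TF1"
        sites = ann.table.loc[
            (ann.table["gene_id"] == tf) & (ann.table["layer"] == "phosphosite")
        ]
        de_table = pd.DataFrame(
            {
                "feature_id": sites["feature_id"],
                "timepoint_min": 15,
                "fold_change": 2.0,
                "p": 0.01,
                "q": 0.01,
                "direction": "up",
                "is_de": True,
            }
        )
        with pytest.warns(UserWarning):
            reg = build_regulator_matrix(
                sorted(ann.tf_genes()), proteins, transcripts, phosphos, ann,
                mode="phosphosite", de_table=de_table,
            )
        assert list(reg.row_meta["gene_id"].unique()) == [tf]
        labels = sorted(reg.row_meta["row_id"])
        positions = sorted(int(p) for p in sites["site_position"])
        assert labels == [f"{tf}@S{p}" for p in positions]

    def test_tf_absent_everywhere_excluded_with_warning(self, cascade):
        transcripts, proteins, phosphos, si, ann, *_ = cascade
        with pytest.warns(UserWarning, match="GHOST"):
            reg = build_regulator_matrix(
                ["TF1", "GHOST"], proteins, transcripts, phosphos, ann, mode="abundance"
            )
        assert "GHOST" not in set(reg.row_meta["gene_id"])

    def test_empty_result_rejected(self, cascade):
        transcripts, proteins, phosphos, si, ann, *_ = cascade
        with pytest.raises(ValidationError):
            with pytest.warns(UserWarning):
                build_regulator_matrix(
                    ["GHOST"], proteins, transcripts, phosphos, ann, mode="abundance"
                )


class TestImportanceScores:
    def make_regs(self, rng, n_samples=24, n_noise=5, target=None):
        cols = [f"s{i}" for i in range(n_samples)]
        rows = {f"noise{i}": rng.normal(size=n_samples) ** 2 + 1 for i in range(n_noise)}
        if target is not None:
            rows["planted"] = target
        return pd.DataFrame(rows, index=cols).T

    @pytest.mark.parametrize("n_seeds", [20])
    def test_identical_regulator_wins(self, n_seeds):
        """The regulator equal to the target outranks independent noise."""
        wins = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=24) ** 2 + 1
            regs = self.make_regs(rng, target=y)
            target = pd.Series(y, index=regs.columns)
            w = importance_scores(target, regs, n_trees=100, seed=seed)
            wins += w.idxmax() == "planted"
        assert wins >= 19

    def test_constant_regulator_gets_zero_weight(self):
        rng = np.random.default_rng(0)
        regs = self.make_regs(rng)
        regs.loc["flat"] = 1.0
        target = pd.Series(rng.normal(size=24), index=regs.columns)
        w = importance_scores(target, regs, n_trees=50, seed=0)
        assert w["flat"] == 0.0

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(1)
        regs = self.make_regs(rng)
        target = pd.Series(rng.normal(size=24), index=regs.columns)
        w = importance_scores(target, regs, n_trees=50, seed=0)
        assert w.sum() == pytest.approx(1.0)

    def test_constant_target_all_zero(self):
        rng = np.random.default_rng(2)
        regs = self.make_regs(rng)
        target = pd.Series(1.0, index=regs.columns)
        w = importance_scores(target, regs, n_trees=50, seed=0)
        assert (w == 0).all()

    def test_invariant_to_regulator_row_order(self):
        rng = np.random.default_rng(3)
        regs = self.make_regs(rng)
        target = pd.Series(rng.normal(size=24), index=regs.columns)
        a = importance_scores(target, regs, n_trees=50, seed=4)
        b = importance_scores(target, regs.iloc[::-1], n_trees=50, seed=4)
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(4)
        regs = self.make_regs(rng, n_samples=5)
        target = pd.Series(rng.normal(size=5), index=regs.columns)
        with pytest.raises(ValidationError):
            importance_scores(target, regs, n_trees=10, seed=0)


class TestInferSubnetwork:
    def setup_case(self, cascade):
        transcripts, proteins, phosphos, si, ann, ploop, truth = cascade
        reg = build_regulator_matrix(
            sorted(ann.tf_genes()), proteins, transcripts, phosphos, ann, mode="abundance"
        )
        return transcripts, si, ann, truth, reg

    def test_self_only_candidate_yields_no_edges(self, cascade):
        transcripts, si, ann, truth, reg = self.setup_case(cascade)
        tf = reg.row_ids[0]
        # the TF's own transcript is the target; same cluster contains only itself
        net = infer_subnetwork(
            reg,
            transcripts,
            reg_clusters={tf: 1},
            tgt_clusters={tf: 1},
            de_regulator_rows={tf},
            de_target_features={tf},
            timepoint=15,
            n_trees=20,
            seed=0,
        )
        assert len(net) == 0

    def test_cluster_restriction_blocks_cross_cluster_edges(self, cascade):
        transcripts, si, ann, truth, reg = self.setup_case(cascade)
        tfs = reg.row_ids
        targets = list(truth.target_genes[:5])
        net = infer_subnetwork(
            reg,
            transcripts,
            reg_clusters={r: 1 for r in tfs},
            tgt_clusters={t: 2 for t in targets},  # disjoint clusters
            de_regulator_rows=set(tfs),
            de_target_features=set(targets),
            timepoint=15,
            n_trees=20,
            seed=0,
        )
        assert len(net) == 0

    def test_no_de_members_yields_empty_network_with_warning(self, cascade):
        transcripts, si, ann, truth, reg = self.setup_case(cascade)
        with pytest.warns(UserWarning, match="empty"):
            net = infer_subnetwork(
                reg, transcripts, {}, {}, set(), set(), timepoint=15, n_trees=10, seed=0
            )
        assert len(net) == 0

    def test_edges_carry_timepoint_and_type(self, cascade):
        transcripts, si, ann, truth, reg = self.setup_case(cascade)
        tfs = reg.row_ids
        targets = list(truth.target_genes[:8])
        net = infer_subnetwork(
            reg,
            transcripts,
            reg_clusters={r: 1 for r in tfs},
            tgt_clusters={t: 1 for t in targets},
            de_regulator_rows=set(tfs),
            de_target_features=set(targets),
            timepoint=30,
            n_trees=50,
            seed=0,
        )
        assert len(net) > 0
        assert set(net.edges["timepoint"]) == {30}
        assert set(net.edges["edge_type"]) == {"abundance"}
        assert (net.edges["source"] != net.edges["target"]).all()

    def test_planted_two_regulator_target_retained_at_default_threshold(self):
        """Both planted regulators of 2-regulator targets survive the
        mean+1sd cut when the remaining candidates are non-responsive TFs."""
        seeds_ok = 0
        for seed in range(10):
            cfg = SimConfig(
                seed=100 + seed,
                n_tfs=2,
                n_kinases=2,
                n_decoy_tfs=6,
                n_targets=4,
                regulators_per_target=(2, 2),
                n_null_targets=60,
                n_null_phospho=60,
                n_null_proteins=40,
            )
            transcripts, proteins, phosphos, si, ann, ploop, truth = simulate_multiomics(cfg)
            reg = build_regulator_matrix(
                sorted(ann.tf_genes()), proteins, transcripts, phosphos, ann, mode="abundance"
            )
            cols = si.samples_for()
            pos = truth.positive_pairs()
            successes = 0
            for g in truth.target_genes:
                w = importance_scores(
                    transcripts.values.loc[g, cols], reg.values[cols], n_trees=150, seed=seed
                )
                kept = set(_retain(w, 1.0, None).index)
                planted = {str(s) for s, t in pos if t == g}
                successes += planted <= kept
            seeds_ok += successes / len(truth.target_genes) > 0.5
        assert seeds_ok >= 8

    def test_retention_modes(self):
        w = pd.Series({"a": 0.5, "b": 0.3, "c": 0.1, "d": 0.1})
        assert set(_retain(w, None, None).index) == {"a", "b", "c", "d"}
        assert list(_retain(w, None, 2).index) == ["a", "b"]
        cut = w.mean() + w.std(ddof=0)
        assert set(_retain(w, 1.0, None).index) == set(w[w > cut].index)


class TestMergeNetworks:
    def net(self, records):
        return Network.from_records(records)

    def test_merging_single_network_is_identity(self):
        n = self.net([("a", "b", 0.5, "abundance", 15, "")])
        assert merge_networks([n]).record_keys() == n.record_keys()

    def test_disjoint_union_counts(self):
        n1 = self.net([(f"a{i}", "b", 0.1, "abundance", 15, "") for i in range(3)])
        n2 = self.net([(f"c{i}", "d", 0.1, "abundance", 15, "") for i in range(4)])
        assert len(merge_networks([n1, n2])) == 7

    def test_same_edge_at_two_timepoints_keeps_both_records(self):
        n1 = self.net([("a", "b", 0.5, "abundance", 15, "")])
        n2 = self.net([("a", "b", 0.6, "abundance", 30, "")])
        merged = merge_networks([n1, n2])
        assert len(merged) == 2
        assert set(merged.edges["timepoint"]) == {15, 30}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_idempotent_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        nets = []
        for _ in range(3):
            records = {}
            while len(records) < 10:
                s, t = rng.choice(8, size=2, replace=False)
                key = (f"g{s}", f"g{t}", "abundance", int(rng.choice([15, 30])), "")
                records[key] = (key[0], key[1], float(rng.random()), key[2], key[3], key[4])
            nets.append(self.net(sorted(records.values())))
        merged = merge_networks(nets)
        again = merge_networks([merged, merged])
        assert again.record_keys() == merged.record_keys()
        reordered = merge_networks(nets[::-1])
        assert reordered.record_keys() == merged.record_keys()
        union = set().union(*[n.record_keys() for n in nets])
        assert merged.record_keys() == union
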