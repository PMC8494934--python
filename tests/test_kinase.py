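import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicnet import (
    FeatureAnnotation,
    OmicsMatrix,
    PloopTable,
    correlation_edges,
    select_ploop_regulators,
)
from omicnet.kinase import KinaseRegulator, activation_state_report
from .conftest import simple_design


def make_reg(name, values, gene=None, site="S1"):
    idx = [f"s{i}" for i in range(len(values))]
    return KinaseRegulator(
        gene_id=gene or name, feature_id=f"{gene or name}@{site}",
        site_label=site, profile=pd.Series(values, index=idx, dtype=float),
    )


def targets_frame(rows: dict, n):
    idx = [f"s{i}" for i in range(n)]
    return pd.DataFrame({k: pd.Series(v, index=idx, dtype=float) for k, v in rows.items()}).T


class TestPloopSelection:
    def setup_tables(self):
        ann = FeatureAnnotation(
            pd.DataFrame(
                {
                    "feature_id": ["K1@S150", "K1@S139", "K2@S150", "TF@S150"],
                    "gene_id": ["K1", "K1", "K2", "TF"],
                    "layer": "phosphosite",
                    "site_position": [150.0, 139.0, 150.0, 150.0],
                    "is_tf": [False, False, False, True],
                    "is_kinase": [True, True, True, False],
                }
            )
        )
        ploop = PloopTable(
            pd.DataFrame({"protein_id": ["K1"], "ploop_start": [140], "ploop_end": [160]})
        )
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.random((4, 6)) + 1,
            index=["K1@S150", "K1@S139", "K2@S150", "TF@S150"],
            columns=[f"s{i}" for i in range(6)],
        )
        matrix = OmicsMatrix("phosphosite", values)
        return ann, ploop, matrix

    def de_table(self, features):
        return pd.DataFrame(
            {
                "feature_id": list(features),
                "timepoint_min": 15,
                "fold_change": 2.0,
                "p": 0.01,
                "q": 0.01,
                "direction": "up",
                "is_de": True,
            }
        )

    def test_site_inside_interval_selected(self):
        ann, ploop, matrix = self.setup_tables()
        regs = select_ploop_regulators(self.de_table(["K1@S150"]), matrix, ann, ploop)
        assert [(r.gene_id, r.site_label) for r in regs] == [("K1", "S150")]

    def test_site_outside_interval_excluded(self):
        ann, ploop, matrix = self.setup_tables()
        regs = select_ploop_regulators(self.de_table(["K1@S139"]), matrix, ann, ploop)
        assert regs == []

    def test_non_de_ploop_site_excluded(self):
        ann, ploop, matrix = self.setup_tables()
        regs = select_ploop_regulators(self.de_table([]), matrix, ann, ploop)
        assert regs == []

    def test_kinase_without_coordinates_warned_and_skipped(self):
        ann, ploop, matrix = self.setup_tables()
        with pytest.warns(UserWarning, match="K2"):
            regs = select_ploop_regulators(
                self.de_table(["K1@S150", "K2@S150"]), matrix, ann, ploop
            )
        assert [(r.gene_id, r.site_label) for r in regs] == [("K1", "S150")]

    def test_non_kinase_protein_never_selected(self):
        ann, ploop, matrix = self.setup_tables()
        ploop2 = PloopTable(
            pd.DataFrame({"protein_id": ["K1", "TF"], "ploop_start": [140, 140], "ploop_end": [160, 160]})
        )
        regs = select_ploop_regulators(self.de_table(["TF@S150"]), matrix, ann, ploop2)
        assert regs == []


class TestCorrelationEdges:
    def test_pearson_passes_spearman_fails_edge_kept(self):
        """A pair with Pearson above 0.5 is kept even with low Spearman.

        A shared extreme point drives Pearson while the remaining ranks are
        scrambled, keeping Spearman below its threshold."""
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 9, 100])
        y = np.array([5.0, 3, 8, 1, 9, 2, 7, 4, 6, 100])
        pear = stats.pearsonr(x, y).statistic
        spear = stats.spearmanr(x, y).statistic
        assert pear >= 0.5 and spear < 0.5  # scenario precondition
        reg = make_reg("K1", x)
        net = correlation_edges([reg], targets_frame({"T1": y}, 10))
        assert len(net) == 1
        assert net.edges["weight"].iloc[0] == pytest.approx(max(pear, spear))

    def test_identical_profile_on_other_protein_kept(self):
        x = np.arange(8.0)
        reg = make_reg("K1", x)
        net = correlation_edges([reg], targets_frame({"T1": x}, 8))
        assert len(net) == 1
        assert net.edges["weight"].iloc[0] == pytest.approx(1.0)

    def test_pair_below_both_thresholds_dropped(self):
        """Constructed 8-point pair with Pearson ~0.45 and Spearman ~0.55."""
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        found = None
        rng = np.random.default_rng(1)
        for _ in range(5000):
            y = x + rng.normal(0, 3.5, size=8)
            pear = stats.pearsonr(x, y).statistic
            spear = stats.spearmanr(x, y).statistic
            if 0.4 < pear < 0.5 and 0.5 < spear < 0.6:
                found = (y, pear, spear)
                break
        assert found is not None
        y, pear, spear = found
        net = correlation_edges([make_reg("K1", x)], targets_frame({"T1": y}, 8))
        assert len(net) == 0

    def test_same_protein_pairs_and_self_excluded(self):
        x = np.arange(8.0)
        reg = make_reg("K1", x, site="S150")
        frame = targets_frame({"K1@S150": x, "K1@S30": x, "T1": x}, 8)
        net = correlation_edges(
            [reg], frame, target_genes={"K1@S150": "K1", "K1@S30": "K1", "T1": "T1"}
        )
        assert set(net.edges["target"]) == {"T1"}

    def test_constant_profile_skipped_with_note(self):
        reg = make_reg("K1", np.arange(8.0))
        with pytest.warns(UserWarning, match="constant"):
            net = correlation_edges([reg], targets_frame({"T1": np.ones(8)}, 8))
        assert len(net) == 0

    def test_absolute_flag_admits_negative_correlation(self):
        x = np.arange(8.0)
        net = correlation_edges([make_reg("K1", x)], targets_frame({"T1": -x}, 8))
        assert len(net) == 0
        net = correlation_edges(
            [make_reg("K1", x)], targets_frame({"T1": -x}, 8), absolute=True
        )
        assert len(net) == 1

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_recomputation(self, seed):
        """Retained edges equal direct evaluation of both coefficients."""
        rng = np.random.default_rng(seed)
        n_reg, n_tgt, n_obs = 12, 30, 20
        regs = [make_reg(f"K{i}", rng.normal(size=n_obs), site="S150") for i in range(n_reg)]
        frame = targets_frame({f"T{j}": rng.normal(size=n_obs) for j in range(n_tgt)}, n_obs)
        net = correlation_edges(regs, frame)
        got = set(zip(net.edges["source"], net.edges["target"]))
        expected = set()
        for r in regs:
            for t in frame.index:
                x, y = r.profile.to_numpy(), frame.loc[t].to_numpy()
                pear = np.corrcoef(x, y)[0, 1]
                spear = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
                if pear >= 0.5 or spear >= 0.6:
                    expected.add((r.gene_id, t))
        assert got == expected

    def test_threshold_anti_monotonicity(self):
        rng = np.random.default_rng(3)
        regs = [make_reg(f"K{i}", rng.normal(size=15), site="S150") for i in range(8)]
        frame = targets_frame({f"T{j}": rng.normal(size=15) for j in range(20)}, 15)
        base = correlation_edges(regs, frame, pearson_min=0.2, spearman_min=0.3)
        tighter = correlation_edges(regs, frame, pearson_min=0.4, spearman_min=0.5)
        assert tighter.record_keys() <= base.record_keys()

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(size=20)
        spear = stats.spearmanr(x, y).statistic
        pear_on_ranks = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert spear == pytest.approx(pear_on_ranks)


class TestActivationStateReport:
    def build(self, site_vals, abund_vals):
        si = simple_design(timepoints=(15,), replicates=4, batch="b")
        cols = si.sample_ids
        ann = FeatureAnnotation(
            pd.DataFrame(
                {
                    "feature_id": ["K1_prot", "K1@S150"],
                    "gene_id": ["K1", "K1"],
                    "layer": ["protein", "phosphosite"],
                    "site_position": [np.nan, 150.0],
                    "is_tf": False,
                    "is_kinase": True,
                }
            )
        )
        reg = KinaseRegulator("K1", "K1@S150", "S150", pd.Series(site_vals, index=cols))
        abundance = OmicsMatrix(
            "protein", pd.DataFrame([abund_vals], index=["K1_prot"], columns=cols)
        )
        phos = OmicsMatrix(
            "phosphosite", pd.DataFrame([site_vals], index=["K1@S150"], columns=cols)
        )
        return abundance, phos, reg, ann, si

    def test_proportional_profiles_correlate_perfectly(self):
        site = np.arange(1.0, 9.0)
        abundance, phos, reg, ann, si = self.build(site, site * 3)
        out = activation_state_report(abundance, phos, [reg], ann, si)
        assert out["correlation"].iloc[0] == pytest.approx(1.0)

    def test_independent_profiles_center_near_zero(self):
        rng = np.random.default_rng(0)
        corrs = []
        for _ in range(100):
            abundance, phos, reg, ann, si = self.build(
                rng.normal(size=8) + 5, rng.normal(size=8) + 5
            )
            out = activation_state_report(abundance, phos, [reg], ann, si)
            corrs.append(out["correlation"].iloc[0])
        assert abs(np.mean(corrs)) < 0.1

    def test_kinase_missing_from_abundance_flagged(self):
        site = np.arange(1.0, 9.0)
        abundance, phos, reg, ann, si = self.build(site, site)
        empty = OmicsMatrix("protein", abundance.values.iloc[0:0])
        out = activation_state_report(empty, phos, [reg], ann, si)
        assert out["note"].str.contains("not in abundance").all()
        assert out["correlation"].isna().all()
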