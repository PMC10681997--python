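import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from fragseq.io import ValidationError
from fragseq.simulate import (
    LobuleSimConfig,
    ZonatedGeneSpec,
    simulate_landmark_panel,
    simulate_lobule_experiment,
)
from fragseq.zonation import (
    DegenerateRescaleError,
    allocate_spot_celltype,
    assign_proximity,
    bin_layers,
    compute_zc,
    filter_landmarks,
    fragment_pseudobulk,
    group_zone,
    landmark_cluster_fragments,
)


def make_panel(rows):
    """rows: list of (gene, zone, means list, sems list)."""
    out = []
    for gene, zone, means, sems in rows:
        row = {"gene": gene, "zone": zone}
        for k, (m, s) in enumerate(zip(means, sems), 1):
            row[f"L{k}_mean"] = m
            row[f"L{k}_sem"] = s
        out.append(row)
    return pd.DataFrame(out)


class TestFilterLandmarks:
    def test_flat_profile_removed_by_fold_change(self):
        panel = make_panel([("flat", "central", [1e-3] * 10, [1e-5] * 10)])
        assert len(filter_landmarks(panel)) == 0

    def test_noisy_profile_removed_by_cv(self):
        means = list(np.linspace(1e-3, 2e-3, 10))
        panel = make_panel([("noisy", "portal", means, means)])  # SEM == mean
        assert len(filter_landmarks(panel)) == 0

    def test_silenced_pole_passes_with_flag(self):
        means = [0.0] + list(np.linspace(1e-4, 1e-3, 9))
        sems = [0.0] + [1e-5] * 9
        with pytest.warns(UserWarning, match="silenced"):
            kept = filter_landmarks(make_panel([("silent", "portal", means, sems)]))
        assert len(kept) == 1 and np.isinf(kept["fold_change"].iloc[0])

    def test_random_panel_matches_naive_predicate_oracle(self, rng):
        rows = []
        for i in range(50):
            means = rng.uniform(0, 2e-3, 10)
            sems = rng.uniform(0, 4e-4, 10)
            rows.append((f"g{i}", "central" if i % 2 else "portal", means, sems))
        panel = make_panel(rows)
        kept = set(filter_landmarks(panel)["gene"])
        oracle = set()
        for gene, _, means, sems in rows:
            means, sems = np.asarray(means), np.asarray(sems)
            a, b = means[0], means[-1]
            if min(a, b) > 0:
                fc = max(a, b) / min(a, b)
            else:
                fc = np.inf if max(a, b) > 0 else 1.0
            ratios = [s / m for m, s in zip(means, sems) if m > 0]
            cv = np.mean(ratios) if ratios else np.inf
            if means.max() > 1e-5 and fc >= 1.1 and cv < 0.2:
                oracle.add(gene)
        assert kept == oracle


class TestFragmentPseudobulk:
    def test_min_cells_excludes_small_fragments(self, toy_experiment):
        pb = fragment_pseudobulk(toy_experiment, "LEC", min_cells=2)
        assert list(pb.index) == ["F2"]  # only F2 has 2 LECs

    def test_sum_mode_adds_counts(self, toy_experiment):
        pb = fragment_pseudobulk(toy_experiment, "LEC", min_cells=2, mode="sum")
        dense = toy_experiment.counts.to_dense()
        # F2's LECs are c3 and c4 (columns 2, 3)
        assert np.allclose(pb.loc["F2"].to_numpy(), dense[:, 2] + dense[:, 3])

    def test_matches_groupby_oracle_on_random_experiment(self):
        exp, _ = simulate_lobule_experiment(LobuleSimConfig(n_fragments=25, seed=13))
        pb = fragment_pseudobulk(exp, "LEC", min_cells=3, mode="sum")
        dense = pd.DataFrame(
            exp.counts.to_dense().T, index=exp.counts.cells, columns=exp.counts.genes
        )
        lec = exp.cells[exp.cells["cell_type"] == "LEC"]
        oracle = dense.loc[lec.index].groupby(lec["fragment"]).sum()
        oracle = oracle[lec.groupby("fragment").size() >= 3]
        pd.testing.assert_frame_equal(
            pb, oracle.loc[pb.index].astype(float), check_names=False
        )


class TestComputeZc:
    @pytest.fixture
    def two_gene_panel(self):
        return make_panel(
            [
                ("c1", "central", np.linspace(2e-3, 1e-4, 10), [1e-5] * 10),
                ("p1", "portal", np.linspace(1e-4, 2e-3, 10), [1e-5] * 10),
            ]
        )

    def test_pure_central_fragment_has_zc_zero(self, two_gene_panel):
        pb = pd.DataFrame({"c1": [10.0, 5.0, 0.0], "p1": [0.0, 5.0, 10.0]}, index=list("abc"))
        res = compute_zc(pb, two_gene_panel)
        assert res.loc["a", "zc_raw"] == 0.0
        assert res.loc["b", "zc_raw"] == pytest.approx(0.5)

    def test_rescale_formula(self, two_gene_panel):
        # raw ZCs 0.2, 0.4, 0.8 -> rescaled 0, 1/3, 1
        pb = pd.DataFrame({"c1": [8.0, 6.0, 2.0], "p1": [2.0, 4.0, 8.0]}, index=list("abc"))
        res = compute_zc(pb, two_gene_panel)
        assert np.allclose(res["zc_raw"], [0.2, 0.4, 0.8])
        assert np.allclose(res["zc_rescaled"], [0.0, 1 / 3, 1.0])

    def test_gene_scaling_invariance(self, two_gene_panel, rng):
        pb = pd.DataFrame(
            rng.uniform(0, 10, (8, 2)), columns=["c1", "p1"],
            index=[f"f{i}" for i in range(8)],
        )
        base = compute_zc(pb, two_gene_panel)
        scaled = pb.copy()
        scaled["p1"] *= 37.5  # max-normalization absorbs per-gene scale
        again = compute_zc(scaled, two_gene_panel)
        pd.testing.assert_frame_equal(base, again)

    def test_zero_landmark_fragment_dropped(self, two_gene_panel):
        pb = pd.DataFrame({"c1": [5.0, 0.0, 1.0], "p1": [1.0, 0.0, 5.0]}, index=list("abc"))
        with pytest.warns(UserWarning, match="dropping"):
            res = compute_zc(pb, two_gene_panel)
        assert list(res.index) == ["a", "c"]

    def test_degenerate_rescale_raises(self, two_gene_panel):
        pb = pd.DataFrame({"c1": [5.0, 5.0], "p1": [5.0, 5.0]}, index=list("ab"))
        with pytest.raises(DegenerateRescaleError):
            compute_zc(pb, two_gene_panel)

    def test_rescale_preserves_order(self, two_gene_panel, rng):
        pb = pd.DataFrame(
            rng.uniform(0.1, 10, (20, 2)), columns=["c1", "p1"],
            index=[f"f{i}" for i in range(20)],
        )
        res = compute_zc(pb, two_gene_panel)
        assert sps.spearmanr(res["zc_raw"], res["zc_rescaled"]).statistic == pytest.approx(1.0)
        assert res["zc_raw"].between(0, 1).all()


class TestLayerBinning:
    def test_decile_examples(self):
        res = pd.DataFrame({"zc_rescaled": [0.05, 0.95, 1.0, 0.9, 0.1]})
        out = bin_layers(res)
        assert list(out["layer"]) == ["L1", "L10", "L10", "L10", "L2"]

    def test_grid_covers_ten_distinct_layers(self):
        grid = np.arange(0.05, 1.0, 0.1)
        out = bin_layers(pd.DataFrame({"zc_rescaled": grid}))
        assert list(out["layer"]) == [f"L{k}" for k in range(1, 11)]

    def test_merged_extremes(self):
        out = bin_layers(pd.DataFrame({"zc_rescaled": [0.05, 0.25, 0.45, 0.85, 0.95]}))
        assert list(out["layer_merged"].astype(str)) == ["L1-L3", "L1-L3", "L5", "L8-L10", "L8-L10"]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bin_layers(pd.DataFrame({"zc_rescaled": [1.2]}))

    def test_zone_grouping(self):
        out = group_zone(bin_layers(pd.DataFrame({"zc_rescaled": [0.45, 0.55]})))
        assert list(out["layer"]) == ["L5", "L6"]
        assert list(out["zone"]) == ["central", "portal"]

    def test_zone_counts_equal_layer_sums(self, rng):
        out = group_zone(bin_layers(pd.DataFrame({"zc_rescaled": rng.uniform(0, 1, 200)})))
        k = out["layer"].str.lstrip("L").astype(int)
        assert (out["zone"] == "central").sum() == (k <= 5).sum()


class TestEndToEndRecovery:
    def test_spearman_against_truth(self):
        cfg = LobuleSimConfig(n_fragments=200, seed=21)
        exp, truth = simulate_lobule_experiment(cfg)
        panel = filter_landmarks(simulate_landmark_panel(cfg))
        pb = fragment_pseudobulk(exp, "LEC", min_cells=5)
        res = compute_zc(pb, panel)
        rho = sps.spearmanr(res["zc_rescaled"], truth.zc.loc[res.index]).statistic
        assert rho >= 0.9


class TestAssignProximity:
    def test_single_metastatic_cell_makes_proximal(self, toy_experiment):
        labels = assign_proximity(
            toy_experiment, min_cells_per_fragment=1, min_landmark_cells_per_sample=0
        )
        assert labels.loc["F3", "proximity"] == "proximal"
        assert labels.loc["F1", "proximity"] == "distal"

    def test_low_burden_sample_excluded(self, toy_experiment):
        labels = assign_proximity(
            toy_experiment, min_cells_per_fragment=1, min_landmark_cells_per_sample=20
        )
        assert len(labels) == 0  # S2 has 1 metastatic cell < 20; S1 has none

    def test_matches_set_membership_oracle(self):
        exp, truth = simulate_lobule_experiment(LobuleSimConfig(n_fragments=60, seed=22))
        labels = assign_proximity(exp, min_cells_per_fragment=5, min_landmark_cells_per_sample=0)
        cells = exp.cells
        for f in labels.index:
            has_met = ((cells["fragment"] == f) & (cells["cell_type"] == "metastatic")).any()
            assert (labels.loc[f, "proximity"] == "proximal") == has_met


class TestLandmarkClustering:
    def _planted_experiment(self, seed=30):
        specs = [
            ZonatedGeneSpec(f"NICHE_D{i}", "*", 0.0, 1.0) for i in range(10)
        ]
        cfg = LobuleSimConfig(n_fragments=60, seed=seed, zonated_genes=specs,
                              proximal_fraction=0.5)
        exp, truth = simulate_lobule_experiment(cfg)
        # plant a strong niche signature: distal genes shut down in proximal fragments
        prox_frags = set(truth.proximity.index[truth.proximity == "proximal"])
        dense = exp.counts.to_dense()
        gidx = exp.counts.gene_index()
        in_prox = exp.cells["fragment"].isin(prox_frags).to_numpy()
        for i in range(10):
            dense[gidx[f"NICHE_D{i}"], in_prox] = 0
        import scipy.sparse as sp

        exp.counts.counts = sp.csr_matrix(dense)
        return exp, truth

    def test_recovers_two_planted_niches(self):
        exp, truth = self._planted_experiment()
        genes = [f"NICHE_D{i}" for i in range(10)]
        labels = landmark_cluster_fragments(exp, genes, seed=0)
        joint = labels.join(truth.proximity)
        ari = adjusted_rand_score(joint["proximity"], joint["cluster"])
        assert labels["cluster"].nunique() == 2
        assert ari >= 0.9

    def test_identical_fragments_single_cluster(self, toy_experiment):
        import scipy.sparse as sp

        toy_experiment.counts.counts = sp.csr_matrix(np.ones((4, 6), dtype=int))
        labels = landmark_cluster_fragments(
            toy_experiment, ["g1", "g2"], min_cells=1, seed=0
        )
        assert labels["cluster"].nunique() == 1

    def test_seed_determinism(self):
        exp, _ = self._planted_experiment()
        genes = [f"NICHE_D{i}" for i in range(10)]
        a = landmark_cluster_fragments(exp, genes, seed=5)
        b = landmark_cluster_fragments(exp, genes, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestAllocateSpot:
    def test_threshold_rule(self):
        w = pd.DataFrame({"LEC": [0.8, 0.5], "KC": [0.2, 0.5]}, index=["s1", "s2"])
        labels = allocate_spot_celltype(w)
        assert labels.loc["s1"] == "LEC"
        assert labels.loc["s2"] == "mixed"

    def test_zero_threshold_is_argmax_with_tie_flag(self):
        w = pd.DataFrame({"LEC": [0.5], "KC": [0.5]}, index=["s1"])
        with pytest.warns(UserWarning, match="tied"):
            labels = allocate_spot_celltype(w, threshold=0.0)
        assert labels.loc["s1"] == "LEC"

    def test_bad_row_sum_rejected(self):
        w = pd.DataFrame({"LEC": [0.7], "KC": [0.2]})
        with pytest.raises(ValidationError):
            allocate_spot_celltype(w)
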