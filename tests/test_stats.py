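import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fragseq._glm import bh_adjust, fit_nb_batch
from fragseq.io import ValidationError
from fragseq.simulate import (
    LobuleSimConfig,
    ZonatedGeneSpec,
    simulate_lobule_experiment,
    simulate_null_pseudobulk,
)
from fragseq.stats import (
    abundance_test,
    compare_fragment_covariates,
    downsample_cells,
    filter_low_expression,
    twogroup_de,
    zonated_de,
)
from fragseq.zonation import assign_proximity, fragment_pseudobulk


class TestGLMBackend:
    def test_coefficients_match_statsmodels_oracle(self, rng):
        """The batched IRLS must agree with an independent GLM implementation."""
        import statsmodels.api as sm

        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        offset = rng.uniform(3, 4, n)
        mu = np.exp(X @ np.array([1.0, 0.5]) + offset)
        Y = rng.poisson(mu, size=(5, n)).astype(float)
        res = fit_nb_batch(Y, X, offset=offset)
        for g in range(5):
            alpha = res.alpha[g]
            if alpha > 0:
                fam = sm.families.NegativeBinomial(alpha=alpha)
            else:
                fam = sm.families.Poisson()
            fit = sm.GLM(Y[g], X, family=fam, offset=offset).fit()
            assert np.allclose(res.coef[g], fit.params, rtol=1e-4, atol=1e-5)
            assert np.allclose(res.se[g], fit.bse, rtol=1e-3, atol=1e-5)

    def test_bh_matches_sort_based_oracle(self, rng):
        p = rng.uniform(size=200)

        def oracle(pvals):
            m = len(pvals)
            order = np.argsort(pvals)
            adj = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                val = min(prev, pvals[i] * m / rank)
                adj[i] = val
                prev = val
            return adj

        assert np.allclose(bh_adjust(p), np.maximum(oracle(p), p))

    def test_bh_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=50) ** 3
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)


class TestZonatedDE:
    def test_constant_gene_not_significant(self):
        pb, layers, samples = simulate_null_pseudobulk(60, 5, seed=1)
        pb["const"] = 50
        de = zonated_de(pb, layers, samples)
        assert abs(de.loc["const", "coef"]) < 0.05
        assert de.loc["const", "p"] > 0.05

    def test_null_type_one_error_calibrated(self):
        fracs = []
        for rep in range(5):
            pb, layers, samples = simulate_null_pseudobulk(120, 1000, seed=50 + rep)
            de = zonated_de(pb, layers, samples)
            fracs.append((de["p"] < 0.05).mean())
        assert 0.03 < np.mean(fracs) < 0.07

    def test_planted_slope_detected_with_positive_sign(self):
        from fragseq.zonation import bin_layers, compute_zc, filter_landmarks
        from fragseq.simulate import simulate_landmark_panel

        cfg = LobuleSimConfig(
            n_fragments=200, seed=60,
            zonated_genes=[ZonatedGeneSpec("ZON1", "LEC", 1.0, 5.0)],
        )
        exp, truth = simulate_lobule_experiment(cfg)
        panel = filter_landmarks(simulate_landmark_panel(cfg))
        pb_mean = fragment_pseudobulk(exp, "LEC", min_cells=5)
        z = bin_layers(compute_zc(pb_mean, panel))
        pb = fragment_pseudobulk(exp, "LEC", min_cells=5, mode="sum")
        shared = pb.index.intersection(z.index)
        de = zonated_de(
            filter_low_expression(pb.loc[shared]),
            z.loc[shared, "layer_merged"].astype(str),
            exp.fragments.loc[shared, "sample"],
        )
        assert de.loc["ZON1", "fdr"] < 0.05
        assert de.loc["ZON1", "coef"] > 0

    def test_single_layer_is_design_error(self):
        pb, layers, samples = simulate_null_pseudobulk(20, 5, seed=2)
        with pytest.raises(ValidationError):
            zonated_de(pb, pd.Series("L4", index=pb.index), samples)

    def test_non_integer_counts_rejected(self):
        pb, layers, samples = simulate_null_pseudobulk(20, 5, seed=3)
        with pytest.raises(ValidationError):
            zonated_de(pb + 0.5, layers, samples)


class TestTwoGroupDE:
    @staticmethod
    def _null(seed, n=60, genes=300):
        pb, _, samples = simulate_null_pseudobulk(n, genes, seed=seed)
        rng = np.random.default_rng(seed)
        groups = pd.Series(
            rng.permutation(np.r_[["a"] * (n // 2), ["b"] * (n - n // 2)]), index=pb.index
        )
        return pb, groups, samples

    def test_null_p_values_uniform(self):
        pb, groups, samples = self._null(70, n=80, genes=1000)
        de = twogroup_de(pb, groups, samples)
        ks = sps.kstest(de["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_fold_change_detected_with_sign(self):
        pb, groups, samples = self._null(71)
        target = pb.columns[0]
        pb.loc[groups == "b", target] *= 4  # planted 4-fold increase in group b
        de = twogroup_de(pb, groups, samples)
        assert de.loc[target, "fdr"] < 0.05
        assert de.loc[target, "coef"] == pytest.approx(np.log(4), abs=0.4)

    def test_group_swap_negates_coefficients(self):
        pb, groups, samples = self._null(72, n=30, genes=20)
        de_ab = twogroup_de(pb, groups, samples, group_order=("a", "b"))
        de_ba = twogroup_de(pb, groups, samples, group_order=("b", "a"))
        assert np.allclose(de_ab["coef"], -de_ba["coef"], atol=1e-6)

    def test_empty_group_is_design_error(self):
        pb, groups, samples = self._null(73, n=20, genes=5)
        with pytest.raises(ValidationError):
            twogroup_de(pb, groups, samples, group_order=("a", "missing"))


class TestAbundance:
    def test_equal_compositions_not_significant(self):
        rng = np.random.default_rng(80)
        rows = []
        for s in range(4):
            for g in ("distal", "proximal"):
                for t in ("LEC", "KC", "T"):
                    rows += [
                        {"sample": f"S{s}", "group": g, "cell_type": t, "fragment": f"F{s}{g}"}
                    ] * int(rng.poisson(100))
        cells = pd.DataFrame(rows)
        cells.index = [f"c{i}" for i in range(len(cells))]
        groups = cells.groupby("fragment")["group"].first()
        res = abundance_test(cells, groups)
        assert (res["fdr"] > 0.05).all()

    def test_planted_shift_detected_with_direction(self):
        exp, truth = simulate_lobule_experiment(LobuleSimConfig(n_fragments=200, seed=81))
        prox = assign_proximity(exp, min_landmark_cells_per_sample=0)
        res = abundance_test(exp.cells, prox["proximity"], group_order=("distal", "proximal"))
        assert res.loc["mac_mono", "coef"] > 0 and res.loc["mac_mono", "fdr"] < 0.05
        assert res.loc["metastatic", "coef"] > 0
        assert res.loc["KC", "coef"] < 0 and res.loc["LEC", "coef"] < 0

    def test_total_count_scaling_invariance(self):
        exp, _ = simulate_lobule_experiment(LobuleSimConfig(n_fragments=120, seed=82))
        prox = assign_proximity(exp, min_landmark_cells_per_sample=0)
        base = abundance_test(exp.cells, prox["proximity"])
        # triple every S1 unit by replicating its cells: CPM normalization
        # keeps per-type composition identical, so coefficients barely move
        s1 = exp.cells[exp.cells["sample"] == "S1"]
        extra = pd.concat([s1, s1], ignore_index=False)
        extra.index = [f"dup{i}" for i in range(len(extra))]
        cells2 = pd.concat([exp.cells, extra])
        doubled = abundance_test(cells2, prox["proximity"])
        # the normalized log abundances are exactly invariant...
        pd.testing.assert_frame_equal(base.attrs["log_cpm"], doubled.attrs["log_cpm"])
        # ...and significance calls and effect directions do not change
        assert (np.sign(base["coef"]) == np.sign(doubled["coef"])).all()
        assert ((base["fdr"] < 0.05) == (doubled["fdr"] < 0.05)).all()


class TestCovariateComparison:
    def test_identical_groups_not_significant(self):
        table = pd.DataFrame(
            {"size": np.r_[np.arange(10.0), np.arange(10.0)], "n_cells": 5},
            index=[f"F{i}" for i in range(20)],
        )
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=table.index)
        res = compare_fragment_covariates(table, groups, covariates=("size",))
        assert res.loc["size", "p"] >= 0.95

    def test_disjoint_supports_reach_minimal_p(self):
        table = pd.DataFrame(
            {"size": np.r_[np.arange(4.0), 100 + np.arange(4.0)]},
            index=[f"F{i}" for i in range(8)],
        )
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=table.index)
        res = compare_fragment_covariates(table, groups, covariates=("size",))
        # exact two-sided rank-sum minimum at n=4+4 is 2/C(8,4) = 1/35
        assert res.loc["size", "p"] == pytest.approx(2 / 70, rel=1e-6)

    def test_matches_scipy_on_random_data(self, rng):
        table = pd.DataFrame({"size": rng.normal(300, 50, 30)}, index=[f"F{i}" for i in range(30)])
        groups = pd.Series(["a"] * 15 + ["b"] * 15, index=table.index)
        res = compare_fragment_covariates(table, groups, covariates=("size",))
        ref = sps.mannwhitneyu(
            table["size"][:15], table["size"][15:], alternative="two-sided"
        )
        assert res.loc["size", "p"] == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        table = pd.DataFrame({"size": [1.0, 2.0]}, index=["F1", "F2"])
        groups = pd.Series(["a", "a"], index=table.index)
        with pytest.raises(ValidationError):
            compare_fragment_covariates(table, groups, covariates=("size",))


class TestDownsample:
    def test_identity_at_full_size(self, toy_experiment):
        out = downsample_cells(toy_experiment, len(toy_experiment.cells), seed=0)
        assert list(out.cells.index) == list(toy_experiment.cells.index)

    def test_empty_at_zero(self, toy_experiment):
        out = downsample_cells(toy_experiment, 0, seed=0)
        assert len(out.cells) == 0
        assert (out.fragments["n_cells"] == 0).all()

    def test_oversampling_rejected(self, toy_experiment):
        with pytest.raises(ValidationError):
            downsample_cells(toy_experiment, 100, seed=0)

    def test_composition_within_hypergeometric_ci(self):
        exp, _ = simulate_lobule_experiment(LobuleSimConfig(n_fragments=80, seed=90))
        n, k = len(exp.cells), len(exp.cells) // 2
        out = downsample_cells(exp, k, seed=1)
        for t, p0 in exp.cells["cell_type"].value_counts(normalize=True).items():
            p1 = (out.cells["cell_type"] == t).mean()
            se = np.sqrt(p0 * (1 - p0) / k)
            assert abs(p1 - p0) < 5 * se + 1e-9

    def test_seed_reproducible(self, toy_experiment):
        a = downsample_cells(toy_experiment, 3, seed=7)
        b = downsample_cells(toy_experiment, 3, seed=7)
        assert list(a.cells.index) == list(b.cells.index)


class TestFilterLowExpression:
    def test_all_zero_gene_removed(self):
        pb = pd.DataFrame({"dead": [0, 0, 0, 0], "ok": [20, 20, 20, 20]})
        out = filter_low_expression(pb)
        assert list(out.columns) == ["ok"]

    def test_boundary_gene_kept(self):
        pb = pd.DataFrame({"edge": [10] * 10})
        assert "edge" in filter_low_expression(pb).columns

    def test_matches_naive_predicate_oracle(self, rng):
        pb = pd.DataFrame(
            rng.poisson(6, size=(30, 50)), columns=[f"g{i}" for i in range(50)]
        )
        groups = pd.Series(["a"] * 10 + ["b"] * 20, index=pb.index)
        out = filter_low_expression(pb, groups, min_count=10, min_prop=0.7)
        smallest = 10
        n_req = int(np.ceil(0.7 * smallest))
        for g in pb.columns:
            expected = (pb[g] >= 10).sum() >= n_req
            assert (g in out.columns) == expected
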