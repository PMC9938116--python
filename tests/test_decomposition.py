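import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import rel_entr

from mefkit.data_io import AbundanceTable, PlotMetadata, TraitTable, align_dataset
from mefkit.decomposition import (COMPONENTS, ModelFitSet,
                                  build_metacommunity_prior, decompose,
                                  decompose_dataset, four_step, r2_kl,
                                  rarefy_bootstrap, summarize_by_forest_type)
from mefkit.synth import ScenarioConfig, generate_scenario


def kl(a, b):
    return rel_entr(np.asarray(a), np.asarray(b)).sum()


class TestR2KL:
    def test_perfect_prediction_gives_one(self):
        o = np.array([0.7, 0.2, 0.1])
        assert r2_kl(o, o) == pytest.approx(1.0, abs=1e-15)

    def test_uniform_prediction_gives_zero(self):
        o = np.array([0.7, 0.2, 0.1])
        u = np.full(3, 1 / 3)
        assert r2_kl(o, u, u) == pytest.approx(0.0, abs=1e-15)

    def test_three_genus_hand_example(self):
        # independent arithmetic: D(o||p) and D(o||u) computed term by term
        o = np.array([0.7, 0.2, 0.1])
        p = np.array([0.5, 0.3, 0.2])
        d_op = (0.7 * np.log(0.7 / 0.5) + 0.2 * np.log(0.2 / 0.3)
                + 0.1 * np.log(0.1 / 0.2))
        d_ou = (0.7 * np.log(2.1) + 0.2 * np.log(0.6) + 0.1 * np.log(0.3))
        assert d_op == pytest.approx(0.0851228259, abs=1e-9)
        assert d_ou == pytest.approx(0.2967937361, abs=1e-9)
        assert r2_kl(o, p) == pytest.approx(1 - d_op / d_ou, abs=1e-12)

    def test_zero_observed_cells_contribute_nothing(self):
        o = np.array([0.5, 0.5, 0.0])
        p = np.array([0.4, 0.4, 0.2])
        expected = 1 - kl(o, p) / kl(o, np.full(3, 1 / 3))
        assert r2_kl(o, p) == pytest.approx(expected, abs=1e-12)

    def test_uniform_observed_flagged_undefined(self):
        o = np.full(4, 0.25)
        assert np.isnan(r2_kl(o, np.array([0.4, 0.3, 0.2, 0.1])))

    def test_never_exceeds_one(self, rng):
        for _ in range(200):
            o = rng.dirichlet(np.ones(5))
            p = rng.dirichlet(np.ones(5))
            assert r2_kl(o, p) <= 1.0 + 1e-12


class TestMetacommunityPrior:
    def test_single_plot_pool_equals_its_relative_abundances(self, tiny_abundance):
        prior = build_metacommunity_prior(tiny_abundance, ["p1"], focal="p1")
        assert np.allclose(prior.q.to_numpy(), [0.5, 0.0, 0.5])

    def test_two_plots_pooled(self):
        abund = AbundanceTable(pd.DataFrame([[1, 0], [0, 1]],
                                            index=["p1", "p2"],
                                            columns=["a", "b"]))
        prior = build_metacommunity_prior(abund, ["p1", "p2"], focal="p1",
                                          epsilon=0.0)
        assert np.allclose(prior.q.to_numpy(), [0.5, 0.5])

    def test_exclude_focal_pseudocounts_unique_genus(self):
        abund = AbundanceTable(pd.DataFrame([[5, 5], [10, 0]],
                                            index=["p1", "p2"],
                                            columns=["a", "b"]))
        prior = build_metacommunity_prior(abund, ["p1", "p2"], focal="p1",
                                          epsilon=1e-6, exclude_focal=True)
        # genus b only in the focal plot: epsilon mass before renormalization
        assert prior.q["b"] == pytest.approx(1e-6 / (1 + 1e-6))
        assert prior.q.sum() == pytest.approx(1.0)


class TestDecompose:
    def test_all_zero_fits(self):
        dec = decompose(ModelFitSet("p", 0.0, 0.0, 0.0, 0.0, 1))
        assert dec.pure_trait == 0 and dec.pure_metacommunity == 0
        assert dec.joint == 0 and dec.bias == 0 and dec.unexplained == 1.0

    def test_illustrative_values(self):
        dec = decompose(ModelFitSet("p", r2_bias_uniform=0.05, r2_trait=0.23,
                                    r2_meta=0.56, r2_hybrid=0.60,
                                    n_permutations=50))
        assert dec.pure_trait == pytest.approx(0.04)
        assert dec.pure_metacommunity == pytest.approx(0.37)
        assert dec.joint == pytest.approx(0.14)
        assert dec.unexplained == pytest.approx(0.40)
        total = (dec.pure_trait + dec.pure_metacommunity + dec.joint
                 + dec.bias + dec.unexplained)
        assert total == pytest.approx(1.0, abs=1e-12)

    @given(st.lists(st.floats(-1.0, 1.0), min_size=4, max_size=4))
    @settings(max_examples=1000, deadline=None)
    def test_additivity_identity(self, r2s):
        bias, trait, meta, hybrid = r2s
        dec = decompose(ModelFitSet("p", bias, trait, meta, hybrid, 1))
        total = (dec.pure_trait + dec.pure_metacommunity + dec.joint
                 + dec.bias + dec.unexplained)
        assert total == pytest.approx(1.0, abs=1e-9)


@pytest.fixture(scope="module")
def small_scenario():
    cfg = ScenarioConfig(name="test", n_genera=40, n_plots=12,
                         individuals_per_plot=200, n_continuous_traits=2,
                         n_binary_traits=1, seed=7)
    return generate_scenario(cfg)


class TestFourStep:
    def test_single_genus_plot_degenerate(self, tiny_traits, tiny_metadata):
        abund = AbundanceTable(pd.DataFrame([[9, 0, 0], [1, 1, 1]],
                                            index=["p1", "p2"],
                                            columns=["ga", "gb", "gc"]))
        ds = align_dataset(abund, tiny_traits, tiny_metadata)
        prior = build_metacommunity_prior(ds.abundance, list(ds.plot_ids), "p1")
        fits = four_step(ds, "p1", prior, n_perm=3, seed=0)
        assert fits.degenerate
        assert fits.r2_trait == 1.0 and fits.r2_hybrid == 1.0

    def test_prior_equal_to_composition_predicts_perfectly(self, small_scenario):
        ds, _ = small_scenario
        plot = ds.plot_ids[0]
        from mefkit.maxent import Prior
        from mefkit.traits import relative_abundances
        o = relative_abundances(ds.abundance).loc[plot]
        prior = Prior(o / o.sum())
        fits = four_step(ds, plot, prior, n_perm=3, seed=0)
        # permuted constraints cannot pull the prediction off a perfect prior
        assert fits.r2_meta == pytest.approx(1.0, abs=0.05)
        assert fits.r2_hybrid == pytest.approx(1.0, abs=1e-6)

    def test_permutation_seeds_shared_between_arms(self, small_scenario):
        ds, _ = small_scenario
        plot = ds.plot_ids[1]
        prior = build_metacommunity_prior(ds.abundance, list(ds.plot_ids), plot)
        a = four_step(ds, plot, prior, n_perm=4, seed=11)
        b = four_step(ds, plot, prior, n_perm=4, seed=11)
        assert a.r2_bias_uniform == b.r2_bias_uniform
        assert a.r2_meta == b.r2_meta


class TestDatasetDecomposition:
    def test_components_sum_to_one(self, small_scenario):
        ds, _ = small_scenario
        table, _ = decompose_dataset(ds, n_perm=3, seed=5)
        total = table[list(COMPONENTS)].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_forest_type_scope_restricts_pool(self, small_scenario):
        ds, _ = small_scenario
        table, _ = decompose_dataset(ds, n_perm=2, seed=5,
                                     prior_scope="forest-type")
        assert len(table) == len(ds.plot_ids)


class TestRarefyBootstrap:
    def _decomp_frame(self, n_per_group=(5, 5), seed=0):
        g = np.random.default_rng(seed)
        rows, ft = [], {}
        for gi, n in enumerate(n_per_group):
            for i in range(n):
                pid = f"t{gi}_p{i}"
                rows.append(pd.Series(
                    g.dirichlet(np.ones(5)), index=COMPONENTS, name=pid))
                ft[pid] = f"FT{gi + 1}"
        table = pd.DataFrame(rows)
        meta = PlotMetadata(pd.DataFrame({
            "latitude": 0.0, "longitude": 0.0,
            "forest_type": pd.Series(ft), "area_ha": 1.0}))
        return table, meta

    def test_group_of_exact_size_has_zero_between_rep_variance(self):
        table, meta = self._decomp_frame((4, 6))
        out = rarefy_bootstrap(table, meta, n_plots=4, reps=5, seed=1)
        ft1 = out[out["forest_type"] == "FT1"]
        assert ft1["pure_trait"].std() == pytest.approx(0.0, abs=1e-15)

    def test_fixed_seed_reproducible(self):
        table, meta = self._decomp_frame((6, 6))
        a = rarefy_bootstrap(table, meta, n_plots=4, reps=5, seed=3)
        b = rarefy_bootstrap(table, meta, n_plots=4, reps=5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_too_small_group_names_it(self):
        table, meta = self._decomp_frame((3, 8))
        with pytest.raises(ValueError, match="FT1"):
            rarefy_bootstrap(table, meta, n_plots=4, reps=3, seed=0)

    def test_rarefied_means_near_full_means(self):
        table, meta = self._decomp_frame((30, 30), seed=4)
        out = rarefy_bootstrap(table, meta, n_plots=20, reps=25, seed=2)
        for ft in ("FT1", "FT2"):
            full = table.loc[meta.table["forest_type"] == ft, "pure_trait"].mean()
            reps = out.loc[out["forest_type"] == ft, "pure_trait"]
            lo, hi = reps.quantile([0.01, 0.99])
            assert lo - 0.05 <= full <= hi + 0.05


class TestForestTypeSummary:
    def test_single_plot_per_type_mean_is_value(self):
        g = np.random.default_rng(0)
        table = pd.DataFrame([g.dirichlet(np.ones(5)) for _ in range(2)],
                             index=["p1", "p2"], columns=COMPONENTS)
        meta = PlotMetadata(pd.DataFrame({
            "latitude": [0.0, 0.0], "longitude": [0.0, 0.0],
            "forest_type": ["A", "B"], "area_ha": [1.0, 1.0]},
            index=["p1", "p2"]))
        out = summarize_by_forest_type(table, meta)
        row = out[(out["forest_type"] == "A") & (out["component"] == "pure_trait")]
        assert row["mean"].iloc[0] == pytest.approx(table.loc["p1", "pure_trait"])
        assert row["q25"].iloc[0] == row["q75"].iloc[0]
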