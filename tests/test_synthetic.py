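import numpy as np
import pandas as pd
import pytest

from responseguilds.dynamics import interannual_changes, standardize
from responseguilds.phylo import patristic_matrix
from responseguilds.synthetic import (
    CommunityConfig,
    apply_missingness,
    integrate_to_abundance,
    simulate_changes,
    simulate_community,
    simulate_traits,
    simulate_trees,
    simulate_true_tree,
)
from responseguilds.dynamics import ChangeMatrix


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_guilds": 10, "n_species": 5},
            {"n_years": 2},
            {"within_guild_rho": 1.5},
            {"density_dependence_phi": 1.0},
            {"heritability_mode": "nope"},
            {"scenario": "nope"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CommunityConfig(**kwargs)


class TestSimulateChanges:
    def test_rho_one_same_guild_perfect_correlation(self):
        config = CommunityConfig(
            n_species=4, n_years=30, n_guilds=2, within_guild_rho=1.0, seed=0
        )
        changes, truth = simulate_changes(config)
        g = truth.guild_of
        same = [s for s in g.index if g[s] == 1]
        r = np.corrcoef(changes.data.loc[same[0]], changes.data.loc[same[1]])
        assert r[0, 1] == pytest.approx(1.0)

    def test_rho_zero_independent(self):
        config = CommunityConfig(
            n_species=10, n_years=2001, n_guilds=2, within_guild_rho=0.0,
            seed=1,
        )
        changes, _ = simulate_changes(config)
        r = np.corrcoef(changes.data.to_numpy())
        off = r[~np.eye(10, dtype=bool)]
        assert np.abs(off).mean() < 0.05

    def test_sample_correlation_concentrates_at_rho(self):
        # Monte-Carlo against the closed-form expectation: two same-guild
        # species at rho=0.8 over 400 years stay within +-0.05 nearly always
        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            config = CommunityConfig(
                n_species=2, n_years=401, n_guilds=1, within_guild_rho=0.8,
                seed=seed,
            )
            changes, _ = simulate_changes(config)
            r = np.corrcoef(changes.data.to_numpy())[0, 1]
            hits += abs(r - 0.8) <= 0.05
        assert hits / n_rep >= 0.95

    def test_deterministic_given_seed(self):
        c = CommunityConfig(n_species=6, n_years=10, seed=5, n_guilds=2)
        a, _ = simulate_changes(c)
        b, _ = simulate_changes(c)
        pd.testing.assert_frame_equal(a.data, b.data)
        other, _ = simulate_changes(
            CommunityConfig(n_species=6, n_years=10, seed=6, n_guilds=2)
        )
        assert not a.data.equals(other.data)

    def test_brownian_loadings_unit_norm(self):
        config = CommunityConfig(
            n_species=12, n_years=20, n_guilds=3,
            heritability_mode="brownian_loadings", seed=2,
        )
        _, truth = simulate_changes(config)
        norms = np.linalg.norm(truth.loadings.to_numpy(), axis=1)
        np.testing.assert_allclose(norms, 1.0)

    def test_brownian_close_relatives_more_correlated(self):
        # phylogenetically close pairs should show stochastically larger
        # change correlations (heritable responses)
        rs, ds = [], []
        for seed in range(10):
            config = CommunityConfig(
                n_species=16, n_years=201, n_guilds=4,
                heritability_mode="brownian_loadings", seed=seed,
            )
            changes, truth = simulate_changes(config)
            corr = np.corrcoef(changes.data.to_numpy())
            pat = patristic_matrix(truth.true_tree)
            pat = pat.loc[changes.species, changes.species].to_numpy()
            iu = np.tril_indices(16, k=-1)
            rs.extend(corr[iu])
            ds.extend(pat[iu])
        assert np.corrcoef(rs, ds)[0, 1] < -0.2


class TestIntegration:
    def test_phi_zero_is_cumulative_sum(self):
        ch = ChangeMatrix(pd.DataFrame(
            [[0.5, -0.3], [1.0, 1.0]], index=["Alpha one", "Beta two"],
            columns=[2001, 2002],
        ))
        am = integrate_to_abundance(ch, phi=0.0)
        assert list(am.data.loc["Alpha one"]) == pytest.approx([0, 0.5, 0.2])
        assert am.years == [2000, 2001, 2002]

    def test_differencing_inverts_integration(self):
        rng = np.random.default_rng(3)
        ch = ChangeMatrix(pd.DataFrame(
            rng.normal(size=(3, 12)),
            index=["Alpha one", "Beta two", "Gamma three"],
            columns=range(2001, 2013),
        ))
        am = integrate_to_abundance(ch, phi=0.0)
        back = interannual_changes(am)
        pd.testing.assert_frame_equal(back.data, ch.data, check_names=False)

    def test_zero_changes_stay_zero(self):
        ch = ChangeMatrix(pd.DataFrame(
            np.zeros((2, 5)), index=["Alpha one", "Beta two"],
            columns=range(2001, 2006),
        ))
        am = integrate_to_abundance(ch, phi=0.5)
        assert (am.data.to_numpy() == 0).all()


class TestMissingness:
    def test_rate_and_protected_observations(self):
        config = CommunityConfig(n_species=20, n_years=40, seed=4,
                                 missing_fraction=0.0)
        changes, _ = simulate_changes(config)
        am = integrate_to_abundance(changes, phi=0.0)
        holey = apply_missingness(am, fraction=0.1, seed=5)
        n_missing = int(holey.missing.sum().sum())
        assert n_missing == round(0.1 * 20 * 40)
        # first two observations of every species survive
        assert holey.data.iloc[:, :2].notna().all().all()


class TestTrees:
    def test_zero_noise_identical_trees(self):
        true = simulate_true_tree(6, seed=6)
        ts = simulate_trees(true, n_trees=5, tree_noise=0.0, seed=7)
        m0 = patristic_matrix(ts.trees[0])
        for t in ts.trees[1:]:
            pd.testing.assert_frame_equal(patristic_matrix(t), m0)
        pd.testing.assert_frame_equal(
            m0, patristic_matrix(true).loc[m0.index, m0.columns]
        )

    def test_singleton_set(self):
        true = simulate_true_tree(4, seed=8)
        assert len(simulate_trees(true, 1, 0.2, seed=9)) == 1

    def test_height_rescaled_to_one(self):
        true = simulate_true_tree(10, seed=10)
        depths = [leaf.distance_from_root()
                  for leaf in true.leaf_node_iter()]
        assert max(depths) == pytest.approx(1.0)


class TestTraits:
    def test_counts_positive_integers_and_topn_survey(self):
        config = CommunityConfig(seed=11)
        _, truth = simulate_changes(config)
        t = simulate_traits(truth, config, seed=12)
        assert (t.traits["O"] >= 1).all()
        assert (t.traits["O"] == t.traits["O"].round()).all()
        assert int(t.traits["Y"].notna().sum()) == 18
        assert set(t.families) == {"Brassicaceae", "Caryophyllaceae"}

    def test_clustered_scenario_concentrates_function_in_guild_one(self):
        config = CommunityConfig(seed=13, scenario="clustered")
        _, truth = simulate_changes(config)
        t = simulate_traits(truth, config, seed=14)
        oa = t.traits["O"] * t.traits["A"]
        elite = truth.guild_of == 1
        assert oa[elite].median() > 10 * oa[~elite].median()


class TestCommunityBundle:
    def test_shapes_and_determinism(self):
        config = CommunityConfig(n_species=15, n_years=20, n_guilds=3,
                                 n_trees=4, seed=15)
        a = simulate_community(config)
        b = simulate_community(config)
        assert a.abundance.data.shape == (15, 20)
        assert len(a.trees) == 4
        pd.testing.assert_frame_equal(a.abundance.data, b.abundance.data)
        pd.testing.assert_frame_equal(a.traits.traits, b.traits.traits)
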