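import numpy as np
import pandas as pd
import pytest

from responseguilds.data_io import AbundanceMatrix
from responseguilds.dynamics import (
    ChangeMatrix,
    correlation_matrix,
    dynamics_distance,
    interannual_changes,
    standardize,
    to_distance,
)


def make_abund(values: dict[str, list[float]], start_year=2000):
    n = len(next(iter(values.values())))
    years = list(range(start_year, start_year + n))
    return AbundanceMatrix(pd.DataFrame(values, index=years).T)


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        am = make_abund({"Alpha one": [1, 2, 3], "Beta two": [5, 1, 3]})
        z = standardize(am)
        for sp in z.species:
            s = z.data.loc[sp].dropna()
            assert s.mean() == pytest.approx(0, abs=1e-12)
            assert s.std(ddof=1) == pytest.approx(1)

    def test_idempotent(self):
        am = make_abund({"Alpha one": [1.0, 2, 3, 7], "Beta two": [5.0, 1, 3, 2]})
        once = standardize(am)
        twice = standardize(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_constant_series_excluded_with_warning(self):
        am = make_abund(
            {"Alpha one": [1, 2, 3], "Beta two": [2, 2, 2], "Gamma th": [0, 1, 5]}
        )
        with pytest.warns(UserWarning, match="Beta two"):
            z = standardize(am)
        assert "Beta two" not in z.species


class TestInterannualChanges:
    def test_simple_differences(self):
        am = make_abund({"Alpha one": [0.0, 0.5, 0.2], "Beta two": [1.0, 0, 1]})
        ch = interannual_changes(am)
        assert list(ch.data.loc["Alpha one"]) == pytest.approx([0.5, -0.3])

    def test_missing_year_blanks_two_changes(self):
        am = make_abund(
            {"Alpha one": [0.0, 1, np.nan, 2, 3, 1],
             "Beta two": [1.0, 0, 1, 2, 0, 2]},
            start_year=1979,
        )
        ch = interannual_changes(am)
        assert np.isnan(ch.data.loc["Alpha one", 1981])
        assert np.isnan(ch.data.loc["Alpha one", 1982])
        assert ch.data.loc["Alpha one"].notna().sum() == 3

    def test_year_labels_shift(self):
        am = make_abund(
            {"Alpha one": list(range(39)), "Beta two": list(np.sin(range(39)))},
            start_year=1976,
        )
        ch = interannual_changes(am)
        assert ch.change_years == list(range(1977, 2015))
        assert len(ch.change_years) == 38


class TestCorrelationMatrix:
    def test_duplicate_and_negated_series(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        ch = ChangeMatrix(pd.DataFrame(
            [x, x, -x], index=["Alpha one", "Beta two", "Gamma three"],
            columns=range(2000, 2020),
        ))
        r, n = correlation_matrix(ch, min_pairs=3)
        assert r.loc["Alpha one", "Beta two"] == pytest.approx(1)
        assert r.loc["Alpha one", "Gamma three"] == pytest.approx(-1)
        assert (n.loc["Alpha one"] == 20).all()

    def test_complete_pairs_match_handmade_oracle(self):
        # interleaved missingness: brute-force Pearson over the explicit
        # overlap must match
        x = np.array([1.0, np.nan, 2, 3, np.nan, 5, 1, 4, 2, 6])
        y = np.array([2.0, 1, np.nan, 4, 2, 6, 2, np.nan, 1, 5])
        ch = ChangeMatrix(pd.DataFrame(
            [x, y], index=["Alpha one", "Beta two"], columns=range(2000, 2010)
        ))
        r, n = correlation_matrix(ch, min_pairs=3)
        both = ~np.isnan(x) & ~np.isnan(y)
        xa, ya = x[both] - x[both].mean(), y[both] - y[both].mean()
        expected = (xa @ ya) / np.sqrt((xa @ xa) * (ya @ ya))
        assert r.loc["Alpha one", "Beta two"] == pytest.approx(expected)
        assert n.loc["Alpha one", "Beta two"] == int(both.sum())

    def test_no_missing_equals_full_sample_pearson(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(6, 25))
        ch = ChangeMatrix(pd.DataFrame(
            vals, index=[f"Sp s{i}" for i in range(6)], columns=range(25)
        ))
        r, _ = correlation_matrix(ch, min_pairs=3)
        expected = np.corrcoef(vals)
        np.testing.assert_allclose(r.to_numpy(), expected, atol=1e-12)

    def test_pairs_below_min_pairs_flagged_not_fabricated(self):
        x = np.array([1.0, 2, np.nan, np.nan, np.nan, np.nan])
        y = np.array([np.nan, np.nan, 1.0, 2, 3, 1])
        z = np.arange(6, dtype=float)
        ch = ChangeMatrix(pd.DataFrame(
            [x, y, z], index=["Alpha one", "Beta two", "Gamma three"],
            columns=range(2000, 2006),
        ))
        with pytest.warns(UserWarning, match="fewer than"):
            r, n = correlation_matrix(ch, min_pairs=3)
        assert np.isnan(r.loc["Alpha one", "Beta two"])
        assert n.loc["Alpha one", "Beta two"] == 0


class TestToDistance:
    def test_linear_map_endpoints(self):
        r = pd.DataFrame(
            [[1.0, 1.0, 0.0, -1.0],
             [1.0, 1.0, 0.81, 0.5],
             [0.0, 0.81, 1.0, 0.2],
             [-1.0, 0.5, 0.2, 1.0]],
            index=list("ABCD"), columns=list("ABCD"),
        )
        d = to_distance(r).d
        assert d.loc["A", "B"] == 0.0   # r=1 -> perfectly synchronous
        assert d.loc["A", "C"] == 1.0   # r=0 -> no correlation
        assert d.loc["A", "D"] == 2.0   # r=-1 -> opposite dynamics
        assert d.loc["B", "C"] == pytest.approx(0.19)  # r=0.81

    def test_out_of_range_correlation_rejected(self):
        r = pd.DataFrame([[1.0, 1.5], [1.5, 1.0]], index=["A", "B"],
                         columns=["A", "B"])
        with pytest.raises(ValueError, match="outside"):
            to_distance(r)

    def test_range_on_random_inputs(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(-1, 1, size=(8, 8))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        r = pd.DataFrame(vals, index=[f"S s{i}" for i in range(8)],
                         columns=[f"S s{i}" for i in range(8)])
        d = to_distance(r).d.to_numpy()
        assert d.min() >= 0 and d.max() <= 2
        assert np.diag(d).sum() == 0


class TestEndToEnd:
    def test_within_guild_closer_than_between(self, small_community):
        ddm = dynamics_distance(small_community.abundance, min_pairs=5)
        guilds = small_community.truth.guild_of
        d = ddm.d
        within, between = [], []
        for i, si in enumerate(d.index):
            for sj in d.index[i + 1:]:
                (within if guilds[si] == guilds[sj] else between).append(
                    d.loc[si, sj]
                )
        assert np.mean(within) < np.mean(between)

    def test_undefined_pairs_block_clustering(self):
        x = np.concatenate([np.arange(8.0), np.full(8, np.nan)])
        y = np.concatenate([np.full(8, np.nan), np.arange(8.0)])
        z = np.sin(np.arange(16.0))
        w = np.cos(np.arange(16.0))
        am = AbundanceMatrix(pd.DataFrame(
            [x, y, z, w],
            index=["Alpha one", "Beta two", "Gamma three", "Delta four"],
            columns=range(2000, 2016),
        ))
        with pytest.warns(UserWarning):
            ddm = dynamics_distance(am, min_pairs=5)
        with pytest.raises(ValueError, match="undefined pairs"):
            ddm.require_complete()
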