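"""Trait-climate association and Mantel permutation machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from conftest import random_symmetric_distance

from clonetrial.env_stats import (
    env_change_matrix,
    mantel_test,
    simple_regression,
    site_year_trait_means,
    spearman_matrix,
    typeb_distance_matrix,
)
from clonetrial.synthetic_trial import default_climate_profiles, simulate_climate


def _climate(sites=("A", "B", "C"), years=(2010, 2011), seed=0):
    profiles = {s: default_climate_profiles()["LY"] for s in sites}
    return simulate_climate(list(sites), list(years), profiles, seed=seed)


def _trait_frame(pairs):
    # pairs: list of (site, year, value) for one trait
    return pd.DataFrame(
        [{"site": s, "year": y, "trait": "height", "value": v} for s, y, v in pairs]
    )


class TestSpearman:
    def _run(self, values, variable="MAT"):
        clim = _climate(sites=("A",), years=range(2010, 2010 + len(values)))
        clim = clim.sort_values("year").reset_index(drop=True)
        tv = _trait_frame(
            [("A", y, v) for y, v in zip(clim["year"], values)]
        )
        out = spearman_matrix(tv, clim, variables=[variable])
        return out.iloc[0]

    def test_monotone_increasing_is_plus_one(self):
        clim = _climate(sites=("A",), years=range(2010, 2016))
        order = clim.sort_values("MAT")
        tv = _trait_frame(
            [("A", y, rank) for rank, y in enumerate(order["year"], 1)]
        )
        row = spearman_matrix(tv, clim, variables=["MAT"]).iloc[0]
        assert row["rho"] == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        clim = _climate(sites=("A",), years=range(2010, 2016))
        order = clim.sort_values("MAT", ascending=False)
        tv = _trait_frame(
            [("A", y, rank) for rank, y in enumerate(order["year"], 1)]
        )
        row = spearman_matrix(tv, clim, variables=["MAT"]).iloc[0]
        assert row["rho"] == pytest.approx(-1.0)

    def test_tied_data_matches_average_rank_bruteforce(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 7.0, 6.0, 9.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2  # average of 1-based ranks
                i = j
            return ranks

        rx, ry = avg_ranks(x), avg_ranks(y)
        brute = np.corrcoef(rx, ry)[0, 1]
        from scipy import stats

        rho, _ = stats.spearmanr(x, y)
        assert rho == pytest.approx(brute, rel=1e-12)

    def test_constant_vector_reported_missing(self):
        row = self._run([5.0, 5.0, 5.0, 5.0])
        assert np.isnan(row["rho"])


class TestSimpleRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept, r2 = simple_regression(x, 2.0 * x + 1.0)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_orthogonal_predictor(self):
        x = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0, 1.0, -2.0, 1.0])  # symmetric in x
        slope, _, r2 = simple_regression(x, y)
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        slope, intercept, r2 = simple_regression(x, y)
        X = np.column_stack([np.ones(25), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2_oracle = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert intercept == pytest.approx(beta[0], rel=1e-10, abs=1e-12)
        assert slope == pytest.approx(beta[1], rel=1e-10, abs=1e-12)
        assert r2 == pytest.approx(r2_oracle, rel=1e-10, abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            simple_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestEnvChangeMatrix:
    def _climate_with_td(self, td_by_site, year=2010):
        rows = []
        for s, td in td_by_site.items():
            rows.append(
                {
                    "site": s, "year": year, "MAT": 10.0, "MWMT": 20.0 + td,
                    "MCMT": 20.0, "TD": td, "MAP": 500.0, "AHM": 40.0,
                    "DD_lt_0": 100.0, "DD_gt_5": 4000.0, "DD_lt_18": 1800.0,
                    "DD_gt_18": 700.0, "NFFD": 200.0, "PAS": 10.0,
                    "EMT": -15.0, "EXT": 40.0, "Eref": 900.0, "CMD": 450.0,
                    "RH": 60.0,
                }
            )
        return pd.DataFrame(rows)

    def test_identical_sites_zero_matrix(self):
        clim = self._climate_with_td({"A": 27.0, "B": 27.0})
        out = env_change_matrix(clim, "TD")
        assert (out.to_numpy() == 0).all()

    def test_single_year_hand_values(self):
        clim = self._climate_with_td({"A": 26.0, "B": 28.0, "C": 31.0})
        out = env_change_matrix(clim, "TD")
        assert out.loc["A", "B"] == pytest.approx(2.0)
        assert out.loc["B", "C"] == pytest.approx(3.0)
        assert out.loc["A", "C"] == pytest.approx(5.0)

    def test_multi_year_matches_bruteforce(self, rng):
        clim = pd.concat(
            [
                self._climate_with_td(
                    {s: float(rng.uniform(24, 30)) for s in "ABC"}, year=y
                )
                for y in (2010, 2011, 2012)
            ],
            ignore_index=True,
        )
        out = env_change_matrix(clim, "TD")
        for s1, s2 in itertools.combinations("ABC", 2):
            vals1 = clim[clim.site == s1].sort_values("year")["TD"].to_numpy()
            vals2 = clim[clim.site == s2].sort_values("year")["TD"].to_numpy()
            assert out.loc[s1, s2] == pytest.approx(
                np.mean(np.abs(vals1 - vals2))
            )

    def test_single_year_triangle_inequality(self, rng):
        for _ in range(10):
            tds = {s: float(rng.uniform(20, 35)) for s in "ABCD"}
            out = env_change_matrix(self._climate_with_td(tds), "TD")
            for a, b, c in itertools.permutations("ABCD", 3):
                assert out.loc[a, c] <= out.loc[a, b] + out.loc[b, c] + 1e-12

    def test_missing_cell_rejected(self):
        clim = pd.concat(
            [
                self._climate_with_td({"A": 26.0, "B": 27.0}, year=2010),
                self._climate_with_td({"A": 26.0}, year=2011),
            ],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="missing"):
            env_change_matrix(clim, "TD")


class TestTypebDistance:
    def test_perfect_correlation_zero_distance(self):
        rb = pd.DataFrame(1.0, index=list("ABC"), columns=list("ABC"))
        assert (typeb_distance_matrix(rb).to_numpy() == 0).all()

    def test_elementwise_complement(self):
        rb = pd.DataFrame(
            [[1.0, 0.2, 0.7], [0.2, 1.0, 0.0], [0.7, 0.0, 1.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        out = typeb_distance_matrix(rb)
        assert out.loc["A", "B"] == pytest.approx(0.8)
        assert out.loc["B", "C"] == pytest.approx(1.0)
        assert out.loc["A", "C"] == pytest.approx(0.3)
        assert (np.diag(out.to_numpy()) == 0).all()

    def test_out_of_range_rejected(self):
        rb = pd.DataFrame(
            [[1.0, 1.2], [1.2, 1.0]], index=list("AB"), columns=list("AB")
        )
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            typeb_distance_matrix(rb)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        A = random_symmetric_distance(rng, 6)
        res = mantel_test(A, A, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200, abs=1e-12)

    def test_anti_ordered_is_minus_one(self, rng):
        A = random_symmetric_distance(rng, 6)
        B = -A + A.max().max() + 1.0
        b = B.to_numpy()
        np.fill_diagonal(b, 0.0)
        B = pd.DataFrame(b, index=A.index, columns=A.columns)
        res = mantel_test(A, B, n_perm=199, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_exact_enumeration_matches_full_monte_carlo(self, rng):
        # 4 labels -> 24 relabelings; the exact p must agree with the
        # empirical tail probability over all permutations
        A = random_symmetric_distance(rng, 4)
        B = random_symmetric_distance(rng, 4)
        res = mantel_test(A, B, n_perm=999, seed=1)
        a, b = A.to_numpy(), B.to_numpy()
        iu = np.triu_indices(4, 1)
        r_obs = np.corrcoef(a[iu], b[iu])[0, 1]
        count = 0
        perms = list(itertools.permutations(range(4)))
        for p in perms:
            bp = b[np.ix_(p, p)]
            if abs(np.corrcoef(a[iu], bp[iu])[0, 1]) >= abs(r_obs) - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / len(perms), rel=1e-12)

    def test_three_labels_warns_about_p_floor(self, rng):
        A = random_symmetric_distance(rng, 3)
        B = random_symmetric_distance(rng, 3)
        with pytest.warns(UserWarning, match="floor"):
            res = mantel_test(A, B, n_perm=999, seed=0)
        assert res.p >= 1 / 6 - 1e-12

    def test_label_mismatch_rejected(self, rng):
        A = random_symmetric_distance(rng, 5)
        B = random_symmetric_distance(rng, 5, labels=list("vwxyz"))
        with pytest.raises(ValueError, match="labels"):
            mantel_test(A, B, n_perm=199)

    def test_monotone_transform_leaves_spearman_invariant(self, rng):
        # companion property for the rank-based trait-climate analysis
        from scipy import stats

        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r1, _ = stats.spearmanr(x, y)
        r2, _ = stats.spearmanr(np.exp(x), y**3)  # both strictly monotone
        assert r1 == pytest.approx(r2, rel=1e-12)


class TestSiteYearMeans:
    def test_age_maps_to_calendar_year(self, single_site_data):
        data, _ = single_site_data
        tv = site_year_trait_means(data, planting_year=2009)
        assert set(tv["year"]) == {2014}  # age 5 + 2009
        expected = data[data.age == 5]["value"].mean()
        assert tv["value"].iloc[0] == pytest.approx(expected)
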