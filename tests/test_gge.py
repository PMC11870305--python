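"""GGE biplot: SVD correctness, SVP invariance, the four analysis views."""

import numpy as np
import pandas as pd
import pytest

from clonetrial.gge_biplot import (
    build_ge_matrix,
    discrimination_representativeness,
    fit_gge,
    mean_vs_stability,
    rank_genotypes,
    which_won_where,
)


def _df(M, genotypes=None, environments=None):
    M = np.asarray(M, dtype=float)
    genotypes = genotypes or [f"G{i+1}" for i in range(M.shape[0])]
    environments = environments or [f"E{j+1}" for j in range(M.shape[1])]
    return pd.DataFrame(M, index=genotypes, columns=environments)


def _blup_table(M, trait="height", age=5):
    df = _df(M)
    rows = []
    for g in df.index:
        for e in df.columns:
            if not pd.isna(df.at[g, e]):
                rows.append(
                    {"clone": g, "site": e, "trait": trait, "age": age,
                     "blup": df.at[g, e]}
                )
    return pd.DataFrame(rows)


class TestFitGge:
    def test_hand_svd_rank_one(self):
        # centered matrix [[1,-1],[-1,1],[0,0]] has singular values (2, 0)
        M = _df([[2.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
        model = fit_gge(M, scaling="none")
        assert model.singular_values[0] == pytest.approx(2.0, abs=1e-12)
        assert model.singular_values[1] == pytest.approx(0.0, abs=1e-12)
        assert model.pct_explained[0] == pytest.approx(100.0, abs=1e-9)

    def test_centering_identity(self, rng):
        M = _df(rng.normal(size=(8, 4)))
        model = fit_gge(M, scaling="none")
        assert np.allclose(model.processed.mean(axis=0), 0.0, atol=1e-12)

    def test_pct_explained_sums_to_100_nonincreasing(self, rng):
        model = fit_gge(_df(rng.normal(size=(10, 5))), scaling="env_sd")
        assert model.pct_explained.sum() == pytest.approx(100.0)
        assert np.all(np.diff(model.singular_values) <= 1e-12)

    def test_rank2_reconstruction_error_is_tail_energy(self, rng):
        for _ in range(10):
            M = _df(rng.normal(size=(9, 6)))
            model = fit_gge(M, scaling="env_sd")
            err = np.linalg.norm(model.processed - model.rank2()) ** 2
            tail = float(np.sum(model.singular_values[2:] ** 2))
            assert err == pytest.approx(tail, rel=1e-8, abs=1e-10)

    def test_svp_modes_reconstruct_identically(self, rng):
        M = _df(rng.normal(size=(7, 4)))
        recons = []
        for svp in ("genotype_focused", "environment_focused", "symmetric"):
            m = fit_gge(M, scaling="none", svp=svp)
            recons.append(m.genotype_scores @ m.environment_scores.T)
        assert np.allclose(recons[0], recons[1], atol=1e-10)
        assert np.allclose(recons[0], recons[2], atol=1e-10)

    def test_zero_sd_environment_rejected(self):
        M = _df([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            fit_gge(M, scaling="env_sd")


class TestBuildGeMatrix:
    def test_complete_table_no_flags(self, rng):
        tab = _blup_table(rng.normal(size=(5, 3)))
        gem = build_ge_matrix(tab, "height", 5)
        assert gem.imputed == [] and gem.dropped_genotypes == []

    def test_missing_cell_imputed_with_column_mean(self, rng):
        M = rng.normal(size=(5, 3))
        Mna = M.copy()
        Mna[0, 1] = np.nan
        gem = build_ge_matrix(_blup_table(Mna), "height", 5)
        expected = np.nanmean(Mna[:, 1])
        assert gem.values.iloc[0, 1] == pytest.approx(expected)
        assert ("G1", "E2") in gem.imputed

    def test_sparse_genotypes_dropped_and_reported(self, rng):
        # half the clones observed at one site only (site-preservation
        # situation): they are excluded and listed
        M = rng.normal(size=(8, 3)).astype(object)
        for i in range(4):
            M[i, 1] = np.nan
            M[i, 2] = np.nan
        gem = build_ge_matrix(_blup_table(M.astype(float)), "height", 5)
        assert sorted(gem.dropped_genotypes) == ["G1", "G2", "G3", "G4"]
        assert gem.values.shape == (4, 3)


class TestWhichWonWhere:
    def test_dominant_genotype_wins_everywhere(self, rng):
        M = rng.normal(size=(6, 3))
        M[2] += 10.0  # one clone far better in every environment
        model = fit_gge(_df(M), scaling="none")
        www = which_won_where(model)
        assert set(www["winners"].values()) == {"G3"}
        assert "G3" in www["vertices"]

    def test_winners_match_bruteforce_argmax(self, rng):
        for _ in range(50):
            M = rng.normal(size=(rng.integers(4, 9), rng.integers(2, 5)))
            model = fit_gge(_df(M), scaling="none")
            www = which_won_where(model)
            R2 = model.rank2()
            for j, env in enumerate(model.environments):
                best = int(np.argmax(R2[:, j]))
                assert www["winners"][env] == model.genotypes[best]

    def test_winner_invariant_under_svp(self, rng):
        M = _df(rng.normal(size=(7, 3)))
        winners = [
            which_won_where(fit_gge(M, scaling="none", svp=svp))["winners"]
            for svp in ("genotype_focused", "environment_focused", "symmetric")
        ]
        assert winners[0] == winners[1] == winners[2]

    def test_planted_two_sector_pattern(self):
        # two environments prefer clone A, the third prefers clone B
        M = _df(
            [
                [3.0, 3.2, 0.1],   # A: best at E1, E2
                [0.2, 0.1, 2.9],   # B: best at E3
                [1.0, 1.1, 1.0],
                [0.5, 0.4, 0.6],
                [0.0, 0.2, 0.3],
            ],
            genotypes=["A", "B", "C", "D", "E"],
        )
        www = which_won_where(fit_gge(M, scaling="none"))
        assert www["winners"]["E1"] == "A" and www["winners"]["E2"] == "A"
        assert www["winners"]["E3"] == "B"
        assert set(www["sectors"]) >= {"A", "B"}

    def test_degenerate_identical_scores_rejected(self):
        M = _df([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        model = fit_gge(M, scaling="none")
        with pytest.raises(ValueError, match="identical|degenerate"):
            which_won_where(model)


class TestMeanVsStability:
    def test_origin_genotype_has_zero_projection_and_distance(self, rng):
        M = rng.normal(size=(6, 3))
        # a genotype equal to the mean of the others sits at the origin
        # after environment-centering
        M[0] = M[1:].mean(axis=0)
        model = fit_gge(_df(M), scaling="none")
        ms = mean_vs_stability(model).set_index("genotype")
        assert ms.loc["G1", "mean_projection"] == pytest.approx(0.0, abs=1e-9)
        assert ms.loc["G1", "stability_distance"] == pytest.approx(0.0, abs=1e-9)

    def test_projection_order_matches_rank2_means(self, rng):
        for _ in range(10):
            M = rng.normal(size=(8, 4))
            model = fit_gge(_df(M), scaling="none")
            ms = mean_vs_stability(model)
            pred_means = model.rank2().mean(axis=1)
            assert np.array_equal(
                np.argsort(-ms["mean_projection"].to_numpy()),
                np.argsort(-pred_means),
            )

    def test_constant_advantage_is_maximally_stable(self):
        base = np.array(
            [[0.0, 0.0, 0.0], [1.0, -1.0, 0.5], [-1.0, 1.0, -0.5], [0.3, 0.2, -0.4]]
        )
        lifted = base.copy()
        lifted[0] += 2.0  # same advantage in every environment
        model = fit_gge(_df(lifted), scaling="none")
        ms = mean_vs_stability(model).set_index("genotype")
        assert ms["mean_projection"].idxmax() == "G1"
        assert ms.loc["G1", "stability_distance"] == pytest.approx(
            0.0, abs=0.15
        )

    def test_projection_order_invariant_under_svp(self, rng):
        M = _df(rng.normal(size=(7, 3)))
        orders = []
        for svp in ("genotype_focused", "environment_focused", "symmetric"):
            ms = mean_vs_stability(fit_gge(M, scaling="none", svp=svp))
            orders.append(list(np.argsort(-ms["mean_projection"].to_numpy())))
        assert orders[0] == orders[1] == orders[2]


class TestDiscriminationRepresentativeness:
    def test_duplicated_environments_have_zero_angle(self, rng):
        col = rng.normal(size=5)
        M = np.column_stack([col, col, rng.normal(size=5)])
        model = fit_gge(_df(M), scaling="none", svp="environment_focused")
        dr = discrimination_representativeness(model).set_index("environment")
        # identical columns -> identical vectors -> equal angles to AEA
        assert dr.loc["E1", "angle_to_aea_deg"] == pytest.approx(
            dr.loc["E2", "angle_to_aea_deg"], abs=1e-6
        )
        assert dr.loc["E1", "vector_length"] == pytest.approx(
            dr.loc["E2", "vector_length"], rel=1e-9
        )

    def test_angles_track_column_correlations(self, rng):
        # cos(angle between environment vectors) approximates the
        # between-environment correlation up to rank-2 truncation
        M = rng.normal(size=(30, 3))
        M[:, 1] = M[:, 0] * 0.9 + rng.normal(size=30) * 0.1
        model = fit_gge(_df(M), scaling="env_sd", svp="environment_focused")
        E = model.environment_scores
        cos01 = E[0] @ E[1] / (np.linalg.norm(E[0]) * np.linalg.norm(E[1]))
        corr01 = np.corrcoef(model.processed[:, 0], model.processed[:, 1])[0, 1]
        assert cos01 == pytest.approx(corr01, abs=0.15)
        assert cos01 > 0.8


class TestRankGenotypes:
    def test_ideal_genotype_ranks_first_with_zero_distance(self):
        base = np.array(
            [[2.0, 2.0, 2.0], [1.0, -1.0, 0.0], [-1.0, 1.0, 0.0], [-2.0, -2.0, -2.0]]
        )
        model = fit_gge(_df(base), scaling="none")
        rk = rank_genotypes(model)
        assert rk.iloc[0]["genotype"] == "G1"
        assert rk.iloc[0]["distance_to_ideal"] == pytest.approx(0.0, abs=0.2)

    def test_rotation_invariance(self, rng):
        # applying one rotation to all biplot coordinates (an isometry of
        # the score plane) must not change the ranking
        import dataclasses

        M = rng.normal(size=(8, 4))
        model = fit_gge(_df(M), scaling="none")
        theta = 0.7
        Q = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        lam = model.singular_values[:2]
        rotated = dataclasses.replace(
            model,
            u2=((model.u2 * lam) @ Q) / lam,
            v2=model.v2 @ Q,
        )
        r1 = rank_genotypes(model)
        r2 = rank_genotypes(rotated)
        assert list(r1["genotype"]) == list(r2["genotype"])
        assert np.allclose(
            r1["distance_to_ideal"], r2["distance_to_ideal"], atol=1e-9
        )

    def test_rank_order_invariant_under_svp(self, rng):
        M = _df(rng.normal(size=(9, 3)))
        orders = [
            list(rank_genotypes(fit_gge(M, scaling="none", svp=svp))["genotype"])
            for svp in ("genotype_focused", "environment_focused", "symmetric")
        ]
        assert orders[0] == orders[1] == orders[2]

    def test_planted_high_stable_clone_selected(self):
        # one clone with high mean and near-constant advantage wins the
        # ideal-genotype ranking (the selection logic for stable
        # high-yield clones)
        M = np.array(
            [
                [2.0, 2.1, 1.9],
                [2.6, -0.5, 0.4],
                [-0.5, 2.4, 0.1],
                [0.0, 0.1, -0.2],
                [-2.0, -2.1, -1.8],
            ]
        )
        model = fit_gge(
            _df(M, genotypes=["stable", "e1spec", "e2spec", "mid", "poor"]),
            scaling="none",
        )
        assert rank_genotypes(model).iloc[0]["genotype"] == "stable"
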