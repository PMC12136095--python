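"""Factor extraction, selection, pruning, rotation, extension, scoring."""

import warnings

import numpy as np
import pandas as pd
import pytest

from svdlatent.cohort import (
    CohortConfig,
    REFERENCE_LOADINGS,
    generate_cohort,
    generate_factor_model_sample,
    implied_sigma,
    marker_kinds,
    prepare_markers,
)
from svdlatent.correlations import mixed_matrix
from svdlatent.efa import (
    align_loadings,
    choose_rotation,
    congruence,
    efa_pipeline,
    extension_loadings,
    factor_scores_regression,
    fit_factor_model,
    map_criterion,
    minres_fit,
    prune_low_communality,
    rotate,
    salient_loadings,
    vss_criterion,
)


class TestMinres:
    def test_rank_one_recovery(self):
        lam = np.array([0.8, 0.7, 0.6])
        R = implied_sigma(lam[:, None])
        fit = minres_fit(R, 1)
        rec = np.abs(fit.loadings[:, 0])
        assert np.abs(rec - lam).max() < 1e-4
        assert fit.objective < 1e-9

    def test_identity_gives_zero_loadings(self):
        fit = minres_fit(np.eye(5), 1)
        assert np.abs(fit.loadings).max() < 1e-3
        assert fit.objective < 1e-6

    def test_ledermann_bound(self):
        with pytest.raises(ValueError, match="Ledermann"):
            minres_fit(np.eye(4), 3)

    def test_objective_not_worse_than_generating_loadings(self):
        L0 = REFERENCE_LOADINGS.to_numpy()
        R = implied_sigma(L0)
        fit = minres_fit(R, 2)
        res0 = R - L0 @ L0.T
        np.fill_diagonal(res0, 0.0)
        assert fit.objective <= np.sum(res0**2) / 2 + 1e-10

    def test_reference_pattern_recovered_noiseless(self):
        R = implied_sigma(REFERENCE_LOADINGS.to_numpy())
        fit = minres_fit(R, 2)
        rot, info = choose_rotation(fit.loadings)
        assert info["decision"] == "varimax"
        A = align_loadings(rot.loadings, REFERENCE_LOADINGS.to_numpy())
        assert np.abs(A - REFERENCE_LOADINGS.to_numpy()).max() <= 0.01
        for j in range(2):
            assert abs(congruence(A[:, j], REFERENCE_LOADINGS.to_numpy()[:, j])) > 0.99


class TestFactorCountCriteria:
    def test_two_factor_structure_suggests_two(self):
        R = implied_sigma(REFERENCE_LOADINGS.to_numpy())
        assert map_criterion(R, 5)[0] == 2
        assert vss_criterion(R, 5, 1)[0] == 2
        assert vss_criterion(R, 5, 2)[0] == 2

    def test_one_factor_structure_suggests_one(self):
        R = implied_sigma(np.array([[0.8], [0.75], [0.7], [0.65], [0.6]]))
        assert map_criterion(R, 3)[0] == 1
        assert vss_criterion(R, 2, 1)[0] == 1

    def test_identity_flags_no_common_factors(self):
        with pytest.warns(RuntimeWarning, match="no common factors"):
            k, profile = map_criterion(np.eye(6), 3)
        assert k == 0
        assert profile[0] == pytest.approx(0.0, abs=1e-12)

    def test_vss_profile_bounded(self):
        R = implied_sigma(REFERENCE_LOADINGS.to_numpy())
        _, profile = vss_criterion(R, 4, 1)
        assert np.all(profile <= 1.0 + 1e-12)


class TestRotation:
    def test_single_factor_unchanged(self):
        L = np.array([[0.8], [0.6]])
        out = rotate(L, "varimax")
        assert np.allclose(out.loadings, L)

    def test_varimax_preserves_communalities(self):
        rng = np.random.default_rng(0)
        L = rng.normal(size=(8, 2))
        out = rotate(L, "varimax")
        assert np.allclose(
            np.sum(out.loadings**2, axis=1), np.sum(L**2, axis=1), atol=1e-8
        )

    def test_scramble_restore(self):
        # varimax must undo a random orthogonal scramble of a simple structure
        L = np.zeros((6, 2))
        L[:3, 0] = [0.8, 0.7, 0.6]
        L[3:, 1] = [0.75, 0.65, 0.55]
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        out = rotate(L @ Q, "varimax")
        A = align_loadings(out.loadings, L)
        for j in range(2):
            assert congruence(A[:, j], L[:, j]) > 0.999

    def test_oblimin_recovers_factor_correlation(self):
        phi = np.array([[1.0, 0.5], [0.5, 1.0]])
        L = np.zeros((6, 2))
        L[:3, 0] = [0.8, 0.7, 0.6]
        L[3:, 1] = [0.75, 0.65, 0.55]
        R = implied_sigma(L, phi)
        fit = minres_fit(R, 2)
        out = rotate(fit.loadings, "oblimin")
        off = abs(out.phi[0, 1])
        assert off == pytest.approx(0.5, abs=0.05)

    def test_rotation_decision_rules(self):
        # orthogonal truth -> varimax; correlated factors -> oblimin retained
        R_orth = implied_sigma(REFERENCE_LOADINGS.to_numpy())
        _, info = choose_rotation(minres_fit(R_orth, 2).loadings)
        assert info["decision"] == "varimax"

        phi = np.array([[1.0, 0.5], [0.5, 1.0]])
        L = np.zeros((6, 2))
        L[:3, 0] = [0.8, 0.7, 0.6]
        L[3:, 1] = [0.75, 0.65, 0.55]
        _, info2 = choose_rotation(minres_fit(implied_sigma(L, phi), 2).loadings)
        assert info2["decision"] == "oblimin"


class TestSalience:
    def test_reference_pattern_counts(self):
        mask = salient_loadings(REFERENCE_LOADINGS)
        assert int(mask["f1"].sum()) == 6
        assert int(mask["f2"].sum()) == 3
        assert not (mask["f1"] & mask["f2"]).any()  # no cross-loadings

    def test_threshold_inclusive_and_sign_blind(self):
        L = pd.DataFrame({"f1": [0.32, -0.32, 0.3199]})
        mask = salient_loadings(L)
        assert list(mask["f1"]) == [True, True, False]

    def test_all_zero_empty(self):
        assert not salient_loadings(pd.DataFrame(np.zeros((4, 2)))).any().any()


class TestPruning:
    def test_no_removals_when_all_communalities_high(self):
        Z = generate_factor_model_sample(REFERENCE_LOADINGS, 5000, seed=2)
        kinds = {c: "continuous" for c in Z.columns}
        sol = prune_low_communality(Z, kinds, 2)
        assert sol.pruning_history == []

    def test_default_cohort_removes_four_low_communality_indicators(self, prepared_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = efa_pipeline(prepared_cohort, marker_kinds(), k=2)
        removed = {v for v, _ in sol.pruning_history}
        assert removed == {"mb_lobar", "mb_deep", "mb_infratentorial", "pvs_brainstem"}
        assert set(sol.loadings.index) == set(REFERENCE_LOADINGS.index)
        assert (sol.communalities >= 0.2).all()

    def test_tie_breaks_lexicographically(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(2000)
        df = pd.DataFrame({
            "a1": base + rng.standard_normal(2000) * 0.5,
            "a2": base + rng.standard_normal(2000) * 0.5,
            "a3": base + rng.standard_normal(2000) * 0.5,
            # two identical pure-noise columns: exactly tied communalities
            "zz": np.tile(rng.standard_normal(1000), 2),
        })
        df["aa"] = df["zz"].to_numpy()
        kinds = {c: "continuous" for c in ["a1", "a2", "a3", "aa", "zz"]}
        sol = prune_low_communality(df, kinds, 1)
        removed = [v for v, _ in sol.pruning_history]
        assert removed[0] == "aa"  # lexicographic before 'zz'


class TestExtension:
    def test_uncorrelated_excluded_variable_near_zero(self):
        Z = generate_factor_model_sample(REFERENCE_LOADINGS, 20_000, seed=4)
        rng = np.random.default_rng(5)
        Z["noise"] = rng.standard_normal(len(Z))
        kinds = {c: "continuous" for c in Z.columns}
        R_full = mixed_matrix(Z, kinds)
        sol = fit_factor_model(mixed_matrix(Z, {c: "continuous" for c in REFERENCE_LOADINGS.index}), 2)
        ext = extension_loadings(R_full, sol, ["noise"])
        assert np.abs(ext.to_numpy()).max() < 0.05

    def test_duplicate_indicator_matches_score_correlation(self):
        Z = generate_factor_model_sample(REFERENCE_LOADINGS, 20_000, seed=6)
        Z["dup"] = Z["wmh_periventricular"].to_numpy()
        kinds = {c: "continuous" for c in Z.columns}
        R_full = mixed_matrix(Z, kinds)
        sol = fit_factor_model(mixed_matrix(Z, {c: "continuous" for c in REFERENCE_LOADINGS.index}), 2)
        ext = extension_loadings(R_full, sol, ["dup"])
        scores, _ = factor_scores_regression(Z, sol)
        for j, col in enumerate(sol.loadings.columns):
            r = np.corrcoef(Z["dup"], scores[col])[0, 1]
            assert ext.iloc[0, j] == pytest.approx(r, abs=0.01)

    def test_deep_mb_extends_onto_svd_factor(self):
        df = generate_cohort(CohortConfig(n_participants=20_000, seed=7))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prep, _ = prepare_markers(df)
            sol = efa_pipeline(prep, marker_kinds(), k=2)
        assert sol.extension is not None
        A = align_loadings(sol.loadings.to_numpy(), REFERENCE_LOADINGS.to_numpy())
        # factor_1 is the SVD factor after alignment-stable ordering
        assert sol.extension.loc["mb_deep", "factor_1"] >= 0.32


class TestFactorScores:
    def test_orthogonal_factors_give_near_uncorrelated_scores(self):
        Z = generate_factor_model_sample(REFERENCE_LOADINGS, 10_000, seed=8)
        sol = fit_factor_model(mixed_matrix(Z, {c: "continuous" for c in Z.columns}), 2)
        scores, W = factor_scores_regression(Z, sol)
        r = np.corrcoef(scores.to_numpy(), rowvar=False)[0, 1]
        assert abs(r) < 0.05

    def test_score_validity_matches_closed_form(self):
        # corr(estimated score, true factor) = sqrt(Lambda' R^-1 Lambda)
        L = REFERENCE_LOADINGS.to_numpy()
        R = implied_sigma(L)
        n = 100_000
        rng = np.random.default_rng(9)
        F = rng.standard_normal((n, 2))
        Z = pd.DataFrame(
            F @ L.T + rng.standard_normal((n, 9)) * np.sqrt(1 - np.sum(L**2, axis=1)),
            columns=REFERENCE_LOADINGS.index,
        )
        sol = fit_factor_model(mixed_matrix(Z, {c: "continuous" for c in Z.columns}), 2)
        scores, _ = factor_scores_regression(Z, sol)
        A = align_loadings(sol.loadings.to_numpy(), L)
        validity_pop = np.sqrt(np.diag(L.T @ np.linalg.inv(R) @ L))
        # align the score columns to the generating factors as well
        sol_cols = list(sol.loadings.columns)
        cong = np.abs(np.corrcoef(scores.to_numpy().T, F.T)[:2, 2:])
        for j in range(2):
            tgt = int(np.argmax(cong[:, j]))
            assert cong[tgt, j] == pytest.approx(validity_pop[j], abs=0.01)

    def test_single_dominant_variable_score_tracks_its_z(self):
        lam = np.array([[0.99], [0.3], [0.3]])
        Z = generate_factor_model_sample(lam, 20_000, seed=10)
        sol = fit_factor_model(mixed_matrix(Z, {c: "continuous" for c in Z.columns}), 1)
        scores, _ = factor_scores_regression(Z, sol)
        r = abs(np.corrcoef(scores.iloc[:, 0], Z["v1"])[0, 1])
        assert r > 0.95


class TestSolutionInvariants:
    def test_variance_explained_ordering_and_sum(self, prepared_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = efa_pipeline(prepared_cohort, marker_kinds(), k=2)
        ve = sol.variance_explained.to_numpy()
        assert ve[0] >= ve[1]
        assert ve.sum() == pytest.approx(sol.communalities.mean(), abs=1e-8)
        assert sol.communalities.add(sol.uniquenesses).sub(1.0).abs().max() < 1e-8

    def test_sign_convention_reproduces_negative_fa_loading(self, prepared_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = efa_pipeline(prepared_cohort, marker_kinds(), k=2)
        svd_col = sol.loadings["factor_1"]
        assert svd_col["wmh_periventricular"] > 0
        assert svd_col["wm_fa"] < 0
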