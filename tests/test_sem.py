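"""SEM engine: implied covariance, ML fitting, effect decomposition,
bias-corrected bootstrap, single-indicator comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

from svdlatent.cohort import CohortConfig
from svdlatent.sem import (
    Parameter,
    SemModel,
    SemModelSpec,
    SVD_INDICATORS,
    bootstrap_bc_ci,
    combine_effects,
    decompose_effects,
    fit_indices,
    fit_ml,
    implied_covariance,
    measurement_spec,
    mediation_spec,
    simulate_from_spec,
    single_indicator_comparison,
)


def default_true_values(model: SemModel) -> dict:
    """Plausible population values for the default mediation model."""
    paths = CohortConfig().structural_paths()
    vals = {}
    for lab in model.labels:
        if lab.startswith("l_"):
            vals[lab] = 0.7
        elif lab.startswith("e_") and lab not in ("e_gm", "e_cognition"):
            vals[lab] = 0.51
        elif lab.startswith("c_"):
            vals[lab] = 0.05
    vals["l_wm_fa"] = -0.73
    vals["e_wm_fa"] = 0.46
    vals.update({
        "b_svd_x": paths["x_svd"], "b_gm_x": paths["x_gm"],
        "b_gm_svd": paths["svd_gm"], "b_cog_svd": paths["svd_cog"],
        "b_cog_gm": paths["gm_cog"], "b_cog_x": paths["x_cog"],
        "e_gm": 0.95, "e_cognition": 0.92, "v_age": 1.0,
    })
    return vals


def path_tracing_covariance(spec: SemModelSpec, values: dict) -> np.ndarray:
    """Independent oracle: sequential covariance recursion on the acyclic
    graph, cov(i, .) = sum_k b_ik cov(k, .) + residual terms, built without
    the (I-A)^{-1} machinery used by the implementation."""
    model = SemModel(spec)
    theta = np.array([values[lab] for lab in model.labels])
    A, S = model.matrices(theta)
    nv = model.nv
    # topological order of the DAG defined by A (column -> row edges)
    order, placed = [], set()
    while len(order) < nv:
        for i in range(nv):
            if i in placed:
                continue
            parents = np.nonzero(A[i])[0]
            if all(p in placed for p in parents):
                order.append(i)
                placed.add(i)
    C = np.zeros((nv, nv))
    for i in order:
        parents = np.nonzero(A[i])[0]
        for j in order:
            if j == i:
                break
            cij = S[i, j] + sum(A[i, p] * C[p, j] for p in parents)
            C[i, j] = C[j, i] = cij
        var = S[i, i] + sum(
            A[i, p] * A[i, q] * C[p, q] for p in parents for q in parents
        ) + 2 * sum(A[i, p] * S[i, p] for p in parents)
        C[i, i] = var
    return C[np.ix_(model.obs_idx, model.obs_idx)]


class TestModelSpec:
    def test_loading_count_contract(self):
        spec = measurement_spec()
        model = SemModel(spec)
        loadings = [lab for lab in model.labels if lab.startswith("l_")]
        assert len(loadings) == 6  # variance-standardized: all loadings free

    def test_duplicate_parameter_cell_rejected(self):
        spec = measurement_spec()
        spec.add_loading("svd", "wm_fa", "extra")
        with pytest.raises(ValueError, match="duplicate"):
            SemModel(spec)

    def test_underidentified_latent_rejected(self):
        spec = SemModelSpec(observed=["a", "b"], latent=["f"])
        spec.add_variance("f", "psi_f")
        with pytest.raises(ValueError, match="under-identified"):
            SemModel(spec)

    def test_implied_covariance_matches_path_tracing_oracle(self):
        spec = mediation_spec()
        model = SemModel(spec)
        vals = default_true_values(model)
        sigma = implied_covariance(spec, vals).to_numpy()
        oracle = path_tracing_covariance(spec, vals)
        assert np.abs(sigma - oracle).max() < 1e-10


class TestFitML:
    def test_exact_truth_perfect_fit(self):
        spec = mediation_spec()
        vals = default_true_values(SemModel(spec))
        sigma = implied_covariance(spec, vals)
        fit = fit_ml(sigma, 50_000, spec)
        assert fit.fmin < 1e-10
        assert fit.chi2 == pytest.approx(0.0, abs=1e-5)
        assert fit.cfi == 1.0
        assert fit.rmsea == 0.0
        assert fit.srmr < 1e-6
        for lab, v in vals.items():
            assert fit.estimates[lab] == pytest.approx(v, abs=1e-5)

    def test_simulation_recovery_within_three_ses(self):
        spec = mediation_spec()
        vals = default_true_values(SemModel(spec))
        data = simulate_from_spec(spec, vals, 50_000, seed=13)
        fit = fit_ml(data.cov(), len(data), spec)
        se = fit.standard_errors()
        for lab, truth in vals.items():
            assert abs(fit.estimates[lab] - truth) < 3 * se[lab] + 1e-9, lab

    def test_null_calibration_chi2_near_df(self):
        # independence data: chi2/df ~ 1 in expectation over replicates
        spec = measurement_spec()
        vals = {lab: (0.6 if lab.startswith("l_") else 0.64 if lab.startswith("e_")
                      else 0.05) for lab in SemModel(spec).labels}
        stats_ratio = []
        for rep in range(40):
            data = simulate_from_spec(spec, vals, 800, seed=100 + rep)
            fit = fit_ml(data.cov(), len(data), spec)
            stats_ratio.append(fit.chi2)
        mean_chi2 = np.mean(stats_ratio)
        # chi2_9 mean 9, sd sqrt(18); MC error of the mean over 40 reps
        assert abs(mean_chi2 - fit.df) < 3 * np.sqrt(2 * fit.df / 40) * np.sqrt(fit.df / 3)

    def test_sample_size_guard(self):
        spec = measurement_spec()
        with pytest.raises(ValueError):
            fit_ml(np.eye(6), 5, spec)

    def test_heywood_flagged(self):
        # classic 3-indicator Heywood: lambda_1^2 = r12 r13 / r23 = 2.7 > 1,
        # so the ML residual variance of the first indicator wants to go
        # negative and hits the lower bound
        spec = measurement_spec(indicators=SVD_INDICATORS[:3], residual_pairs=[])
        S = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.3], [0.9, 0.3, 1.0]])
        with pytest.warns(RuntimeWarning, match="Heywood"):
            fit = fit_ml(S, 500, spec)
        assert fit.heywood

    def test_standardized_consistent_with_implied_scales(self):
        spec = mediation_spec()
        vals = default_true_values(SemModel(spec))
        data = simulate_from_spec(spec, vals, 5000, seed=14)
        fit = fit_ml(data.cov(), len(data), spec)
        _, full, A, S, B = fit.model.implied(fit.theta)
        sd = np.sqrt(np.diag(full))
        names = fit.model.vars
        for (m, r, c), std_val in fit.standardized.items():
            i, j = names.index(r), names.index(c)
            if m == "A":
                raw = A[i, j]
                assert std_val == pytest.approx(raw * sd[j] / sd[i], abs=1e-8)


class TestFitIndices:
    def test_hand_arithmetic_oracle(self):
        cfi, rmsea, _ = fit_indices(100, 36, 1000, 45, 892)
        assert cfi == pytest.approx(1 - 64 / 955, abs=1e-12)
        assert rmsea == pytest.approx(np.sqrt(64 / (36 * 891)), abs=1e-12)

    def test_chi2_equal_df_is_perfect(self):
        cfi, rmsea, _ = fit_indices(36, 36, 500, 45, 892)
        assert cfi == 1.0 and rmsea == 0.0

    def test_zero_df_convention(self):
        cfi, rmsea, _ = fit_indices(0, 0, 500, 45, 892)
        assert rmsea == 0.0

    def test_perfect_residuals_zero_srmr(self):
        _, _, srmr = fit_indices(10, 9, 500, 45, 892, np.zeros((4, 4)))
        assert srmr == 0.0


class TestEffectDecomposition:
    def test_product_and_sum_arithmetic(self):
        dec = combine_effects(0.1, {"x->m->y": 0.5 * 0.4})
        assert dec.total_indirect == pytest.approx(0.20)
        assert dec.total == pytest.approx(0.30)

    def test_reference_age_model_arithmetic(self):
        dec = combine_effects(
            -0.003,
            {"age->svd->cognition": -0.043,
             "age->svd->gm->cognition": -0.007,
             "age->gm->cognition": -0.018},
        )
        assert dec.total == pytest.approx(-0.071, abs=1e-12)
        assert dec.total_indirect == pytest.approx(-0.068, abs=1e-12)
        assert round(dec.proportion_mediated["total_indirect"]) == 96
        assert round(dec.proportion_mediated["age->gm->cognition"]) == 25

    def test_identity_total_equals_direct_plus_indirect_on_fits(self):
        spec = mediation_spec()
        vals = default_true_values(SemModel(spec))
        data = simulate_from_spec(spec, vals, 3000, seed=15)
        rng = np.random.default_rng(16)
        for _ in range(5):
            idx = rng.integers(0, len(data), len(data))
            fit = fit_ml(data.iloc[idx].cov(), len(data), spec)
            dec = decompose_effects(fit, "age")
            assert dec.total == pytest.approx(
                dec.direct + sum(dec.pathways.values()), abs=1e-12)

    def test_zero_total_flagged(self):
        with pytest.warns(RuntimeWarning, match="zero"):
            dec = combine_effects(-0.2, {"x->m->y": 0.2})
        assert np.isnan(dec.proportion_mediated["total_indirect"])


class TestBootstrapBC:
    @staticmethod
    def _product_stat(df):
        x, m, y = df["x"].to_numpy(), df["m"].to_numpy(), df["y"].to_numpy()
        a = np.cov(x, m)[0, 1] / np.var(x)
        X = np.column_stack([m, x, np.ones_like(x)])
        b = np.linalg.lstsq(X, y, rcond=None)[0][0]
        return {"indirect": a * b}

    def test_symmetric_distribution_matches_percentile(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame({"z": rng.standard_normal(4000)})
        out = bootstrap_bc_ci(df, lambda d: {"mean": float(d["z"].mean())},
                              n_boot=2000, seed=18)
        est, lo, hi = out["mean"]
        se = 1 / np.sqrt(4000)
        # z0 ~ 0 for the symmetric mean: interval approximately est +/- 1.96 se
        assert lo == pytest.approx(est - 1.96 * se, abs=0.25 * se)
        assert hi == pytest.approx(est + 1.96 * se, abs=0.25 * se)

    def test_known_truth_coverage(self):
        # indirect effect a*b with a=b=0.4, n=2000; 500 resamples, 200
        # replicates: empirical coverage should sit near 95%
        a = b = 0.4
        truth = a * b
        rng = np.random.default_rng(19)
        covered = 0
        n_rep = 200
        for rep in range(n_rep):
            n = 2000
            x = rng.standard_normal(n)
            m = a * x + rng.standard_normal(n) * np.sqrt(1 - a**2)
            y = b * m + rng.standard_normal(n) * np.sqrt(1 - b**2)
            df = pd.DataFrame({"x": x, "m": m, "y": y})
            out = bootstrap_bc_ci(df, self._product_stat, n_boot=500,
                                  seed=int(rng.integers(2**31)))
            _, lo, hi = out["indirect"]
            covered += lo <= truth <= hi
        rate = covered / n_rep
        mc_se = np.sqrt(0.95 * 0.05 / n_rep)
        assert abs(rate - 0.95) < 3 * mc_se

    def test_degenerate_statistic_zero_width(self):
        df = pd.DataFrame({"z": np.ones(100)})
        with pytest.warns(RuntimeWarning, match="constant"):
            out = bootstrap_bc_ci(df, lambda d: {"c": float(d["z"].mean())},
                                  n_boot=200, seed=0)
        est, lo, hi = out["c"]
        assert lo == hi == 1.0

    def test_failure_rate_guard(self):
        df = pd.DataFrame({"z": np.arange(50.0)})

        def flaky(d):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="resamples failed"):
            # point estimate must work, resamples fail
            calls = {"n": 0}

            def stat(d):
                calls["n"] += 1
                if calls["n"] > 1:
                    raise ValueError("fail")
                return {"s": 0.0}

            bootstrap_bc_ci(df, stat, n_boot=100, seed=0)


class TestSingleIndicatorComparison:
    @staticmethod
    def _latent_mediator_table(seed, n=2000, loadings=(0.8, 0.7, 0.7, 0.6, 0.6, 0.5)):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        svd = 0.4 * x + np.sqrt(1 - 0.16) * rng.standard_normal(n)
        gm = -0.2 * x - 0.3 * svd + np.sqrt(1 - 0.2151) * rng.standard_normal(n)
        cog = -0.4 * svd + 0.3 * gm + np.sqrt(0.6) * rng.standard_normal(n)
        cols = {"age": x, "gm": gm, "cognition": cog}
        for name, lam in zip(SVD_INDICATORS, loadings):
            cols[name] = lam * svd + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        return pd.DataFrame(cols)

    def test_latent_model_dominates_noisy_indicators(self):
        hits = 0
        for seed in range(10):
            tab = self._latent_mediator_table(seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = single_indicator_comparison(tab, "age")
            latent = out.loc["latent_svd"]
            singles = out.drop("latent_svd")
            ok = (abs(latent["indirect_via_mediator"])
                  >= singles["indirect_via_mediator"].abs().max()) and (
                latent["outcome_r2"] >= singles["outcome_r2"].max() - 1e-6)
            hits += ok
        assert hits >= 9  # attenuation property across generator seeds

    def test_perfect_indicator_matches_latent(self):
        tab = self._latent_mediator_table(100, n=20_000,
                                          loadings=(0.999, 0.7, 0.7, 0.6, 0.6, 0.5))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = single_indicator_comparison(tab, "age")
        assert out.loc["pvs_basal_ganglia", "indirect_via_mediator"] == pytest.approx(
            out.loc["latent_svd", "indirect_via_mediator"], abs=0.02)

    def test_pure_noise_indicator_near_zero_indirect(self):
        tab = self._latent_mediator_table(101, n=20_000,
                                          loadings=(0.8, 0.7, 0.7, 0.6, 0.6, 0.01))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = single_indicator_comparison(tab, "age")
        assert abs(out.loc["wm_tr", "indirect_via_mediator"]) < 0.02
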