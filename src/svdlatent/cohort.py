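"""Synthetic cohort generator for latent small-vessel-disease (SVD) analyses.

Emulates the statistical structure of a community-based brain-MRI cohort:
regional perivascular-space (PVS) counts, periventricular/subcortical white
matter hyperintensity (WMH) volumes, binary microbleed (MB) presence flags,
mean white-matter fractional anisotropy (FA) and trace (TR), gray-matter and
intracranial volumes, demographics, vascular risk factors, and a multi-test
cognitive battery.

The continuous MRI markers follow an orthogonal two-factor model
``z = Lambda f + Psi^{1/2} eps``; factor 1 is the SVD construct, factor 2 a
second (non-SVD) PVS dimension.  MB presence arises by thresholding latent
normal liabilities at the quantile matching each configured prevalence, so
population tetrachoric/biserial correlations equal products of liability
loadings.  The structural layer generates gray-matter volume and a latent
cognition variable along the acyclic path diagram
``age -> SVD -> GM -> cognition`` (with direct paths), with standardized
coefficients chosen so the composite pathway effects match configured
targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cognition import tukey_ladder

# Marker layout: 10 continuous indicators then 3 binary MB flags.
PVS_MARKERS = [
    "pvs_basal_ganglia",
    "pvs_frontoparietal",
    "pvs_temporal",
    "pvs_insular",
    "pvs_thalamus",
    "pvs_brainstem",
]
WMH_MARKERS = ["wmh_periventricular", "wmh_subcortical"]
DTI_MARKERS = ["wm_fa", "wm_tr"]
CONTINUOUS_MARKERS = PVS_MARKERS + WMH_MARKERS + DTI_MARKERS
BINARY_MARKERS = ["mb_lobar", "mb_deep", "mb_infratentorial"]
ALL_MARKERS = CONTINUOUS_MARKERS + BINARY_MARKERS

#: The nine indicators retained by the published factor solution, in its order.
RETAINED_MARKERS = [
    "pvs_basal_ganglia",
    "pvs_frontoparietal",
    "pvs_temporal",
    "pvs_insular",
    "pvs_thalamus",
    "wmh_periventricular",
    "wmh_subcortical",
    "wm_fa",
    "wm_tr",
]

#: Published varimax loading pattern of the nine retained indicators
#: (rows follow RETAINED_MARKERS; columns are the SVD factor and the
#: second PVS factor).
REFERENCE_LOADINGS = pd.DataFrame(
    [
        [0.50, 0.14],
        [0.03, 0.94],
        [0.05, 0.90],
        [0.00, 0.57],
        [0.42, 0.16],
        [0.85, -0.13],
        [0.66, -0.14],
        [-0.73, 0.01],
        [0.84, 0.07],
    ],
    index=RETAINED_MARKERS,
    columns=["f1", "f2"],
)

# Default generator loadings.  Identical to the reference pattern except
# thalamus PVS on f1 (0.50 instead of 0.42): a population communality of
# 0.202 sits exactly on the 0.2 pruning threshold, where sampling noise at
# n=892 would prune a marker meant to be retained about half the time; the
# default builds in a stability margin.  Brainstem PVS gets deliberately
# weak loadings (population h^2 0.08 < 0.2) so communality pruning removes
# it.
_DEFAULT_CONT_LOADINGS = REFERENCE_LOADINGS.copy()
_DEFAULT_CONT_LOADINGS.loc["pvs_thalamus", "f1"] = 0.50
_DEFAULT_CONT_LOADINGS.loc["pvs_brainstem"] = [0.26, 0.12]
_DEFAULT_CONT_LOADINGS = _DEFAULT_CONT_LOADINGS.loc[CONTINUOUS_MARKERS]

# Binary MB liabilities: (prevalence, loading on f1, loading on f2).
# Loadings keep population communalities below 0.2 in the removal order of
# the reference analysis (lobar < brainstem PVS < infratentorial < deep);
# deep MB stays strong enough that its extension loading onto the SVD
# factor remains salient (lambda x score validity ~ 0.35).
_DEFAULT_BINARY_SPECS = {
    "mb_lobar": (0.24, 0.21, 0.12),
    "mb_deep": (0.14, 0.38, 0.08),
    "mb_infratentorial": (0.08, 0.31, 0.10),
}

# Raw-scale marker distributions.  family is one of:
#   count     -- mean/sd normal, rounded and floored at 0
#   normal    -- mean/sd normal
#   lognormal -- (mu, sigma) of log; calibrated to reported median/IQR
_DEFAULT_MARKER_SCALES = {
    "pvs_basal_ganglia": ("count", 63.3, 16.0),
    "pvs_frontoparietal": ("count", 403.9, 154.2),
    "pvs_temporal": ("count", 122.4, 60.4),
    "pvs_insular": ("count", 5.8, 5.1),
    "pvs_thalamus": ("count", 8.7, 5.1),
    "pvs_brainstem": ("count", 9.2, 3.6),
    # log-scale mu/sigma from median 2351 mm^3, IQR (998, 6143)
    "wmh_periventricular": ("lognormal", np.log(2351.0), np.log(6143.0 / 998.0) / 1.34898),
    # median 251 mm^3, IQR (43, 946)
    "wmh_subcortical": ("lognormal", np.log(251.0), np.log(946.0 / 43.0) / 1.34898),
    "wm_fa": ("normal", 0.393, 0.025),
    "wm_tr": ("normal", 0.0025, 0.0001),
}

# Composite structural pathway targets (standardized, per SD of exposure):
# exposure->SVD->cognition, exposure->SVD->GM->cognition,
# exposure->GM->cognition, and the direct exposure->cognition path.
DEFAULT_PATHWAY_TARGETS = {
    "svd": -0.043,
    "svd_gm": -0.007,
    "gm": -0.018,
    "direct": -0.003,
}

_DEFAULT_COVARIATES = {
    "age": ("normal", 73.6, 7.9),
    "icv": ("normal", 1_358_887.0, 145_867.0),
    "gm_volume": ("normal", 599_773.0, 64_803.0),
    "frs": ("normal", 17.0, 9.0),
    "sbp": ("normal", 126.6, 19.9),
    "sex": ("categorical", ["female", "male"], [0.53, 0.47]),
    "race_ethnicity": (
        "categorical",
        ["white", "chinese_american", "black", "hispanic"],
        [0.42, 0.13, 0.27, 0.18],
    ),
    "education": (
        "categorical",
        ["highschool_or_lower", "less_than_bachelor", "bachelor", "graduate"],
        [0.24, 0.30, 0.21, 0.25],
    ),
    "site": ("categorical", [f"site_{i}" for i in range(1, 7)], [1 / 6] * 6),
    "language": (
        "categorical",
        ["english", "spanish", "cantonese", "mandarin"],
        [0.86, 0.07, 0.05, 0.02],
    ),
    "antihypertensive_use": ("binary", 0.57),
    "diabetes": ("binary", 0.21),
    "hyperlipidemia": ("binary", 0.45),
    "current_smoking": ("binary", 0.06),
    "current_alcohol": ("binary", 0.48),
    "apoe4_carrier": ("binary", 0.27),
    # WHR by sex: women 0.90 (0.08), men 0.97 (0.06), handled specially
    # physical activity: lognormal matched to median 1102.5, IQR (325, 2460)
    "physical_activity": ("lognormal", np.log(1102.5), np.log(2460.0 / 325.0) / 1.34898),
    "mri_cog_interval_years": ("normal", 0.5, 0.3),
    "mri_first": ("binary", 0.5),
}

#: Cognitive battery: per-test loading on the latent cognition variable and
#: mean shift of the normed score (whole sample sits below the norming
#: population).  Loading 0.65 and shift -0.228 put the PC1-weighted global
#: composite near mean -0.72, SD 2.19 in a 10-test battery.
COGNITIVE_TESTS = [
    "casi",
    "digit_symbol",
    "digit_span",
    "trails_b",
    "avlt_immediate",
    "avlt_delayed",
    "semantic_fluency",
    "phonemic_fluency",
    "benson_copy",
    "block_design",
]
DEFAULT_TEST_LOADING = 0.65
DEFAULT_TEST_SHIFT = -0.228

DEFAULT_DOMAIN_MAPPING = {
    "immediate_memory": ["avlt_immediate"],
    "delayed_memory": ["avlt_delayed"],
    "language_semantic_fluency": ["semantic_fluency"],
    "phonemic_fluency": ["phonemic_fluency"],
    "attention_processing_speed": ["digit_symbol", "digit_span"],
    "executive": ["trails_b", "casi"],
    "visuospatial": ["benson_copy", "block_design"],
}


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


def implied_sigma(loading_matrix, factor_correlation=None, uniquenesses=None):
    """Population correlation matrix implied by a factor model.

    Sigma = Lambda Phi Lambda' + Psi.  When ``uniquenesses`` is omitted they
    are set to 1 - h^2 so the diagonal is exactly 1; a communality above 1
    (Heywood configuration) is an error.

    Parameters
    ----------
    loading_matrix : (p, k) array
    factor_correlation : (k, k) array, optional
        Defaults to the identity (orthogonal factors).
    uniquenesses : (p,) array, optional

    Returns
    -------
    (p, p) ndarray, symmetric with unit diagonal.
    """
    L = np.atleast_2d(np.asarray(loading_matrix, dtype=float))
    if L.ndim != 2:
        raise ConfigurationError("loading matrix must be 2-D")
    p, k = L.shape
    phi = np.eye(k) if factor_correlation is None else np.asarray(factor_correlation, float)
    if phi.shape != (k, k) or not np.allclose(phi, phi.T):
        raise ConfigurationError("factor correlation must be symmetric k x k")
    common = L @ phi @ L.T
    h2 = np.diag(common)
    if np.any(h2 > 1.0 + 1e-12):
        bad = int(np.argmax(h2))
        raise ConfigurationError(
            f"communality {h2[bad]:.4f} > 1 for variable index {bad} (Heywood configuration)"
        )
    psi = (1.0 - h2) if uniquenesses is None else np.asarray(uniquenesses, float)
    sigma = common + np.diag(psi)
    return (sigma + sigma.T) / 2.0


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort.

    Defaults reproduce the reference cohort's marker summary statistics in
    expectation (e.g. age 73.6 (7.9) years, basal ganglia PVS 63.3 (16),
    lobar MB prevalence 24%) and the two-factor loading structure of the
    retained indicators.
    """

    n_participants: int = 892
    seed: int = 0
    loadings: pd.DataFrame = field(default_factory=lambda: _DEFAULT_CONT_LOADINGS.copy())
    binary_specs: dict = field(default_factory=lambda: dict(_DEFAULT_BINARY_SPECS))
    marker_scales: dict = field(default_factory=lambda: dict(_DEFAULT_MARKER_SCALES))
    pathway_targets: dict = field(default_factory=lambda: dict(DEFAULT_PATHWAY_TARGETS))
    covariate_specs: dict = field(default_factory=lambda: dict(_DEFAULT_COVARIATES))
    test_loading: float = DEFAULT_TEST_LOADING
    test_shift: float = DEFAULT_TEST_SHIFT
    age_frs_correlation: float = 0.4
    #: additive shift applied to every f1 loading in site_6 (invariance power tests)
    site_loading_shift: float = 0.0
    #: optional per-column MCAR missingness rates
    mcar_rates: dict = field(default_factory=dict)
    #: fraction of the cohort flagged cognitively normal (top of latent cognition)
    normal_fraction: float = 0.8

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        for name, (prev, *_rest) in self.binary_specs.items():
            if not 0.0 < prev < 1.0:
                raise ConfigurationError(f"prevalence for {name} must be in (0, 1)")
        for name, rate in self.mcar_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"MCAR rate for {name} must be in [0, 1]")
        for name, spec in self.marker_scales.items():
            if spec[0] in ("count", "normal") and spec[2] <= 0:
                raise ConfigurationError(f"SD for {name} must be > 0")
        # implied correlation over all 13 latent indicator scales must be PSD
        sigma = self.latent_sigma()
        w = np.linalg.eigvalsh(sigma)
        if w.min() < -1e-10:
            raise ConfigurationError(
                "implied indicator correlation matrix is not positive semi-definite "
                f"(min eigenvalue {w.min():.3e}); check the loading block"
            )

    def full_loading_matrix(self) -> pd.DataFrame:
        """13 x 2 loading matrix: continuous indicators then MB liabilities."""
        rows = [self.loadings.loc[CONTINUOUS_MARKERS].to_numpy()]
        rows.append(
            np.array([[self.binary_specs[m][1], self.binary_specs[m][2]] for m in BINARY_MARKERS])
        )
        return pd.DataFrame(np.vstack(rows), index=ALL_MARKERS, columns=["f1", "f2"])

    def latent_sigma(self) -> pd.DataFrame:
        """Implied correlation matrix of all 13 latent indicator scales."""
        L = self.full_loading_matrix()
        return pd.DataFrame(implied_sigma(L.to_numpy()), index=L.index, columns=L.index)

    def structural_paths(self) -> dict:
        """Standardized structural coefficients derived from pathway targets.

        Each composite target is a product of free paths; where the split is
        underdetermined the magnitudes are set equal (convention), signs
        chosen so the exposure raises SVD and lowers GM/cognition.  These
        splits are a synthetic convention, not reference estimates.
        """
        t = self.pathway_targets
        a_s = float(np.sqrt(abs(t["svd"])))           # X -> SVD
        b_s = t["svd"] / a_s                          # SVD -> cognition
        db = t["svd_gm"] / a_s                        # (SVD->GM) * (GM->cog)
        mag = float(np.sqrt(abs(db)))
        d = -mag if db < 0 else mag                   # SVD -> GM (negative)
        b_g = db / d if d != 0 else 0.0               # GM -> cognition (positive)
        a_g = t["gm"] / b_g if b_g != 0 else 0.0      # X -> GM
        return {
            "x_svd": a_s,
            "svd_cog": b_s,
            "svd_gm": d,
            "gm_cog": b_g,
            "x_gm": a_g,
            "x_cog": t["direct"],
        }

    # ---- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "n_participants": self.n_participants,
            "seed": self.seed,
            "loadings": {m: [float(v) for v in self.loadings.loc[m]] for m in self.loadings.index},
            "binary_specs": {k: list(map(float, v)) for k, v in self.binary_specs.items()},
            "pathway_targets": {k: float(v) for k, v in self.pathway_targets.items()},
            "site_loading_shift": float(self.site_loading_shift),
            "mcar_rates": {k: float(v) for k, v in self.mcar_rates.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        cfg = cls()
        if "loadings" in payload:
            cfg.loadings = pd.DataFrame.from_dict(
                payload.pop("loadings"), orient="index", columns=["f1", "f2"]
            ).loc[CONTINUOUS_MARKERS]
        if "binary_specs" in payload:
            cfg.binary_specs = {k: tuple(v) for k, v in payload.pop("binary_specs").items()}
        for key, val in payload.items():
            setattr(cfg, key, val)
        return cfg


def _empty_table() -> pd.DataFrame:
    cols = (
        ["participant_id"]
        + ALL_MARKERS
        + ["gm_volume", "icv"]
        + [
            "age", "sex", "race_ethnicity", "education", "site", "language",
            "frs", "sbp", "antihypertensive_use", "diabetes", "hyperlipidemia",
            "current_smoking", "current_alcohol", "whr", "physical_activity",
            "apoe4_carrier", "mri_cog_interval_years", "mri_first",
        ]
        + COGNITIVE_TESTS
        + ["cognitively_normal", "latent_svd", "latent_f2", "latent_cognition", "latent_gm_z", "age_z"]
    )
    return pd.DataFrame(columns=cols)


def generate_cohort(config: CohortConfig | None = None, **overrides) -> pd.DataFrame:
    """Draw a participant-level cohort table.

    Deterministic given ``config.seed``.  Columns prefixed ``latent_`` carry
    the generator's ground truth (the SVD factor, the second factor, latent
    cognition and standardized GM) for validation; downstream stages never
    read them.
    """
    config = dataclasses.replace(config or CohortConfig(), **overrides)
    config.validate()
    n = config.n_participants
    if n == 0:
        return _empty_table()
    rng = np.random.default_rng(config.seed)

    paths = config.structural_paths()
    age_z = rng.standard_normal(n)
    svd = paths["x_svd"] * age_z + np.sqrt(1.0 - paths["x_svd"] ** 2) * rng.standard_normal(n)
    f2 = rng.standard_normal(n)
    # GM: unit-variance residual completion (cov(age, svd) = a_s)
    pred_var = (
        paths["x_gm"] ** 2
        + paths["svd_gm"] ** 2
        + 2.0 * paths["x_gm"] * paths["svd_gm"] * paths["x_svd"]
    )
    gm_z = paths["x_gm"] * age_z + paths["svd_gm"] * svd
    gm_z = gm_z + np.sqrt(max(1.0 - pred_var, 1e-12)) * rng.standard_normal(n)
    # cognition: needs the joint covariance of (age, svd, gm)
    cov3 = np.array(
        [
            [1.0, paths["x_svd"], paths["x_gm"] + paths["svd_gm"] * paths["x_svd"]],
            [paths["x_svd"], 1.0, paths["svd_gm"] + paths["x_gm"] * paths["x_svd"]],
            [
                paths["x_gm"] + paths["svd_gm"] * paths["x_svd"],
                paths["svd_gm"] + paths["x_gm"] * paths["x_svd"],
                1.0,
            ],
        ]
    )
    b = np.array([paths["x_cog"], paths["svd_cog"], paths["gm_cog"]])
    cog_pred_var = float(b @ cov3 @ b)
    cognition = (
        paths["x_cog"] * age_z
        + paths["svd_cog"] * svd
        + paths["gm_cog"] * gm_z
        + np.sqrt(max(1.0 - cog_pred_var, 1e-12)) * rng.standard_normal(n)
    )

    df = pd.DataFrame({"participant_id": [f"P{i:06d}" for i in range(1, n + 1)]})

    # --- continuous indicators on the latent z scale --------------------
    site_labels = None
    cov_specs = config.covariate_specs
    site_spec = cov_specs["site"]
    site_labels = rng.choice(site_spec[1], size=n, p=site_spec[2])

    F = np.column_stack([svd, f2])
    L = config.loadings.loc[CONTINUOUS_MARKERS].to_numpy().copy()
    z_cont = {}
    for i, name in enumerate(CONTINUOUS_MARKERS):
        lam = L[i].copy()
        h2 = float(lam @ lam)
        z = F @ lam + np.sqrt(1.0 - h2) * rng.standard_normal(n)
        if config.site_loading_shift:
            # optional site-specific measurement shift for invariance power tests
            mask = site_labels == "site_6"
            z[mask] = (
                (lam[0] + config.site_loading_shift) * svd[mask]
                + lam[1] * f2[mask]
                + np.sqrt(max(1.0 - h2, 0.0)) * rng.standard_normal(int(mask.sum()))
            )
        z_cont[name] = z

    for name in CONTINUOUS_MARKERS:
        family, p1, p2 = config.marker_scales[name]
        z = z_cont[name]
        if family == "count":
            df[name] = np.maximum(np.rint(p1 + p2 * z), 0.0).astype(int)
        elif family == "normal":
            df[name] = p1 + p2 * z
        elif family == "lognormal":
            df[name] = np.exp(p1 + p2 * z)
        else:  # pragma: no cover - guarded by validate
            raise ConfigurationError(f"unknown marker family {family!r}")

    # --- binary MB flags via liability thresholds -----------------------
    for name in BINARY_MARKERS:
        prev, l1, l2 = config.binary_specs[name]
        h2 = l1 * l1 + l2 * l2
        liab = l1 * svd + l2 * f2 + np.sqrt(1.0 - h2) * rng.standard_normal(n)
        from scipy.stats import norm

        df[name] = (liab > norm.ppf(1.0 - prev)).astype(int)

    # --- volumes, demographics, risk factors ----------------------------
    _, gm_mean, gm_sd = cov_specs["gm_volume"]
    df["gm_volume"] = gm_mean + gm_sd * gm_z
    _, icv_mean, icv_sd = cov_specs["icv"]
    df["icv"] = icv_mean + icv_sd * rng.standard_normal(n)
    _, age_mean, age_sd = cov_specs["age"]
    df["age"] = age_mean + age_sd * age_z

    sex_spec = cov_specs["sex"]
    df["sex"] = rng.choice(sex_spec[1], size=n, p=sex_spec[2])
    race_spec = cov_specs["race_ethnicity"]
    df["race_ethnicity"] = rng.choice(race_spec[1], size=n, p=race_spec[2])
    edu_spec = cov_specs["education"]
    df["education"] = rng.choice(edu_spec[1], size=n, p=edu_spec[2])
    df["site"] = site_labels
    lang_spec = cov_specs["language"]
    df["language"] = rng.choice(lang_spec[1], size=n, p=lang_spec[2])

    rho = config.age_frs_correlation
    _, frs_mean, frs_sd = cov_specs["frs"]
    frs_z = rho * age_z + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    df["frs"] = frs_mean + frs_sd * frs_z
    _, sbp_mean, sbp_sd = cov_specs["sbp"]
    df["sbp"] = sbp_mean + sbp_sd * rng.standard_normal(n)
    for name in (
        "antihypertensive_use", "diabetes", "hyperlipidemia",
        "current_smoking", "current_alcohol", "apoe4_carrier", "mri_first",
    ):
        df[name] = (rng.random(n) < cov_specs[name][1]).astype(int)
    whr = np.where(
        df["sex"] == "female",
        0.90 + 0.08 * rng.standard_normal(n),
        0.97 + 0.06 * rng.standard_normal(n),
    )
    df["whr"] = whr
    _, pa_mu, pa_sigma = cov_specs["physical_activity"]
    df["physical_activity"] = np.exp(pa_mu + pa_sigma * rng.standard_normal(n))
    _, iv_mean, iv_sd = cov_specs["mri_cog_interval_years"]
    df["mri_cog_interval_years"] = np.maximum(iv_mean + iv_sd * rng.standard_normal(n), 0.0)

    # --- cognitive battery ----------------------------------------------
    lam_c = config.test_loading
    for t in COGNITIVE_TESTS:
        df[t] = (
            config.test_shift
            + lam_c * cognition
            + np.sqrt(1.0 - lam_c * lam_c) * rng.standard_normal(n)
        )
    cutoff = np.quantile(cognition, 1.0 - config.normal_fraction)
    df["cognitively_normal"] = (cognition >= cutoff).astype(int)

    df["latent_svd"] = svd
    df["latent_f2"] = f2
    df["latent_cognition"] = cognition
    df["latent_gm_z"] = gm_z
    df["age_z"] = age_z

    # --- optional MCAR missingness --------------------------------------
    for col, rate in config.mcar_rates.items():
        if rate > 0:
            mask = rng.random(n) < rate
            df.loc[mask, col] = np.nan

    return df


def generate_factor_model_sample(
    loadings: pd.DataFrame | np.ndarray,
    n: int,
    seed: int,
    factor_correlation=None,
) -> pd.DataFrame:
    """Draw standardized indicators from ``z = Lambda f + Psi^{1/2} eps``.

    Uniquenesses are set for unit variances.  Used for loading-recovery
    experiments where the indicators are wanted directly on the z scale,
    without the raw-unit rescaling of the full cohort generator.
    """
    if isinstance(loadings, pd.DataFrame):
        names = list(loadings.index)
        L = loadings.to_numpy(dtype=float)
    else:
        L = np.asarray(loadings, dtype=float)
        names = [f"v{i+1}" for i in range(L.shape[0])]
    p, k = L.shape
    phi = np.eye(k) if factor_correlation is None else np.asarray(factor_correlation, float)
    h2 = np.diag(L @ phi @ L.T)
    if np.any(h2 > 1.0):
        raise ConfigurationError("communality > 1 (Heywood configuration)")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(phi + 1e-12 * np.eye(k))
    F = rng.standard_normal((n, k)) @ chol.T
    Z = F @ L.T + rng.standard_normal((n, p)) * np.sqrt(1.0 - h2)
    return pd.DataFrame(Z, columns=names)


@dataclass
class PreparationRecord:
    """Transformation parameters fitted by :func:`prepare_markers`."""

    means: dict
    sds: dict
    tukey_lambdas: dict
    tukey_shifts: dict
    dichotomized: list


def prepare_markers(
    table: pd.DataFrame,
    tukey_columns: tuple = tuple(WMH_MARKERS),
    record: PreparationRecord | None = None,
) -> tuple[pd.DataFrame, PreparationRecord]:
    """Prepare MRI markers for factor analysis.

    Continuous markers are converted to z-scores to unify their scales;
    right-skewed volume markers (the WMH compartments by default) first pass
    through the Tukey ladder-of-powers transformation; MB counts are
    dichotomized to presence/absence.  Fitted parameters are returned so the
    identical transformation can be replayed on new data (pass ``record``).
    """
    out = table.copy()
    if record is None:
        record = PreparationRecord({}, {}, {}, {}, list(BINARY_MARKERS))
        fit = True
    else:
        fit = False
    for col in CONTINUOUS_MARKERS:
        if col not in out.columns:
            raise KeyError(f"required marker column {col!r} missing")
        x = out[col].to_numpy(dtype=float)
        if col in tukey_columns:
            if fit:
                lam, shift, x = tukey_ladder(x, return_shift=True)
                record.tukey_lambdas[col] = lam
                record.tukey_shifts[col] = shift
            else:
                lam = record.tukey_lambdas[col]
                shift = record.tukey_shifts[col]
                x = _apply_tukey(x + shift, lam)
        if fit:
            m, s = float(np.nanmean(x)), float(np.nanstd(x, ddof=0))
            if not np.isfinite(s) or s <= 1e-12 * max(1.0, abs(m)):
                raise ValueError(f"marker column {col!r} has zero variance")
            record.means[col], record.sds[col] = m, s
        out[col] = (x - record.means[col]) / record.sds[col]
    for col in BINARY_MARKERS:
        out[col] = (out[col].to_numpy(dtype=float) > 0).astype(int)
    return out, record


def _apply_tukey(x, lam):
    if lam == 0:
        return np.log(x)
    if lam < 0:
        return -np.power(x, lam)
    return np.power(x, lam)


def marker_kinds(columns=ALL_MARKERS) -> dict:
    """Per-marker measurement kind tags used by the mixed correlation matrix."""
    return {c: ("binary" if c in BINARY_MARKERS else "continuous") for c in columns}
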