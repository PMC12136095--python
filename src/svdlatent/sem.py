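"""Structural equation models for latent-mediator analyses.

A small covariance-structure engine in the RAM parameterization: variables
(latent + observed) are connected by directed paths (matrix A) and symmetric
(co)variances (matrix S); the model-implied covariance of the observed block
is ``Sigma = F (I-A)^{-1} S (I-A)^{-T} F'``.  Maximum-likelihood estimation
minimizes the normal-theory discrepancy

    F_ML = log|Sigma| + tr(S_sample Sigma^{-1}) - log|S_sample| - p

with an analytic gradient; chi-square is (n-1) F_ML at the optimum.
Equality constraints are expressed by sharing parameter labels, which is
also how multi-group invariance models are built (see
:mod:`svdlatent.invariance`).

The mediation layer decomposes the total effect of an exposure on cognition
into the direct path and pathway-specific indirect effects (products of
standardized path coefficients along every directed route), with
bias-corrected bootstrap confidence intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Indicators of the latent SVD construct, and the same-modality residual
#: covariance pairs (shared method variance).
SVD_INDICATORS = [
    "pvs_basal_ganglia",
    "pvs_thalamus",
    "wmh_periventricular",
    "wmh_subcortical",
    "wm_fa",
    "wm_tr",
]
RESIDUAL_COVARIANCE_PAIRS = [
    ("pvs_basal_ganglia", "pvs_thalamus"),
    ("wmh_periventricular", "wmh_subcortical"),
    ("wm_fa", "wm_tr"),
]


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------
@dataclass
class Parameter:
    matrix: str          # "A" (directed) or "S" (symmetric)
    row: str
    col: str
    label: str | None    # None => fixed
    value: float = 0.0   # fixed value or starting value
    lower: float | None = None


@dataclass
class SemModelSpec:
    """Latent/measurement/structural declarations for one group."""

    observed: list
    latent: list = field(default_factory=list)
    params: list = field(default_factory=list)

    def add_loading(self, latent, indicator, label=None, value=0.5):
        self.params.append(Parameter("A", indicator, latent, label, value))

    def add_regression(self, outcome, predictor, label=None, value=0.0):
        self.params.append(Parameter("A", outcome, predictor, label, value))

    def add_variance(self, name, label=None, value=1.0, lower=1e-6):
        self.params.append(Parameter("S", name, name, label, value, lower))

    def add_covariance(self, a, b, label=None, value=0.0):
        self.params.append(Parameter("S", a, b, label, value))

    @property
    def variables(self):
        return self.latent + self.observed

    def validate(self):
        labels = [p.label for p in self.params if p.label is not None]
        seen, dup = set(), set()
        for lab in labels:
            if lab in seen:
                dup.add(lab)
            seen.add(lab)
        # duplicate labels on *distinct* entries are equality constraints and
        # legal; a duplicate on the same (matrix,row,col) cell is an error
        cells = {}
        for p in self.params:
            key = (p.matrix, p.row, p.col) if p.matrix == "A" else (
                "S", *sorted((p.row, p.col)))
            if key in cells:
                raise ValueError(f"duplicate parameter declaration for {key}")
            cells[key] = p
        for v in self.latent:
            has_ind = any(p.matrix == "A" and p.col == v and p.row in self.observed
                          for p in self.params)
            has_var = any(p.matrix == "S" and p.row == v and p.col == v
                          for p in self.params)
            if not (has_ind and has_var):
                raise ValueError(
                    f"latent variable {v!r} under-identified: needs indicators "
                    "and a (fixed or free) variance")


class SemModel:
    """Compiled single-group model: theta -> Sigma(theta) with gradients."""

    def __init__(self, spec: SemModelSpec, shared_labels: dict | None = None):
        spec.validate()
        self.spec = spec
        self.vars = spec.variables
        self.nv = len(self.vars)
        self.obs_idx = np.array([self.vars.index(v) for v in spec.observed])
        self.idx = {v: i for i, v in enumerate(self.vars)}
        # free-parameter bookkeeping: label -> position in theta
        self.labels: list = []
        self.start: list = []
        self.bounds: list = []
        pos = {} if shared_labels is None else shared_labels
        self._entries = []  # (matrix, i, j, theta_pos or None, fixed_value)
        for p in spec.params:
            i, j = self.idx[p.row], self.idx[p.col]
            if p.label is None:
                self._entries.append((p.matrix, i, j, None, p.value))
                continue
            if p.label not in pos:
                pos[p.label] = len(pos)
                self.labels.append(p.label)
                self.start.append(p.value)
                self.bounds.append((p.lower, None))
            self._entries.append((p.matrix, i, j, pos[p.label], p.value))
        self.label_pos = pos

    @property
    def n_free(self) -> int:
        return len(set(t for (_, _, _, t, _) in self._entries if t is not None))

    def matrices(self, theta: np.ndarray):
        A = np.zeros((self.nv, self.nv))
        S = np.zeros((self.nv, self.nv))
        for m, i, j, t, v in self._entries:
            val = v if t is None else theta[t]
            if m == "A":
                A[i, j] = val
            else:
                S[i, j] = val
                S[j, i] = val
        return A, S

    def implied(self, theta: np.ndarray):
        A, S = self.matrices(theta)
        B = np.linalg.inv(np.eye(self.nv) - A)
        full = B @ S @ B.T
        sigma = full[np.ix_(self.obs_idx, self.obs_idx)]
        return sigma, full, A, S, B

    def discrepancy_and_grad(self, theta, S_sample, n_theta):
        """F_ML and dF/dtheta (length n_theta; zeros for foreign labels)."""
        sigma, _full, A, S, B = self.implied(theta)
        p = sigma.shape[0]
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.inf, np.zeros(n_theta)
        sigma_inv = np.linalg.inv(sigma)
        _, logdet_s = np.linalg.slogdet(S_sample)
        F = logdet + float(np.trace(S_sample @ sigma_inv)) - logdet_s - p
        W = sigma_inv - sigma_inv @ S_sample @ sigma_inv  # dF = tr(W dSigma)
        G1 = np.zeros((self.nv, self.nv))
        G1[np.ix_(self.obs_idx, self.obs_idx)] = W
        BtG1B = B.T @ G1 @ B            # S-parameter gradients: tr(W F B E B'F')
        Q = B @ S @ BtG1B               # A-parameter gradients: 2 Q[src, dst]
        grad = np.zeros(n_theta)
        for m, i, j, t, _v in self._entries:
            if t is None:
                continue
            if m == "S":
                g = BtG1B[i, j] * (1.0 if i == j else 2.0)
            else:
                # A[i, j] is the path j -> i; dB = B E_{ij} B
                g = 2.0 * Q[j, i]
            grad[t] += g
        return F, grad

    def standardize(self, theta):
        """Completely standardized solution: paths scaled by implied SDs."""
        _sigma, full, A, S, _B = self.implied(theta)
        sd = np.sqrt(np.maximum(np.diag(full), 1e-12))
        out = {}
        for m, i, j, t, v in self._entries:
            val = v if t is None else theta[t]
            if m == "A":
                out[("A", self.vars[i], self.vars[j])] = val * sd[j] / sd[i]
            else:
                out[("S", self.vars[i], self.vars[j])] = val / (sd[i] * sd[j])
        return out


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------
@dataclass
class SemFit:
    model: "SemModel"
    theta: np.ndarray
    labels: list
    sigma: np.ndarray
    s_sample: np.ndarray
    n_obs: int
    fmin: float
    chi2: float
    df: int
    chi2_baseline: float
    df_baseline: int
    cfi: float
    rmsea: float
    srmr: float
    converged: bool
    heywood: bool
    estimates: dict = field(default_factory=dict)      # label -> value
    standardized: dict = field(default_factory=dict)   # (matrix, row, col) -> value

    @property
    def p_value(self) -> float:
        return float(stats.chi2.sf(self.chi2, self.df)) if self.df > 0 else 1.0

    def r_squared(self, variable: str) -> float:
        """1 - standardized residual variance of an endogenous variable."""
        resid = self.standardized.get(("S", variable, variable))
        if resid is None:
            raise KeyError(f"no residual variance parameter for {variable!r}")
        return 1.0 - resid

    def standard_errors(self) -> pd.Series:
        """Asymptotic SEs from the numerical Hessian of the discrepancy."""
        nt = len(self.theta)
        H = np.zeros((nt, nt))
        eps = 1e-5
        for a in range(nt):
            tp = self.theta.copy(); tp[a] += eps
            tm = self.theta.copy(); tm[a] -= eps
            _, gp = self.model.discrepancy_and_grad(tp, self.s_sample, nt)
            _, gm = self.model.discrepancy_and_grad(tm, self.s_sample, nt)
            H[a] = (gp - gm) / (2 * eps)
        H = (H + H.T) / 2
        cov = 2.0 / (self.n_obs - 1) * np.linalg.pinv(H)
        return pd.Series(np.sqrt(np.maximum(np.diag(cov), 0.0)), index=self.labels)


def fit_indices(chi2, df, chi2_baseline, df_baseline, n, residuals=None):
    """CFI, RMSEA and (if standardized residuals are given) SRMR.

    CFI = 1 - max(chi2-df, 0)/max(chi2_b-df_b, chi2-df, 0);
    RMSEA = sqrt(max(chi2-df, 0)/(df (n-1))), defined as 0 when df = 0.
    """
    num = max(chi2 - df, 0.0)
    den = max(chi2_baseline - df_baseline, chi2 - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    rmsea = float(np.sqrt(num / (df * (n - 1)))) if df > 0 else 0.0
    srmr = None
    if residuals is not None:
        r = np.asarray(residuals, float)
        iu = np.triu_indices(r.shape[0])
        srmr = float(np.sqrt(np.mean(r[iu] ** 2)))
    return cfi, rmsea, srmr


def _standardized_residuals(S_sample, sigma):
    d = np.sqrt(np.outer(np.diag(S_sample), np.diag(S_sample)))
    return (S_sample - sigma) / d


def pc1_loading_starts(model: "SemModel", spec: SemModelSpec, S_sample: np.ndarray,
                       start: np.ndarray) -> np.ndarray:
    """Seed loading parameters from the first principal component.

    All-positive constant starts can trap quasi-Newton iterations in a local
    minimum when an indicator's true loading is negative (the white-matter
    FA indicator loads negatively on SVD); PC1 of the indicator correlation
    block gets the sign pattern right.
    """
    start = start.copy()
    d = np.sqrt(np.diag(S_sample))
    R = S_sample / np.outer(d, d)
    obs_pos = {v: i for i, v in enumerate(spec.observed)}
    for latent in spec.latent:
        inds = [p.row for p in spec.params
                if p.matrix == "A" and p.col == latent and p.row in obs_pos]
        if len(inds) < 2:
            continue
        ii = [obs_pos[v] for v in inds]
        w, V = np.linalg.eigh(R[np.ix_(ii, ii)])
        v1 = V[:, -1] * np.sqrt(max(w[-1], 0.0))
        if v1[np.argmax(np.abs(v1))] < 0:
            v1 = -v1
        for v, lam in zip(inds, v1):
            for p in spec.params:
                if p.matrix == "A" and p.col == latent and p.row == v and p.label is not None:
                    start[model.label_pos[p.label]] = float(np.clip(lam, -0.95, 0.95))
            for p in spec.params:
                if (p.matrix == "S" and p.row == v and p.col == v
                        and p.label is not None):
                    start[model.label_pos[p.label]] = float(max(1.0 - lam**2, 0.1))
    return start


def fit_ml(
    S_sample,
    n: int,
    spec: SemModelSpec,
    max_starts: int = 3,
    seed: int = 0,
) -> SemFit:
    """Fit a model to a sample covariance matrix by normal-theory ML.

    Quasi-Newton (L-BFGS-B) on the free parameters with the analytic
    gradient; on non-convergence up to ``max_starts`` jittered restarts.
    Residual variances are bounded below at 1e-6; a solution on that bound
    is flagged as a Heywood case with a warning.
    """
    if isinstance(S_sample, pd.DataFrame):
        S_sample = S_sample.loc[spec.observed, spec.observed].to_numpy()
    S_sample = np.asarray(S_sample, float)
    p = len(spec.observed)
    if S_sample.shape != (p, p):
        raise ValueError("sample covariance does not match the observed variables")
    if n <= p:
        raise ValueError("need n > number of observed variables")
    model = SemModel(spec)
    nt = len(model.start)
    theta0 = pc1_loading_starts(model, spec, S_sample, np.array(model.start, float))
    bounds = model.bounds
    rng = np.random.default_rng(seed)

    best = None
    for attempt in range(max_starts):
        start = theta0 if attempt == 0 else theta0 + 0.1 * rng.standard_normal(nt)
        start = np.array(
            [max(s, b[0]) if b[0] is not None else s for s, b in zip(start, bounds)]
        )
        res = optimize.minimize(
            model.discrepancy_and_grad,
            start,
            args=(S_sample, nt),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success and np.isfinite(res.fun):
            best = res if res.fun <= best.fun else best
            break
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("SEM fit failed to converge from all starts")
    theta = best.x
    heywood = any(
        b[0] is not None and theta[i] <= b[0] + 1e-9 for i, b in enumerate(bounds)
    )
    if heywood:
        warnings.warn("Heywood case: a residual variance hit its lower bound", RuntimeWarning)

    sigma, *_ = model.implied(theta)
    fmin = float(best.fun)
    chi2 = max((n - 1) * fmin, 0.0)
    df = p * (p + 1) // 2 - model.n_free
    if df < 0:
        raise ValueError("negative degrees of freedom: model not identified")
    # independence baseline
    _, logdet_s = np.linalg.slogdet(S_sample)
    f_b = float(np.sum(np.log(np.diag(S_sample))) - logdet_s)
    chi2_b = max((n - 1) * f_b, 0.0)
    df_b = p * (p - 1) // 2
    resid = _standardized_residuals(S_sample, sigma)
    cfi, rmsea, srmr = fit_indices(chi2, df, chi2_b, df_b, n, resid)
    estimates = {lab: float(theta[model.label_pos[lab]]) for lab in model.labels}
    fit = SemFit(
        model=model, theta=theta, labels=model.labels, sigma=sigma,
        s_sample=S_sample, n_obs=n, fmin=fmin, chi2=chi2, df=df,
        chi2_baseline=chi2_b, df_baseline=df_b, cfi=cfi, rmsea=rmsea,
        srmr=srmr, converged=bool(best.success or fmin < 1e-10),
        heywood=heywood, estimates=estimates,
    )
    fit.standardized = model.standardize(theta)
    return fit


def implied_covariance(spec: SemModelSpec, values: dict) -> pd.DataFrame:
    """Population covariance of the observed variables at given parameter
    values (labels -> value); the analytic path-tracing oracle."""
    model = SemModel(spec)
    theta = np.array([values[lab] for lab in model.labels], float)
    sigma, *_ = model.implied(theta)
    return pd.DataFrame(sigma, index=spec.observed, columns=spec.observed)


def simulate_from_spec(spec: SemModelSpec, values: dict, n: int, seed: int) -> pd.DataFrame:
    """Draw multivariate-normal data with the model-implied covariance."""
    sigma = implied_covariance(spec, values).to_numpy()
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(np.zeros(len(spec.observed)), sigma, size=n,
                                method="cholesky")
    return pd.DataFrame(X, columns=spec.observed)


# --------------------------------------------------------------------------
# canonical model builders
# --------------------------------------------------------------------------
def measurement_spec(
    indicators=None,
    residual_pairs=None,
    latent: str = "svd",
    group_tag: str = "",
    shared_loadings: bool = False,
    latent_variance: float | None = 1.0,
) -> SemModelSpec:
    """Single-latent measurement model with same-modality residual covariances.

    ``latent_variance=None`` frees the latent variance (used by metric-level
    multi-group models in non-reference groups); otherwise it is fixed,
    identifying the scale so loadings are standardized when data are.
    """
    indicators = list(indicators or SVD_INDICATORS)
    residual_pairs = residual_pairs if residual_pairs is not None else [
        (a, b) for a, b in RESIDUAL_COVARIANCE_PAIRS if a in indicators and b in indicators
    ]
    spec = SemModelSpec(observed=indicators, latent=[latent])
    tag = group_tag
    for ind in indicators:
        lab = f"l_{ind}" if shared_loadings else f"l_{ind}{tag}"
        spec.add_loading(latent, ind, lab, value=0.6)
    if latent_variance is None:
        spec.add_variance(latent, f"psi_{latent}{tag}", value=1.0, lower=1e-6)
    else:
        spec.params.append(Parameter("S", latent, latent, None, latent_variance))
    for ind in indicators:
        spec.add_variance(ind, f"e_{ind}{tag}", value=0.5)
    for a, b in residual_pairs:
        spec.add_covariance(a, b, f"c_{a}_{b}{tag}", value=0.05)
    return spec


def mediation_spec(
    x: str = "age",
    mediator_indicators=None,
    covariates: list | None = None,
    outcome: str = "cognition",
    gm: str = "gm",
) -> SemModelSpec:
    """Latent-SVD mediation model.

    Structural layer: x -> SVD, x -> GM, SVD -> GM, SVD -> outcome,
    GM -> outcome, x -> outcome (direct).  Optional exogenous covariates get
    paths to all three endogenous variables and a saturated covariance block
    with x.
    """
    spec = measurement_spec(mediator_indicators)
    covariates = list(covariates or [])
    spec.observed = spec.observed + [gm, outcome, x] + covariates
    spec.add_regression("svd", x, "b_svd_x")
    spec.add_regression(gm, x, "b_gm_x")
    spec.add_regression(gm, "svd", "b_gm_svd")
    spec.add_regression(outcome, "svd", "b_cog_svd")
    spec.add_regression(outcome, gm, "b_cog_gm")
    spec.add_regression(outcome, x, "b_cog_x")
    # once svd is endogenous its scale is identified by fixing the *residual*
    # variance at 1 (the latent-standardization convention); the reported
    # solution is standardized afterwards either way
    spec.params = [p for p in spec.params
                   if not (p.matrix == "S" and p.row == "svd" and p.col == "svd")]
    spec.params.append(Parameter("S", "svd", "svd", None, 1.0))
    spec.add_variance(gm, f"e_{gm}", value=0.9)
    spec.add_variance(outcome, f"e_{outcome}", value=0.9)
    spec.add_variance(x, f"v_{x}", value=1.0)
    for i, c in enumerate(covariates):
        spec.add_variance(c, f"v_{c}", value=1.0)
        spec.add_covariance(c, x, f"cv_{c}_{x}")
        for d in covariates[:i]:
            spec.add_covariance(c, d, f"cv_{c}_{d}")
        spec.add_regression("svd", c, f"b_svd_{c}")
        spec.add_regression(gm, c, f"b_gm_{c}")
        spec.add_regression(outcome, c, f"b_cog_{c}")
    return spec


# --------------------------------------------------------------------------
# effect decomposition
# --------------------------------------------------------------------------
@dataclass
class EffectDecomposition:
    x: str
    outcome: str
    direct: float
    pathways: dict                 # "x->svd->cognition" -> effect
    total_indirect: float
    total: float
    proportion_mediated: dict      # pathway (and "total_indirect") -> percent of total
    cis: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        out = {"direct": self.direct, **self.pathways,
               "total_indirect": self.total_indirect, "total": self.total}
        return pd.Series(out)


def combine_effects(direct: float, pathways: dict, x="x", outcome="y") -> EffectDecomposition:
    """Assemble a decomposition from a direct effect and pathway-specific
    indirect effects.  total = direct + sum(pathways) identically."""
    total_indirect = float(sum(pathways.values()))
    total = float(direct + total_indirect)
    if total == 0.0:
        warnings.warn("total effect is zero; proportion mediated undefined", RuntimeWarning)
        prop = {k: np.nan for k in pathways}
        prop["total_indirect"] = np.nan
    else:
        prop = {k: 100.0 * v / total for k, v in pathways.items()}
        prop["total_indirect"] = 100.0 * total_indirect / total
    return EffectDecomposition(
        x=x, outcome=outcome, direct=float(direct), pathways=dict(pathways),
        total_indirect=total_indirect, total=total, proportion_mediated=prop,
    )


def _structural_paths(fit: SemFit) -> dict:
    """Standardized directed edges, keyed (src, dst)."""
    edges = {}
    for (m, dst, src), val in fit.standardized.items():
        if m == "A":
            edges[(src, dst)] = val
    return edges


def decompose_effects(fit: SemFit, x: str, outcome: str = "cognition") -> EffectDecomposition:
    """Enumerate every directed path from exposure to outcome in the fitted
    (acyclic) graph; each pathway effect is the product of its standardized
    coefficients.  Indicator nodes are sinks and never lie on such paths."""
    edges = _structural_paths(fit)
    adj: dict = {}
    for (src, dst), val in edges.items():
        adj.setdefault(src, []).append(dst)

    pathways = {}
    direct = edges.get((x, outcome), 0.0)

    def walk(node, path, prod):
        if node == outcome:
            if len(path) > 2:
                pathways["->".join(path)] = prod
            return
        for nxt in adj.get(node, []):
            if nxt in path:
                continue
            walk(nxt, path + [nxt], prod * edges[(node, nxt)])

    walk(x, [x], 1.0)
    dec = combine_effects(direct, pathways, x=x, outcome=outcome)
    return dec


# --------------------------------------------------------------------------
# bias-corrected bootstrap
# --------------------------------------------------------------------------
def bootstrap_bc_ci(
    table: pd.DataFrame,
    stat_fn,
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    max_failure_rate: float = 0.10,
):
    """Nonparametric case-resampling bootstrap with bias-corrected CIs.

    ``stat_fn(df) -> dict[str, float]``.  The bias correction is
    z0 = Phi^{-1}(fraction of resamples below the point estimate); endpoints
    are the Phi(2 z0 +/- z_{alpha/2}) percentiles of the bootstrap
    distribution.  With a symmetric distribution about the estimate
    (z0 = 0) this reduces to plain percentile intervals.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    point = stat_fn(table)
    keys = list(point)
    rng = np.random.default_rng(seed)
    n = len(table)
    draws = {k: [] for k in keys}
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            val = stat_fn(table.iloc[idx])
        except Exception:
            failures += 1
            continue
        for k in keys:
            draws[k].append(val[k])
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap resamples failed")
    z_lo, z_hi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
    out = {}
    for k in keys:
        arr = np.asarray(draws[k], float)
        est = point[k]
        if np.ptp(arr) == 0.0:
            warnings.warn(f"statistic {k!r} constant across resamples; zero-width CI",
                          RuntimeWarning)
            out[k] = (est, float(arr[0]), float(arr[0]))
            continue
        frac = np.mean(arr < est) + 0.5 * np.mean(arr == est)
        frac = min(max(frac, 1.0 / (len(arr) + 1)), 1.0 - 1.0 / (len(arr) + 1))
        z0 = stats.norm.ppf(frac)
        lo_q = stats.norm.cdf(2 * z0 + z_lo)
        hi_q = stats.norm.cdf(2 * z0 + z_hi)
        lo, hi = np.quantile(arr, [lo_q, hi_q])
        out[k] = (float(est), float(lo), float(hi))
    return out


# --------------------------------------------------------------------------
# latent vs single-indicator comparison
# --------------------------------------------------------------------------
def _path_only_spec(x: str, mediator: str, outcome: str = "cognition", gm: str = "gm") -> SemModelSpec:
    spec = SemModelSpec(observed=[mediator, gm, outcome, x])
    spec.add_regression(mediator, x, "b_m_x")
    spec.add_regression(gm, x, "b_gm_x")
    spec.add_regression(gm, mediator, "b_gm_m")
    spec.add_regression(outcome, mediator, "b_cog_m")
    spec.add_regression(outcome, gm, "b_cog_gm")
    spec.add_regression(outcome, x, "b_cog_x")
    spec.add_variance(mediator, "e_m", value=0.9)
    spec.add_variance(gm, "e_gm", value=0.9)
    spec.add_variance(outcome, "e_cog", value=0.9)
    spec.add_variance(x, "v_x", value=1.0)
    return spec


def single_indicator_comparison(
    table: pd.DataFrame,
    x: str,
    indicators=None,
    outcome: str = "cognition",
    gm: str = "gm",
    seed: int = 0,
) -> pd.DataFrame:
    """Refit the structural model with each observed indicator replacing the
    latent mediator; report indirect-via-mediator effects and outcome R^2
    next to the latent-SVD model.

    Measurement error attenuates single-indicator mediation, so the latent
    model is expected to show the largest indirect effect and R^2.
    """
    indicators = list(indicators or SVD_INDICATORS)
    cols = indicators + [gm, outcome, x]
    data = table[cols].dropna()
    n = len(data)
    rows = []

    spec = mediation_spec(x=x, mediator_indicators=indicators, outcome=outcome, gm=gm)
    S = data[spec.observed].astype(float).corr()
    fit = fit_ml(S, n, spec, seed=seed)
    dec = decompose_effects(fit, x, outcome)
    via = sum(v for kpath, v in dec.pathways.items() if "svd" in kpath)
    rows.append({"mediator": "latent_svd", "indirect_via_mediator": via,
                 "outcome_r2": fit.r_squared(outcome), "chi2": fit.chi2, "df": fit.df})

    for ind in indicators:
        pspec = _path_only_spec(x, ind, outcome, gm)
        Si = data[pspec.observed].astype(float).corr()
        pfit = fit_ml(Si, n, pspec, seed=seed)
        pdec = decompose_effects(pfit, x, outcome)
        via_i = sum(v for kpath, v in pdec.pathways.items() if ind in kpath)
        rows.append({"mediator": ind, "indirect_via_mediator": via_i,
                     "outcome_r2": pfit.r_squared(outcome), "chi2": pfit.chi2, "df": pfit.df})
    return pd.DataFrame(rows).set_index("mediator")
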