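"""Multi-group CFA measurement-invariance testing across study sites.

Ladder of nested models for the single-latent SVD measurement model:

* ``configural`` — same factor structure per site; loadings, residual
  variances and same-modality residual covariances free in every group,
  latent variance fixed at 1 in every group.
* ``metric`` — loadings constrained equal across sites; the latent variance
  stays fixed at 1 in the first (reference) group and is freed in the rest.
* ``residual`` — additionally equal residual variances across sites and the
  latent variance fixed at 1 in all groups (equal indicator reliability);
  residual covariances stay group-specific.

With 6 sites and 6 indicators these conventions give 36, 61 and 96 model
degrees of freedom respectively.  Nested levels are compared with a
likelihood-ratio test; the scaled chi-square difference statistic is
implemented so externally supplied robust scaling factors can be used
(plain ML corresponds to scaling factors of 1, where the statistic reduces
to the simple chi-square difference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sem import (
    SemModel,
    SemModelSpec,
    SVD_INDICATORS,
    fit_indices,
    measurement_spec,
    _standardized_residuals,
)

LEVELS = ("configural", "metric", "residual")


@dataclass
class MultiGroupFit:
    level: str
    groups: list
    theta: np.ndarray
    labels: list
    fmin: float
    chi2: float
    df: int
    n_free: int
    n_total: int
    cfi: float
    rmsea: float
    srmr: float
    converged: bool
    group_estimates: dict = field(default_factory=dict)
    scaling_factor: float = 1.0


def _group_specs(groups, indicators, level: str):
    specs = []
    for gi, g in enumerate(groups):
        tag = f"__{g}"
        if level == "configural":
            spec = measurement_spec(indicators, group_tag=tag, latent_variance=1.0)
        elif level == "metric":
            spec = measurement_spec(
                indicators,
                group_tag=tag,
                shared_loadings=True,
                latent_variance=1.0 if gi == 0 else None,
            )
        elif level == "residual":
            spec = measurement_spec(indicators, group_tag=tag, shared_loadings=True,
                                    latent_variance=1.0)
            # share residual variances across groups (drop the group tag)
            for p in spec.params:
                if p.label is not None and p.label.startswith("e_"):
                    p.label = p.label[: -len(tag)]
        else:
            raise ValueError(f"unknown invariance level {level!r}")
        specs.append(spec)
    return specs


def fit_multigroup(
    table: pd.DataFrame,
    group_column: str = "site",
    level: str = "configural",
    indicators=None,
    seed: int = 0,
) -> MultiGroupFit:
    """Joint ML fit of the measurement model over the groups of
    ``group_column`` with the equality constraints of ``level``."""
    indicators = list(indicators or SVD_INDICATORS)
    p = len(indicators)
    groups = sorted(table[group_column].dropna().unique())
    covs, ns = [], []
    for g in groups:
        sub = table.loc[table[group_column] == g, indicators].dropna()
        if len(sub) <= p:
            raise ValueError(f"group {g!r} has n={len(sub)} <= {p} observed variables")
        covs.append(sub.astype(float).cov().to_numpy())
        ns.append(len(sub))
    specs = _group_specs(groups, indicators, level)

    shared: dict = {}
    models = [SemModel(s, shared_labels=shared) for s in specs]
    labels = [None] * len(shared)
    for lab, posn in shared.items():
        labels[posn] = lab
    nt = len(shared)
    start = np.zeros(nt)
    bounds: list = [(None, None)] * nt
    for m in models:
        for lab, s0, b in zip(m.labels, m.start, m.bounds):
            start[m.label_pos[lab]] = s0
            bounds[m.label_pos[lab]] = b
    from .sem import pc1_loading_starts

    for m, s, S_g in zip(models, specs, covs):
        start = pc1_loading_starts(m, s, S_g, start)

    n_tot = sum(ns)
    w = [(n_g - 1) / (n_tot - len(groups)) for n_g in ns]

    def objective(theta):
        F, G = 0.0, np.zeros(nt)
        for m, S_g, w_g in zip(models, covs, w):
            f_g, g_g = m.discrepancy_and_grad(theta, S_g, nt)
            F += w_g * f_g
            G += w_g * g_g
        return F, G

    best = None
    rng = np.random.default_rng(seed)
    for attempt in range(3):
        x0 = start if attempt == 0 else start + 0.05 * rng.standard_normal(nt)
        x0 = np.array([max(x, b[0]) if b[0] is not None else x for x, b in zip(x0, bounds)])
        res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 4000, "ftol": 1e-13, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    theta = best.x

    chi2 = 0.0
    srmr_parts = []
    fb_sum = 0.0
    for m, S_g, n_g in zip(models, covs, ns):
        f_g, _ = m.discrepancy_and_grad(theta, S_g, nt)
        chi2 += (n_g - 1) * f_g
        sigma_g, *_ = m.implied(theta)
        srmr_parts.append(_standardized_residuals(S_g, sigma_g))
        _, logdet = np.linalg.slogdet(S_g)
        fb_sum += (n_g - 1) * (np.sum(np.log(np.diag(S_g))) - logdet)
    chi2 = max(float(chi2), 0.0)
    n_free = len(shared)
    df = len(groups) * p * (p + 1) // 2 - n_free
    chi2_b = max(float(fb_sum), 0.0)
    df_b = len(groups) * p * (p - 1) // 2
    iu = np.triu_indices(p)
    resid_stack = np.concatenate([r[iu] for r in srmr_parts])
    cfi, rmsea, _ = fit_indices(chi2, df, chi2_b, df_b, n_tot)
    srmr = float(np.sqrt(np.mean(resid_stack**2)))

    est = {}
    for m, g in zip(models, groups):
        est[g] = {lab: float(theta[m.label_pos[lab]]) for lab in m.labels}
    return MultiGroupFit(
        level=level, groups=list(groups), theta=theta, labels=labels,
        fmin=float(best.fun), chi2=chi2, df=df, n_free=n_free, n_total=n_tot,
        cfi=cfi, rmsea=rmsea, srmr=srmr, converged=bool(best.success),
        group_estimates=est,
    )


def scaled_chisq_diff(
    chi2_restricted: float,
    df_restricted: int,
    chi2_free: float,
    df_free: int,
    scale_restricted: float = 1.0,
    scale_free: float = 1.0,
):
    """Satorra-Bentler-style scaled chi-square difference test.

    Inputs are the (possibly robust-scaled) test statistics with their
    scaling factors c; the difference scaling factor is
    ``cd = (df_r c_r - df_f c_f)/(df_r - df_f)`` and the statistic
    ``(T_r c_r - T_f c_f)/cd`` on ``df_r - df_f`` degrees of freedom.  With
    both scaling factors 1 (plain ML) this is simply ``T_r - T_f``.  A
    negative scaled difference is floored at 0 with a warning.
    """
    if df_restricted <= df_free:
        raise ValueError("models are not nested: restricted df must exceed free df")
    ddf = df_restricted - df_free
    cd = (df_restricted * scale_restricted - df_free * scale_free) / ddf
    if cd <= 0:
        raise ValueError("non-positive difference scaling factor")
    stat = (chi2_restricted * scale_restricted - chi2_free * scale_free) / cd
    if stat < 0:
        warnings.warn("negative scaled chi-square difference floored at 0", RuntimeWarning)
        stat = 0.0
    p = float(stats.chi2.sf(stat, ddf))
    return float(stat), int(ddf), p


@dataclass
class InvarianceLadder:
    fits: dict                    # level -> MultiGroupFit
    comparisons: pd.DataFrame     # one row per nested comparison

    def summary(self) -> pd.DataFrame:
        rows = []
        for level in LEVELS:
            f = self.fits[level]
            rows.append({"level": level, "chi2": f.chi2, "df": f.df,
                         "cfi": f.cfi, "rmsea": f.rmsea, "srmr": f.srmr,
                         "n_free": f.n_free})
        return pd.DataFrame(rows).set_index("level")


def invariance_ladder(
    table: pd.DataFrame,
    group_column: str = "site",
    indicators=None,
    seed: int = 0,
) -> InvarianceLadder:
    """Fit the full configural/metric/residual ladder and the nested
    likelihood-ratio comparisons between consecutive levels."""
    fits = {lvl: fit_multigroup(table, group_column, lvl, indicators, seed=seed)
            for lvl in LEVELS}
    rows = []
    for lo, hi in (("configural", "metric"), ("metric", "residual")):
        f_free, f_restr = fits[lo], fits[hi]
        stat, ddf, p = scaled_chisq_diff(
            f_restr.chi2, f_restr.df, f_free.chi2, f_free.df,
            f_restr.scaling_factor, f_free.scaling_factor,
        )
        rows.append({"comparison": f"{hi} vs {lo}", "statistic": stat,
                     "df": ddf, "p_value": p})
    return InvarianceLadder(fits=fits, comparisons=pd.DataFrame(rows).set_index("comparison"))
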