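"""Exploratory factor analysis of the MRI markers.

Minimum-residual (minres) extraction — no inversion of the correlation
matrix is required, which matters because mixed matrices containing
tetrachoric entries need not be positive definite — with VSS/MAP factor
selection, iterative low-communality pruning, an oblimin-then-varimax
rotation decision, salient-loading interpretation, extension analysis of the
excluded variables, and regression factor scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.multivariate.factor_rotation import rotate_factors

from .correlations import MixedCorrelationMatrix, mixed_matrix, kmo

SALIENCE_THRESHOLD = 0.32
ROTATION_PHI_THRESHOLD = 0.32


# --------------------------------------------------------------------------
# minres extraction
# --------------------------------------------------------------------------
@dataclass
class MinresResult:
    loadings: np.ndarray        # p x k, unrotated
    uniquenesses: np.ndarray
    communalities: np.ndarray
    objective: float            # sum of squared off-diagonal residuals
    converged: bool
    n_iter: int


def _ledermann_ok(p: int, k: int) -> bool:
    return (p - k) ** 2 >= p + k


def _loadings_given_psi(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    w, V = np.linalg.eigh(R - np.diag(psi))
    order = np.argsort(w)[::-1]
    w, V = w[order[:k]], V[:, order[:k]]
    return V * np.sqrt(np.maximum(w, 0.0))


def _offdiag_objective(R: np.ndarray, L: np.ndarray) -> float:
    res = R - L @ L.T
    np.fill_diagonal(res, 0.0)
    return float(np.sum(res**2)) / 2.0


def minres_fit(R, k: int, max_iter: int = 1000, tol: float = 1e-9) -> MinresResult:
    """Minimum-residual factor extraction.

    Minimizes the sum of squared off-diagonal residuals of ``R - L L'`` over
    uniquenesses (communalities constrained to [0, 1]); given uniquenesses,
    the optimal loadings come from the leading eigenpairs of the reduced
    matrix.  Starting communalities are squared multiple correlations from
    the (smoothed) matrix.
    """
    if isinstance(R, MixedCorrelationMatrix):
        Rs = R.smoothed_values()
        R = R.values
    else:
        R = np.asarray(R, float)
        Rs = R
    p = R.shape[0]
    if k < 1 or k >= p:
        raise ValueError("factor count must satisfy 1 <= k < p")
    if not _ledermann_ok(p, k):
        raise ValueError(f"k={k} exceeds the Ledermann bound for p={p} variables")

    # starting uniquenesses from squared multiple correlations
    try:
        inv = np.linalg.inv(Rs if np.linalg.eigvalsh(Rs).min() > 1e-8 else Rs + 1e-6 * np.eye(p))
        smc = 1.0 - 1.0 / np.diag(inv)
        psi0 = np.clip(1.0 - smc, 0.005, 1.0)
    except np.linalg.LinAlgError:
        psi0 = np.full(p, 0.5)

    def objective(psi):
        w, V = np.linalg.eigh(R - np.diag(psi))
        order = np.argsort(w)[::-1]
        resid_eigs = w[order[k:]]
        # off-diagonal objective: residual after removing top-k structure,
        # counting the (free) diagonal out via the residual eigenvalues
        L = V[:, order[:k]] * np.sqrt(np.maximum(w[order[:k]], 0.0))
        return _offdiag_objective(R, L)

    res = optimize.minimize(
        objective,
        psi0,
        method="L-BFGS-B",
        bounds=[(0.001, 1.0)] * p,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    psi = res.x
    L = _loadings_given_psi(R, psi, k)
    h2 = np.sum(L**2, axis=1)
    obj = _offdiag_objective(R, L)
    converged = bool(res.success) or obj < 1e-12
    if not converged and res.nit >= max_iter:
        raise RuntimeError(f"minres failed to converge after {res.nit} iterations (objective {obj:.3e})")
    return MinresResult(
        loadings=L,
        uniquenesses=1.0 - h2,
        communalities=h2,
        objective=obj,
        converged=converged,
        n_iter=int(res.nit),
    )


# --------------------------------------------------------------------------
# factor-count criteria
# --------------------------------------------------------------------------
def map_criterion(R, k_max: int) -> tuple[int, np.ndarray]:
    """Velicer's minimum average partial criterion.

    For each k the first k principal components are partialled out of R and
    the squared off-diagonal partial correlations averaged; the suggested
    count minimizes this average.  k = 0 (the average squared correlation of
    R itself minimal) flags "no common factors".
    """
    if isinstance(R, MixedCorrelationMatrix):
        R = R.values
    R = np.asarray(R, float)
    p = R.shape[0]
    if k_max >= p:
        raise ValueError("k_max must be < number of variables")
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    avgs = np.empty(k_max + 1)
    offdiag = ~np.eye(p, dtype=bool)
    avgs[0] = np.mean(R[offdiag] ** 2)
    for k in range(1, k_max + 1):
        A = V[:, :k] * np.sqrt(np.maximum(w[:k], 0.0))
        C = R - A @ A.T
        d = np.sqrt(np.diag(C))
        if np.any(d < 1e-8):
            avgs[k:] = np.inf
            break
        P = C / np.outer(d, d)
        avgs[k] = np.mean(P[offdiag] ** 2)
    k_best = int(np.argmin(avgs))
    if k_best == 0:
        warnings.warn("MAP criterion suggests no common factors", RuntimeWarning)
    return k_best, avgs


def vss_criterion(R, k_max: int, complexity: int = 1) -> tuple[int, np.ndarray]:
    """Very simple structure criterion.

    For each candidate k the minres solution is simplified to the largest
    ``complexity`` loadings per variable and scored
    ``1 - SS_offdiag(residual)/SS_offdiag(R)``; the suggested count is the
    argmax of the profile.
    """
    if complexity not in (1, 2):
        raise ValueError("complexity must be 1 or 2")
    if isinstance(R, MixedCorrelationMatrix):
        R = R.values
    R = np.asarray(R, float)
    p = R.shape[0]
    if k_max >= p:
        raise ValueError("k_max must be < number of variables")
    offdiag = ~np.eye(p, dtype=bool)
    ss_total = np.sum(R[offdiag] ** 2)
    profile = np.zeros(k_max)
    for k in range(1, k_max + 1):
        fit = minres_fit(R, k)
        L = fit.loadings
        if k >= 2:
            L, _ = rotate_factors(L, "varimax")
        Ls = np.zeros_like(L)
        keep = min(complexity, k)
        for i in range(p):
            idx = np.argsort(np.abs(L[i]))[::-1][:keep]
            Ls[i, idx] = L[i, idx]
        resid = R - Ls @ Ls.T
        profile[k - 1] = 1.0 - np.sum(resid[offdiag] ** 2) / ss_total
    return int(np.argmax(profile)) + 1, profile


def suggest_k(R, k_max: int) -> int:
    """Consensus factor count: VSS (complexity 1 and 2) and MAP; MAP governs
    on disagreement, with a warning."""
    k_map, _ = map_criterion(R, k_max)
    k_vss1, _ = vss_criterion(R, k_max, complexity=1)
    k_vss2, _ = vss_criterion(R, k_max, complexity=2)
    if len({k_map, k_vss1, k_vss2} - {0}) > 1:
        warnings.warn(
            f"VSS ({k_vss1}/{k_vss2}) and MAP ({k_map}) disagree; MAP governs",
            RuntimeWarning,
        )
    return k_map if k_map > 0 else max(k_vss1, k_vss2)


# --------------------------------------------------------------------------
# rotation
# --------------------------------------------------------------------------
@dataclass
class RotationResult:
    loadings: np.ndarray
    phi: np.ndarray        # inter-factor correlations (identity if orthogonal)
    method: str


def rotate(loadings, method: str = "varimax") -> RotationResult:
    """Rotate an unrotated loading matrix (gradient-projection criteria).

    ``oblimin`` is direct quartimin (gamma = 0) and returns the factor
    correlation matrix; ``varimax`` is orthogonal and preserves per-variable
    communalities.  A single factor is returned unchanged.
    """
    L = np.asarray(loadings, float)
    k = L.shape[1]
    if k == 1:
        return RotationResult(L.copy(), np.eye(1), method)
    if method == "varimax":
        # Kaiser row-normalization before rotation (the classical varimax
        # default); communalities are invariant either way but the criterion
        # optimum differs for unbalanced communalities.
        h = np.sqrt(np.maximum(np.sum(L**2, axis=1), 1e-12))
        Lr, _T = rotate_factors(L / h[:, None], "varimax")
        return RotationResult(Lr * h[:, None], np.eye(k), "varimax")
    if method == "oblimin":
        Lr, T = rotate_factors(L, "quartimin")
        phi = T.T @ T
        return RotationResult(Lr, phi, "oblimin")
    raise ValueError(f"unknown rotation {method!r}")


def choose_rotation(loadings) -> tuple[RotationResult, dict]:
    """Oblique-first rotation decision.

    Rotate obliquely (oblimin); if every inter-factor correlation is below
    0.32 in magnitude (< 10% shared variance) the factors are treated as
    orthogonal and the varimax solution is adopted instead.
    """
    ob = rotate(loadings, "oblimin")
    k = ob.phi.shape[0]
    off = np.abs(ob.phi[~np.eye(k, dtype=bool)]) if k > 1 else np.array([0.0])
    max_phi = float(off.max()) if off.size else 0.0
    if max_phi < ROTATION_PHI_THRESHOLD:
        final = rotate(loadings, "varimax")
        decision = "varimax"
    else:
        final = ob
        decision = "oblimin"
    return final, {"decision": decision, "max_interfactor_correlation": max_phi, "phi_oblimin": ob.phi}


def _order_and_sign(L: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order factors by decreasing variance explained; orient each so its
    largest-magnitude loading is positive."""
    ve = np.mean(L**2, axis=0)
    order = np.argsort(ve)[::-1]
    L = L[:, order]
    phi = phi[np.ix_(order, order)]
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
            phi[j, :] = -phi[j, :]
            phi[:, j] = -phi[:, j]
    np.fill_diagonal(phi, 1.0)
    return L, phi


def salient_loadings(loadings, threshold: float = SALIENCE_THRESHOLD) -> pd.DataFrame:
    """Boolean mask of salient loadings (|loading| >= threshold, inclusive)."""
    L = pd.DataFrame(loadings) if not isinstance(loadings, pd.DataFrame) else loadings
    return L.abs() >= threshold


def align_loadings(L, target) -> np.ndarray:
    """Match columns of ``L`` to ``target`` by greedy absolute congruence,
    then fix signs.  Used wherever two solutions must be compared, since
    factor order and sign are arbitrary."""
    L = np.asarray(L, float)
    T = np.asarray(target, float)
    k = T.shape[1]
    cong = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            num = float(L[:, a] @ T[:, b])
            den = np.sqrt(np.sum(L[:, a] ** 2) * np.sum(T[:, b] ** 2))
            cong[a, b] = num / den if den > 0 else 0.0
    perm = [-1] * k
    used: set = set()
    for _ in range(k):
        masked = np.abs(cong).copy()
        if used:
            masked[list(used), :] = -np.inf
        assigned = [b for b in range(k) if perm[b] >= 0]
        if assigned:
            masked[:, assigned] = -np.inf
        a, b = np.unravel_index(np.argmax(masked), (k, k))
        perm[b] = a
        used.add(a)
    out = L[:, perm].copy()
    for j in range(k):
        if out[:, j] @ T[:, j] < 0:
            out[:, j] = -out[:, j]
    return out


def congruence(a, b) -> float:
    """Tucker congruence coefficient between two loading vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


# --------------------------------------------------------------------------
# full solution object and pipeline
# --------------------------------------------------------------------------
@dataclass
class FactorSolution:
    loadings: pd.DataFrame               # retained variables x factors, rotated
    uniquenesses: pd.Series
    communalities: pd.Series
    phi: np.ndarray
    rotation: str
    variance_explained: pd.Series        # proportion of indicator variance per factor
    pruning_history: list                # (variable, h2 at removal)
    salient: pd.DataFrame
    extension: pd.DataFrame | None = None
    score_coefficients: pd.DataFrame | None = None
    scores: pd.DataFrame | None = None
    kmo_overall: float | None = None
    rotation_info: dict = field(default_factory=dict)
    correlation: MixedCorrelationMatrix | None = None
    n_obs: int | None = None


def fit_factor_model(R: MixedCorrelationMatrix, k: int) -> FactorSolution:
    """minres extraction + rotation decision on a mixed matrix, packaged."""
    fit = minres_fit(R, k)
    if k >= 2:
        rot, info = choose_rotation(fit.loadings)
        L, phi = _order_and_sign(rot.loadings.copy(), rot.phi.copy())
        rotation = rot.method
    else:
        L, phi, rotation, info = fit.loadings.copy(), np.eye(1), "none", {}
        L, phi = _order_and_sign(L, phi)
    cols = [f"factor_{j+1}" for j in range(k)]
    ldf = pd.DataFrame(L, index=R.names, columns=cols)
    h2 = pd.Series(fit.communalities, index=R.names, name="h2")
    ve = pd.Series(np.mean(L**2, axis=0), index=cols, name="variance_explained")
    return FactorSolution(
        loadings=ldf,
        uniquenesses=1.0 - h2,
        communalities=h2,
        phi=phi,
        rotation=rotation,
        variance_explained=ve,
        pruning_history=[],
        salient=salient_loadings(ldf),
        rotation_info=info,
        correlation=R,
    )


def prune_low_communality(
    table: pd.DataFrame,
    kinds: dict,
    k: int,
    threshold: float = 0.2,
) -> FactorSolution:
    """Iteratively remove the lowest-communality indicator (< threshold),
    re-estimating the mixed matrix and minres fit after every removal, until
    all communalities reach the threshold.  Ties break lexicographically.
    """
    remaining = dict(kinds)
    history = []
    while True:
        if len(remaining) < k + 1:
            raise ValueError("pruning would leave too few variables for the factor model")
        R = mixed_matrix(table, remaining)
        fit = minres_fit(R, k)
        h2 = pd.Series(fit.communalities, index=R.names)
        low = h2[h2 < threshold]
        if low.empty:
            sol = fit_factor_model(R, k)
            sol.pruning_history = history
            return sol
        worst = sorted(low.index[low == low.min()])[0]
        history.append((worst, float(h2[worst])))
        remaining.pop(worst)


def extension_loadings(
    R_full: MixedCorrelationMatrix,
    solution: FactorSolution,
    excluded: list,
) -> pd.DataFrame:
    """Regression-based extension analysis.

    Projects excluded variables into the factor space of the retained
    solution: ``L_ext = R_ev W``, with W the factor-score coefficient matrix
    of the retained variables and R_ev the excluded-by-retained correlation
    block of the full mixed matrix.
    """
    retained = list(solution.loadings.index)
    missing = [v for v in excluded if v not in R_full.names]
    if missing:
        raise KeyError(f"excluded variables {missing} absent from the full matrix")
    Rfull_df = pd.DataFrame(R_full.smoothed_values(), index=R_full.names, columns=R_full.names)
    Rrr = Rfull_df.loc[retained, retained].to_numpy()
    Rev = Rfull_df.loc[excluded, retained].to_numpy()
    L = solution.loadings.to_numpy()
    W = np.linalg.solve(Rrr, L @ solution.phi)
    # normalize to correlations with the (estimated) factor scores
    score_var = np.diag(W.T @ Rrr @ W)
    ext = Rev @ W / np.sqrt(np.maximum(score_var, 1e-12))
    return pd.DataFrame(ext, index=excluded, columns=solution.loadings.columns)


def factor_scores_regression(
    table: pd.DataFrame,
    solution: FactorSolution,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Regression-method factor scores.

    ``W = R^{-1} Lambda Phi`` on the smoothed retained-variable matrix;
    scores are the standardized data times W.  Returns (scores,
    coefficient matrix).
    """
    retained = list(solution.loadings.index)
    R = solution.correlation
    if R is None:
        raise ValueError("solution carries no correlation matrix")
    Rdf = pd.DataFrame(R.smoothed_values(), index=R.names, columns=R.names)
    Rrr = Rdf.loc[retained, retained].to_numpy()
    W = np.linalg.solve(Rrr, solution.loadings.to_numpy() @ solution.phi)
    X = table[retained].to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    scores = Z @ W
    cols = list(solution.loadings.columns)
    return (
        pd.DataFrame(scores, index=table.index, columns=cols),
        pd.DataFrame(W, index=retained, columns=cols),
    )


def efa_pipeline(
    prepared: pd.DataFrame,
    kinds: dict,
    k: int | str = "auto",
    prune_threshold: float = 0.2,
    salience: float = SALIENCE_THRESHOLD,
) -> FactorSolution:
    """Full EFA stage: mixed matrix, KMO, factor count, pruning, rotation
    decision, salience, extension of pruned variables, regression scores."""
    R_full = mixed_matrix(prepared, kinds)
    overall, per_var = kmo(R_full)
    R_full.kmo_overall, R_full.kmo_per_variable = overall, per_var
    if k == "auto":
        k = suggest_k(R_full, k_max=min(5, len(kinds) - 2))
    sol = prune_low_communality(prepared, kinds, int(k), prune_threshold)
    sol.kmo_overall = overall
    sol.salient = salient_loadings(sol.loadings, salience)
    excluded = [v for v, _ in sol.pruning_history]
    if excluded:
        sol.extension = extension_loadings(R_full, sol, excluded)
    sol.scores, sol.score_coefficients = factor_scores_regression(prepared, sol)
    return sol
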