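"""Mixed Pearson/tetrachoric/biserial correlation matrices and the
Kaiser-Meyer-Olkin factorability measure.

Binary presence/absence indicators are treated as thresholded standard
normal liabilities, so binary-binary pairs get tetrachoric and
continuous-binary pairs biserial estimates of the latent-scale correlation.
Matrices containing such estimates need not be positive definite; eigenvalue
clipping ("smoothing") is applied where an inverse is required (KMO, factor
scores), and recorded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two continuous vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def _bvn_upper(h: float, k: float, rho: float) -> float:
    """P(X > h, Y > k) for standard bivariate normal with correlation rho."""
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    # survival via inclusion-exclusion on the CDF
    return float(
        1.0 - stats.norm.cdf(h) - stats.norm.cdf(k) + mvn.cdf([h, k])
    )


def tetrachoric(table, correction: float = 0.5) -> float:
    """Tetrachoric correlation from a 2x2 contingency table.

    Maximum-likelihood estimate under a bivariate standard normal with
    thresholds fixed at the marginal quantiles, found by root-finding on the
    (1,1)-cell probability, which is monotone in rho.  Tables with a zero
    cell receive a continuity correction (``correction`` added to every
    cell).  Layout: ``table[i, j]`` counts observations with x=i, y=j.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of nonnegative counts")
    if t.sum() <= 0:
        raise ValueError("empty table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("a zero margin makes the tetrachoric correlation undefined")
    if np.any(t == 0):
        t = t + correction
    n = t.sum()
    p1 = t[1].sum() / n          # P(x = 1)
    q1 = t[:, 1].sum() / n       # P(y = 1)
    p11 = t[1, 1] / n
    h = stats.norm.ppf(1.0 - p1)
    k = stats.norm.ppf(1.0 - q1)

    def f(rho):
        return _bvn_upper(h, k, rho) - p11

    lo, hi = -0.9999, 0.9999
    flo, fhi = f(lo), f(hi)
    if flo > 0:
        return -1.0 + 2e-4
    if fhi < 0:
        return 1.0 - 2e-4
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def biserial(x, y, clamp: bool = True) -> float:
    """Biserial correlation between a continuous x and a binary y.

    The point-biserial correlation rescaled by sqrt(p q) / phi(tau) under
    the normal-liability model (tau the threshold at P(y=1)).  Raw estimates
    can exceed 1 in magnitude; they are clamped with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    p = y.mean()
    if p in (0.0, 1.0):
        raise ValueError("both classes of y must be present")
    if np.std(x) == 0.0:
        raise ValueError("x is constant")
    m1 = x[y == 1].mean()
    m0 = x[y == 0].mean()
    s = x.std(ddof=0)
    tau = stats.norm.ppf(1.0 - p)
    r = (m1 - m0) / s * p * (1.0 - p) / stats.norm.pdf(tau)
    if abs(r) > 1.0:
        if clamp:
            warnings.warn("biserial estimate outside [-1, 1]; clamped", RuntimeWarning)
            r = float(np.clip(r, -1.0, 1.0))
    return float(r)


@dataclass
class MixedCorrelationMatrix:
    """Symmetric mixed-kind correlation matrix with smoothing metadata."""

    names: list
    values: np.ndarray
    kinds: np.ndarray                      # per-pair tags: pearson|tetrachoric|biserial
    smoothed: bool = False
    eigen_floor: float = 1e-6
    max_smoothing_change: float = 0.0
    kmo_overall: float | None = None
    kmo_per_variable: pd.Series | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def smoothed_values(self, floor: float | None = None, change_cap: float = 0.05) -> np.ndarray:
        """Eigenvalue-clipped, re-normalized PD version of the matrix.

        Needed wherever the matrix must be inverted.  Clips eigenvalues at
        ``floor``, rescales back to unit diagonal, and errors if any entry
        moves by more than ``change_cap``.
        """
        floor = self.eigen_floor if floor is None else floor
        R = self.values
        w, V = np.linalg.eigh(R)
        if w.min() >= floor:
            return R.copy()
        w = np.maximum(w, floor)
        S = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        np.fill_diagonal(S, 1.0)
        change = float(np.max(np.abs(S - R)))
        if change > change_cap:
            raise ValueError(
                f"positive-definite smoothing would move an entry by {change:.3f} "
                f"(> cap {change_cap}); the matrix is badly indefinite"
            )
        self.smoothed = True
        self.max_smoothing_change = max(self.max_smoothing_change, change)
        return S

    def to_csv(self, path, sidecar: str | None = None) -> None:
        self.to_dataframe().to_csv(path)
        if sidecar is None:
            sidecar = str(path) + ".meta.json"
        meta = {
            "kinds": {
                f"{self.names[i]}|{self.names[j]}": str(self.kinds[i, j])
                for i in range(len(self.names))
                for j in range(i + 1, len(self.names))
            },
            "smoothed": bool(self.smoothed),
            "eigen_floor": float(self.eigen_floor),
            "max_smoothing_change": float(self.max_smoothing_change),
        }
        with open(sidecar, "w") as fh:
            json.dump(meta, fh, indent=1)


def mixed_matrix(
    table: pd.DataFrame,
    kinds: dict,
    listwise: bool = True,
    eigen_floor: float = 1e-6,
) -> MixedCorrelationMatrix:
    """Mixed correlation matrix over the columns named in ``kinds``.

    Estimator dispatch per pair of measurement kinds: continuous-continuous
    Pearson, binary-binary tetrachoric, continuous-binary biserial.
    ``listwise`` drops any row with a missing value among the selected
    columns (default); otherwise each pair uses its complete observations.
    """
    names = list(kinds)
    if len(names) < 2:
        raise ValueError("need at least two variables")
    data = table[names].astype(float)
    if listwise:
        data = data.dropna()
    p = len(names)
    R = np.eye(p)
    kind_tags = np.empty((p, p), dtype=object)
    kind_tags[:] = ""
    for i in range(p):
        for j in range(i + 1, p):
            a, b = names[i], names[j]
            if listwise:
                xi, xj = data[a].to_numpy(), data[b].to_numpy()
            else:
                sub = data[[a, b]].dropna()
                xi, xj = sub[a].to_numpy(), sub[b].to_numpy()
            if len(xi) < 3:
                raise ValueError(f"fewer than 3 complete observations for pair ({a}, {b})")
            ka, kb = kinds[a], kinds[b]
            try:
                if ka == "continuous" and kb == "continuous":
                    r, tag = pearson(xi, xj), "pearson"
                elif ka == "binary" and kb == "binary":
                    tab = np.zeros((2, 2))
                    for u in (0, 1):
                        for v in (0, 1):
                            tab[u, v] = np.sum((xi == u) & (xj == v))
                    r, tag = tetrachoric(tab), "tetrachoric"
                elif ka == "continuous":
                    r, tag = biserial(xi, xj), "biserial"
                else:
                    r, tag = biserial(xj, xi), "biserial"
            except ValueError as err:
                raise ValueError(f"pair ({a}, {b}): {err}") from err
            R[i, j] = R[j, i] = r
            kind_tags[i, j] = kind_tags[j, i] = tag
    return MixedCorrelationMatrix(names=names, values=R, kinds=kind_tags, eigen_floor=eigen_floor)


def kmo(R) -> tuple[float, pd.Series]:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, with q the
    anti-image partial correlations from the inverse of R.  Returns the
    overall measure and the per-variable analogue.  An (effectively)
    diagonal matrix has no correlations to explain: by convention the
    overall measure is 0 with a "not factorable" warning.
    """
    if isinstance(R, MixedCorrelationMatrix):
        names = R.names
        M = R.smoothed_values()
    else:
        M = np.asarray(R, float)
        names = list(range(M.shape[0]))
    try:
        inv = np.linalg.inv(M)
    except np.linalg.LinAlgError as err:
        raise ValueError("correlation matrix singular even after smoothing") from err
    d = np.sqrt(np.diag(inv))
    Q = -inv / np.outer(d, d)
    np.fill_diagonal(Q, 0.0)
    R0 = M - np.diag(np.diag(M))
    r2 = R0**2
    q2 = Q**2
    denom = r2.sum() + q2.sum()
    if denom < 1e-12:
        warnings.warn("matrix is (near-)diagonal: not factorable; KMO set to 0", RuntimeWarning)
        return 0.0, pd.Series(0.0, index=names)
    overall = float(r2.sum() / denom)
    per_var_denom = r2.sum(axis=1) + q2.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_var = np.where(per_var_denom > 1e-12, r2.sum(axis=1) / per_var_denom, 0.0)
    return overall, pd.Series(per_var, index=names)
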