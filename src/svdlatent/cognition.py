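"""Cognitive scoring: Tukey ladder normalization, domain scores, and the
PCA-weighted global cognitive composite.

The global composite follows the convention of computing a principal
component analysis on the normalized test scores of cognitively normal
participants only, then applying the first-component loadings as fixed
weights to every participant's scores.  Higher scores mean better
performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Tukey ladder-of-powers candidate exponents (0 denotes log).
LADDER = (-2.0, -1.0, -0.5, 0.0, 1.0 / 3.0, 0.5, 1.0, 2.0)


def _transform(x: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0.0:
        return np.log(x)
    if lam < 0.0:
        # negate so the transformation is monotone increasing
        return -np.power(x, lam)
    return np.power(x, lam)


def tukey_ladder(x, ladder=LADDER, return_shift: bool = False):
    """Select the ladder-of-powers exponent that best normalizes ``x``.

    The criterion is the probability-plot correlation: the Pearson
    correlation between the sorted transformed sample and standard normal
    order-statistic quantiles.  Values must be positive for log/negative
    exponents; non-positive samples are shifted by ``1 - min(x)`` first and
    the shift is reported.

    Returns ``(lambda, transformed)`` or ``(lambda, shift, transformed)``
    when ``return_shift`` is set.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("need at least 3 finite observations")
    if np.ptp(x) == 0.0:
        raise ValueError("constant vector: no normalizing power exists")
    shift = 0.0
    if x.min() <= 0.0:
        shift = 1.0 - x.min()
    xs = np.sort(x + shift)
    n = xs.size
    osm = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    best_lam, best_r = None, -np.inf
    for lam in ladder:
        t = _transform(xs, lam)
        if not np.all(np.isfinite(t)) or np.ptp(t) == 0.0:
            continue
        r = float(np.corrcoef(osm, t)[0, 1])
        if r > best_r:
            best_lam, best_r = lam, r
    transformed = _transform(np.asarray(x, dtype=float) + shift, best_lam)
    if return_shift:
        return best_lam, shift, transformed
    return best_lam, transformed


def domain_scores(battery: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    """Average the normalized tests mapped to each cognitive domain.

    A participant missing any constituent test receives NA for that domain
    (consistent with listwise handling downstream).
    """
    if not mapping:
        raise ValueError("empty domain mapping")
    out = {}
    for domain, tests in mapping.items():
        if not tests:
            raise ValueError(f"domain {domain!r} maps to no tests")
        missing = [t for t in tests if t not in battery.columns]
        if missing:
            raise KeyError(f"domain {domain!r} references absent tests {missing}")
        block = battery[list(tests)]
        score = block.mean(axis=1)
        score[block.isna().any(axis=1)] = np.nan
        out[domain] = score
    return pd.DataFrame(out, index=battery.index)


@dataclass
class GlobalScoreResult:
    scores: pd.Series
    weights: pd.Series          # unit-norm PC1 loadings
    explained_fraction: float   # PC1 share of total variance in the normal subset


def global_score(
    battery: pd.DataFrame,
    tests: list | None = None,
    normal_flag: str | pd.Series = "cognitively_normal",
) -> GlobalScoreResult:
    """PC1-weighted global cognitive composite.

    The first principal component of the correlation matrix of the
    cognitively normal subset supplies fixed weights (normalized to unit
    length); the composite is the weighted sum of every participant's test
    scores, oriented so that higher values indicate better performance
    (majority-positive weights).
    """
    if tests is None:
        from .cohort import COGNITIVE_TESTS

        tests = [t for t in COGNITIVE_TESTS if t in battery.columns]
    if len(tests) < 2:
        raise ValueError("need at least two tests for a composite")
    flag = battery[normal_flag] if isinstance(normal_flag, str) else normal_flag
    normal = battery.loc[flag.astype(bool), tests].dropna()
    if normal.shape[0] < len(tests):
        raise ValueError("cognitively normal subset smaller than the test count")
    R = np.corrcoef(normal.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    w = evecs[:, -1]
    if np.sum(w > 0) < np.sum(w < 0):
        w = -w
    w = w / np.linalg.norm(w)
    scores = battery[tests].to_numpy(dtype=float) @ w
    return GlobalScoreResult(
        scores=pd.Series(scores, index=battery.index, name="global_cognition"),
        weights=pd.Series(w, index=tests),
        explained_fraction=float(evals[-1] / evals.sum()),
    )


def score_battery(table: pd.DataFrame, mapping: dict | None = None) -> pd.DataFrame:
    """Append domain scores and the global composite to a cohort table."""
    from .cohort import DEFAULT_DOMAIN_MAPPING

    mapping = mapping or DEFAULT_DOMAIN_MAPPING
    out = table.copy()
    doms = domain_scores(table, mapping)
    for c in doms.columns:
        out[f"domain_{c}"] = doms[c]
    res = global_score(table)
    out["global_cognition"] = res.scores
    return out
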