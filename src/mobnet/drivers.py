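"""Environmental drivers of MOB abundance and function.

Three stages link soil predictors to responses (class relative abundances,
PMORs): random-forest variable importance with a permutation-null
significance test, simple (optionally log10) regressions, and a
Spearman-correlation heatmap with significance stars.

The random forest itself is fit with scikit-learn; the importance statistic
(% increase in mean-squared error when a predictor is permuted, the
randomForest %IncMSE convention) and its significance under a permutation
null of the response are computed here so the full procedure is seeded and
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor


@dataclass
class ImportanceResult:
    importance: pd.Series       # % increase in MSE per predictor
    p_values: pd.Series         # permutation-null p per predictor
    significant: pd.Series      # p < alpha
    var_explained: float        # out-of-bag R^2, percent
    alpha: float


def _perm_importance(model, x: np.ndarray, y: np.ndarray, n_shuffles: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Mean % increase in MSE when each column is permuted."""
    base = float(np.mean((model.predict(x) - y) ** 2))
    if base == 0:
        base = 1e-12
    out = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        incs = []
        for _ in range(n_shuffles):
            xp = x.copy()
            xp[:, j] = rng.permutation(xp[:, j])
            mse = float(np.mean((model.predict(xp) - y) ** 2))
            incs.append(100.0 * (mse - base) / base)
        out[j] = float(np.mean(incs))
    return out


def rf_importance(x: pd.DataFrame, y, n_trees: int = 500, n_perm: int = 50,
                  n_shuffles: int = 5, alpha: float = 0.05,
                  seed: int = 0) -> ImportanceResult:
    """Random-forest variable importance with permutation-null significance.

    ``n_perm`` refits of the forest on a shuffled response build the null
    distribution of each predictor's importance; p is the fraction of null
    importances at least as large (add-one corrected).
    """
    x = x.dropna()
    y = pd.Series(np.asarray(y, dtype=float), index=x.index).loc[x.index]
    mask = y.notna()
    x, y = x[mask], y[mask]
    if len(x) < 10:
        raise ValueError("random-forest importance needs at least 10 samples")
    xa, ya = x.to_numpy(dtype=float), y.to_numpy(dtype=float)
    rng = np.random.default_rng([int(seed), 41])

    def fit(target, rs):
        m = RandomForestRegressor(n_estimators=n_trees, oob_score=True,
                                  random_state=rs, n_jobs=1)
        m.fit(xa, target)
        return m

    model = fit(ya, int(rng.integers(2 ** 31)))
    obs = _perm_importance(model, xa, ya, n_shuffles, rng)

    null = np.zeros((n_perm, xa.shape[1]))
    for b in range(n_perm):
        y_null = rng.permutation(ya)
        m_null = fit(y_null, int(rng.integers(2 ** 31)))
        null[b] = _perm_importance(m_null, xa, y_null, 1, rng)
    p = (1 + (null >= obs[None, :]).sum(axis=0)) / (1 + n_perm)

    imp = pd.Series(obs, index=x.columns)
    pv = pd.Series(p, index=x.columns)
    return ImportanceResult(importance=imp, p_values=pv,
                            significant=pv < alpha,
                            var_explained=100.0 * float(model.oob_score_),
                            alpha=alpha)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    log_x: bool
    log_y: bool


def fit_regression(x, y, log_x: bool = False, log_y: bool = False) -> RegressionResult:
    """OLS of y on x, optionally after log10 transforms.

    Log mode requires strictly positive values; the offending sample is named.
    """
    xs = pd.Series(np.asarray(x, dtype=float),
                   index=getattr(x, "index", None))
    ys = pd.Series(np.asarray(y, dtype=float), index=xs.index)
    mask = xs.notna() & ys.notna()
    xs, ys = xs[mask], ys[mask]
    for flag, series, name in ((log_x, xs, "x"), (log_y, ys, "y")):
        if flag:
            bad = series[series <= 0]
            if len(bad):
                raise ValueError(
                    f"log10 transform of {name} undefined for sample "
                    f"{bad.index[0]!r} (value {bad.iloc[0]!r})")
    xv = np.log10(xs.to_numpy()) if log_x else xs.to_numpy()
    yv = np.log10(ys.to_numpy()) if log_y else ys.to_numpy()
    res = stats.linregress(xv, yv)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2),
                            p_value=float(res.pvalue), n=len(xv),
                            log_x=log_x, log_y=log_y)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_heatmap(left: pd.DataFrame, right: pd.DataFrame,
                        method: str = "spearman"
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise correlations between two variable sets with star labels.

    Missing values are excluded pairwise.  Returns (correlations, p-values,
    stars) as left-variables x right-variables frames.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method: {method!r}")
    func = stats.spearmanr if method == "spearman" else stats.pearsonr
    corr = pd.DataFrame(index=left.columns, columns=right.columns, dtype=float)
    pval = corr.copy()
    for a in left.columns:
        for b in right.columns:
            xa, xb = left[a], right.loc[left.index, b]
            mask = xa.notna() & xb.notna()
            r, p = func(xa[mask], xb[mask])
            corr.loc[a, b], pval.loc[a, b] = float(r), float(p)
    starred = pval.map(significance_stars)
    return corr, pval, starred
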