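"""Partial least squares path modelling (PLS-PM).

Latent variables (soil nutrients, soil ions, type I / type II relative
abundance, community diversity, pmoA abundance, PMORs) are measured by
blocks of manifest indicators and connected by a directed acyclic inner
model.  Estimation follows the Lohmoeller iteration: latent scores are
alternately refreshed from their outer weights (mode A, reflective blocks)
and from an inner approximation (path weighting scheme by default) until the
outer weights stabilise.  Path coefficients are then OLS regressions of each
endogenous latent score on its predecessors; significance comes from a
case-resampling bootstrap; model quality is the goodness of fit
GoF = sqrt(mean communality x mean R^2).

Sign indeterminacy is resolved by aligning every latent score positively
with its first manifest indicator, making results deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PathModel:
    """Latent blocks and the inner (structural) path structure.

    ``blocks`` maps latent name -> list of manifest column names;
    ``paths`` is a list of (source, target) latent pairs and must be acyclic.
    """

    blocks: dict
    paths: list

    def __post_init__(self) -> None:
        latents = list(self.blocks)
        seen: dict[str, str] = {}
        for lv, mvs in self.blocks.items():
            if not mvs:
                raise ValueError(f"block {lv!r} has no manifest variables")
            for mv in mvs:
                if mv in seen:
                    raise ValueError(
                        f"manifest {mv!r} appears in blocks {seen[mv]!r} and {lv!r}")
                seen[mv] = lv
        for a, b in self.paths:
            if a not in latents or b not in latents:
                raise ValueError(f"path {a!r}->{b!r} references unknown latent")
        self.order = self._topological_order()

    def _topological_order(self) -> list:
        indeg = {lv: 0 for lv in self.blocks}
        for _, b in self.paths:
            indeg[b] += 1
        queue = [lv for lv, d in indeg.items() if d == 0]
        order = []
        while queue:
            lv = queue.pop(0)
            order.append(lv)
            for a, b in self.paths:
                if a == lv:
                    indeg[b] -= 1
                    if indeg[b] == 0:
                        queue.append(b)
        if len(order) != len(self.blocks):
            raise ValueError("inner path structure contains a cycle")
        return order

    def predecessors(self, lv) -> list:
        return [a for a, b in self.paths if b == lv]

    def successors(self, lv) -> list:
        return [b for a, b in self.paths if a == lv]

    @property
    def endogenous(self) -> list:
        return [lv for lv in self.order if self.predecessors(lv)]


@dataclass
class PlspmResult:
    model: PathModel
    outer_weights: dict        # latent -> Series over manifests
    loadings: dict             # latent -> Series (corr of manifest with score)
    communalities: pd.Series   # per manifest
    scores: pd.DataFrame       # samples x latents (unit variance)
    path_coefficients: dict    # (source, target) -> standardized beta
    r_squared: dict            # endogenous latent -> R^2
    gof: float
    n_iterations: int
    indirect_effects: dict     # (source, target) -> summed product of chains
    total_effects: dict


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def _unit_variance(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    return v / sd if sd > 0 else v


def fit_plspm(data: pd.DataFrame, model: PathModel, scheme: str = "path",
              tol: float = 1e-7, max_iter: int = 300) -> PlspmResult:
    """Fit the path model on complete cases of ``data``.

    All manifests are standardised internally; scheme is one of
    ``path`` (default), ``centroid``, ``factorial``.
    """
    if scheme not in ("path", "centroid", "factorial"):
        raise ValueError(f"unknown weighting scheme: {scheme!r}")
    manifests = [mv for mvs in model.blocks.values() for mv in mvs]
    df = data[manifests].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete cases")
    x = {lv: _standardize(df[mvs].to_numpy(dtype=float))
         for lv, mvs in model.blocks.items()}
    n = len(df)
    latents = list(model.blocks)
    w = {lv: np.ones(x[lv].shape[1]) for lv in latents}

    def scores_from(wts):
        y = {}
        for lv in latents:
            v = _unit_variance(x[lv] @ wts[lv])
            # positive alignment with the first manifest
            c = float(np.dot(v, x[lv][:, 0])) / n
            if c < 0:
                wts[lv] = -wts[lv]
                v = -v
            y[lv] = v
        return y

    y = scores_from(w)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # inner approximation
        z = {}
        for lv in latents:
            preds = model.predecessors(lv)
            succs = model.successors(lv)
            if not preds and not succs:
                z[lv] = y[lv]
                continue
            acc = np.zeros(n)
            if scheme == "path":
                if preds:
                    yp = np.column_stack([y[p] for p in preds])
                    beta, *_ = np.linalg.lstsq(yp, y[lv], rcond=None)
                    acc += yp @ beta
                for s in succs:
                    acc += float(np.dot(y[lv], y[s]) / n) * y[s]
            else:
                for nb in preds + succs:
                    c = float(np.dot(y[lv], y[nb]) / n)
                    weight = np.sign(c) if scheme == "centroid" else c
                    acc += weight * y[nb]
            z[lv] = acc
        # outer update, mode A: weights proportional to cov(manifest, inner score)
        w_new = {lv: x[lv].T @ z[lv] / n for lv in latents}
        for lv in latents:
            sd = (x[lv] @ w_new[lv]).std(ddof=0)
            if sd > 0:
                w_new[lv] = w_new[lv] / sd
        delta = max(np.max(np.abs(w_new[lv] - w[lv])) for lv in latents)
        w = w_new
        y = scores_from(w)
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"PLS-PM did not converge in {max_iter} iterations "
            f"(last outer-weight change {delta:.2e})")

    scores = pd.DataFrame({lv: y[lv] for lv in latents}, index=df.index)

    paths = {}
    r2 = {}
    for lv in model.endogenous:
        preds = model.predecessors(lv)
        yp = np.column_stack([y[p] for p in preds])
        beta, *_ = np.linalg.lstsq(yp, y[lv], rcond=None)
        for p, b in zip(preds, beta):
            paths[(p, lv)] = float(b)
        resid = y[lv] - yp @ beta
        r2[lv] = float(1.0 - (resid ** 2).sum() / (y[lv] ** 2).sum())

    loadings = {}
    comm = {}
    weights = {}
    for lv, mvs in model.blocks.items():
        lo = x[lv].T @ y[lv] / n
        loadings[lv] = pd.Series(lo, index=mvs)
        weights[lv] = pd.Series(w[lv], index=mvs)
        for mv, l in zip(mvs, lo):
            comm[mv] = float(l ** 2)
    communalities = pd.Series(comm)

    gof = goodness_of_fit(communalities, r2)
    indirect, total = _effects(model, paths)
    return PlspmResult(model=model, outer_weights=weights, loadings=loadings,
                       communalities=communalities, scores=scores,
                       path_coefficients=paths, r_squared=r2, gof=gof,
                       n_iterations=n_iter, indirect_effects=indirect,
                       total_effects=total)


def goodness_of_fit(communalities: pd.Series, r_squared: dict) -> float:
    """GoF = sqrt(mean communality of manifests x mean R^2 of endogenous latents)."""
    if not len(r_squared):
        return float("nan")
    return float(np.sqrt(communalities.mean() * np.mean(list(r_squared.values()))))


def _effects(model: PathModel, paths: dict) -> tuple[dict, dict]:
    """Indirect effects: sum over all directed chains of length >= 2 of the
    product of path coefficients; total = direct + indirect."""
    indirect = {}
    for lv in model.order:
        local: dict[tuple, float] = {}

        def walk2(current, product, length):
            for nxt in model.successors(current):
                b = paths.get((current, nxt), 0.0)
                if length + 1 >= 2:
                    key = (lv, nxt)
                    local[key] = local.get(key, 0.0) + product * b
                walk2(nxt, product * b, length + 1)

        walk2(lv, 1.0, 0)
        indirect.update(local)

    total = dict(indirect)
    for (a, b), v in paths.items():
        total[(a, b)] = total.get((a, b), 0.0) + v
    return indirect, total


@dataclass
class BootstrapResult:
    estimates: dict            # (source, target) -> point estimate
    boot_mean: dict
    boot_se: dict
    ci_lower: dict             # 95% percentile
    ci_upper: dict
    stars: dict                # '', '*', '**', '***'
    n_boot: int
    n_effective: int           # bootstrap fits that converged
    seed: int


def bootstrap_paths(data: pd.DataFrame, model: PathModel, n_boot: int = 1000,
                    seed: int = 0, scheme: str = "path",
                    tol: float = 1e-7, max_iter: int = 300) -> BootstrapResult:
    """Case-resampling bootstrap of the path coefficients.

    Star levels test CI exclusion of zero at 95 / 99 / 99.9% percentile
    coverage (* / ** / ***).
    """
    if n_boot < 10:
        raise ValueError("n_boot must be at least 10")
    base = fit_plspm(data, model, scheme=scheme, tol=tol, max_iter=max_iter)
    keys = list(base.path_coefficients)
    rng = np.random.default_rng([int(seed), 61])
    manifests = [mv for mvs in model.blocks.values() for mv in mvs]
    df = data[manifests].dropna().reset_index(drop=True)
    draws = {k: [] for k in keys}
    n_ok = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(df), len(df))
        try:
            res = fit_plspm(df.iloc[idx], model, scheme=scheme, tol=tol,
                            max_iter=max_iter)
        except (RuntimeError, ValueError):
            continue
        n_ok += 1
        for k in keys:
            draws[k].append(res.path_coefficients.get(k, np.nan))
    if n_ok < max(10, n_boot // 10):
        raise RuntimeError("too few bootstrap fits converged")

    def star_for(vals):
        for level, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            lo, hi = np.percentile(vals, [100 * level / 2, 100 * (1 - level / 2)])
            if lo > 0 or hi < 0:
                return s
        return ""

    est, mean, se, lo95, hi95, stars = {}, {}, {}, {}, {}, {}
    for k in keys:
        vals = np.asarray(draws[k], dtype=float)
        vals = vals[np.isfinite(vals)]
        est[k] = base.path_coefficients[k]
        mean[k] = float(vals.mean())
        se[k] = float(vals.std(ddof=1))
        lo95[k], hi95[k] = (float(v) for v in np.percentile(vals, [2.5, 97.5]))
        stars[k] = star_for(vals)
    return BootstrapResult(estimates=est, boot_mean=mean, boot_se=se,
                           ci_lower=lo95, ci_upper=hi95, stars=stars,
                           n_boot=n_boot, n_effective=n_ok, seed=seed)


def wetland_path_model() -> PathModel:
    """Default inner wiring: nutrients and ions drive the MOB groups and
    community, those drive pmoA abundance, and everything upstream of the
    rate feeds PMORs (best-effort reconstruction of the study design)."""
    blocks = {
        "nutrients": ["TOC", "TN", "TP", "NH4", "NO3"],
        "ions": ["pH", "EC"],
        "typeI": ["typeI_share"],
        "typeII": ["typeII_share"],
        "community": ["CAP1", "richness"],
        "pmoA": ["log10_copies"],
        "PMORs": ["pmor"],
    }
    paths = [
        ("nutrients", "typeI"), ("nutrients", "typeII"),
        ("nutrients", "community"), ("nutrients", "pmoA"),
        ("ions", "typeI"), ("ions", "typeII"),
        ("ions", "community"), ("ions", "PMORs"),
        ("typeI", "pmoA"), ("typeII", "pmoA"),
        ("community", "pmoA"),
        ("typeI", "PMORs"), ("typeII", "PMORs"),
        ("pmoA", "PMORs"),
    ]
    return PathModel(blocks=blocks, paths=paths)
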