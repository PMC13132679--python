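"""Community statistics: filtering, rarefaction, diversity, ordination.

Counts are filtered (ASVs with < 10 total reads removed), rarefied to a
common depth (1252 reads by default, sampling without replacement), and
summarised as richness and relative abundances.  Composition is compared
through Bray-Curtis dissimilarity with PERMANOVA, and related to soil
predictors through distance-based redundancy analysis (CAP / db-RDA:
principal-coordinate decomposition followed by redundancy analysis) with
stepwise forward selection, permutation tests and VIF screening.
Group contrasts use one-way ANOVA with Tukey HSD compact letter displays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io_tables import AsvTable, SoilTable, TaxonomyMap

DEFAULT_MIN_READS = 10
DEFAULT_RAREFACTION_DEPTH = 1252


@dataclass
class DistanceMatrix:
    """Symmetric sample x sample dissimilarity matrix."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)

    def subset(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# filtering / rarefaction / diversity
# ---------------------------------------------------------------------------

def filter_low_count(asv: AsvTable, min_reads: int = DEFAULT_MIN_READS) -> AsvTable:
    """Drop ASVs with total reads strictly below ``min_reads``."""
    keep = asv.counts.sum(axis=0) >= min_reads
    return AsvTable(asv.counts.loc[:, keep].copy(), asv.sample_meta.copy())


def rarefy(asv: AsvTable, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int = 0) -> AsvTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a warning.
    Sampling is multivariate hypergeometric, so the expected rarefied count of
    an ASV is depth * count / total.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng([int(seed), 17])
    totals = asv.counts.sum(axis=1)
    keep = totals >= depth
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} samples below rarefaction depth {depth}",
            stacklevel=2)
    rows = []
    kept_ids = list(asv.counts.index[keep])
    for sid in kept_ids:
        row = asv.counts.loc[sid].to_numpy()
        if row.sum() == depth:
            rows.append(row)
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    counts = pd.DataFrame(np.asarray(rows, dtype=np.int64), index=kept_ids,
                          columns=asv.counts.columns)
    return AsvTable(counts, asv.sample_meta.loc[kept_ids].copy())


def richness(asv: AsvTable) -> pd.Series:
    """Observed ASV richness (count > 0) per sample."""
    return (asv.counts > 0).sum(axis=1)


def relative_abundance(asv: AsvTable, tax: TaxonomyMap | None = None,
                       level: str = "asv") -> pd.DataFrame:
    """Per-sample proportions at ASV, genus or MOB-class resolution.

    Rows sum to 1 (all-zero samples stay all-zero); unmapped ASVs fall into
    the ``unclassified`` group.
    """
    if level not in ("asv", "genus", "mob_class"):
        raise ValueError(f"unknown level: {level!r}")
    counts = asv.counts
    if level != "asv":
        if tax is None:
            raise ValueError("taxonomy required for genus/mob_class level")
        groups = (tax.genus_series(asv.asv_ids) if level == "genus"
                  else tax.class_series(asv.asv_ids))
        counts = counts.T.groupby(groups.to_numpy()).sum().T
    totals = counts.sum(axis=1)
    out = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return out


def log10_copies(qpcr: pd.DataFrame, column: str = "copies_per_g") -> pd.Series:
    """log10-transform qPCR copy numbers; zero or negative copies are invalid."""
    vals = qpcr[column]
    bad = vals[(vals <= 0) | vals.isna()]
    if len(bad):
        raise ValueError(
            f"non-positive qPCR copy numbers for samples {list(bad.index)[:5]}")
    return np.log10(vals)


# ---------------------------------------------------------------------------
# dissimilarity + PERMANOVA
# ---------------------------------------------------------------------------

def bray_curtis(asv: AsvTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: 1 - 2 sum(min(u,v)) / (sum u + sum v)."""
    d = squareform(pdist(asv.counts.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(asv.sample_ids, d)


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_b, df_w = n_groups - 1, n - n_groups
    if df_w <= 0 or ss_within <= 0:
        return np.inf
    return (ss_between / df_b) / (ss_within / df_w)


def permanova(d: DistanceMatrix, groups, n_perm: int = 999,
              seed: int = 0) -> tuple[float, float]:
    """One-way PERMANOVA pseudo-F with permutation p-value.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so the smallest attainable
    p is 1 / (n_perm + 1).
    """
    groups = pd.Series(list(groups), index=d.sample_ids)
    codes, uniques = pd.factorize(groups)
    if len(uniques) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    d2 = d.values ** 2
    f_obs = _permanova_f(d2, codes, len(uniques))
    rng = np.random.default_rng([int(seed), 23])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _permanova_f(d2, perm, len(uniques)) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)


# ---------------------------------------------------------------------------
# CAP / db-RDA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    sample_ids: list
    site_scores: pd.DataFrame          # samples x constrained axes
    eigenvalues: np.ndarray            # constrained, non-increasing
    total_inertia: float
    constrained_inertia: float
    biplot_scores: pd.DataFrame        # predictors x axes (correlations)
    predictors: list
    permutation_p: dict                # per-predictor marginal p
    global_p: float | None
    vifs: dict


def pcoa_coordinates(d: DistanceMatrix, eig_tol: float = 1e-8
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a distance matrix with Lingoes correction.

    If any Gower eigenvalue is < -eig_tol the matrix is non-Euclidean (as
    Bray-Curtis typically is) and the Lingoes constant c = -lambda_min is
    added to all squared off-diagonal distances before re-decomposition.
    """
    dv = d.values
    n = dv.shape[0]

    def gower(d2):
        j = np.eye(n) - np.ones((n, n)) / n
        return -0.5 * j @ d2 @ j

    g = gower(dv ** 2)
    eigvals = np.linalg.eigvalsh(g)
    if eigvals[0] < -eig_tol:
        c = -eigvals[0]
        d2 = dv ** 2 + 2.0 * c * (1 - np.eye(n))
        g = gower(d2)
    w, v = np.linalg.eigh(g)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    keep = w > eig_tol
    coords = v[:, keep] * np.sqrt(w[keep])
    return coords, w[keep]


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _rda_fit(y: np.ndarray, x: np.ndarray):
    """Redundancy analysis of centred response on standardised predictors."""
    b, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ b
    resid = y - fitted
    return fitted, resid


def _rda_inertia(mat: np.ndarray) -> float:
    return float((mat ** 2).sum()) / max(mat.shape[0] - 1, 1)


def vif(soil: SoilTable | pd.DataFrame, predictors) -> dict:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j); collinear -> inf."""
    table = soil.table if isinstance(soil, SoilTable) else soil
    x = _standardize(table[list(predictors)].to_numpy())
    out = {}
    for j, name in enumerate(predictors):
        if len(predictors) == 1:
            out[name] = 1.0
            continue
        others = np.delete(x, j, axis=1)
        fitted, resid = _rda_fit(x[:, [j]], others)
        ss_res = float((resid ** 2).sum())
        ss_tot = float((x[:, j] ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[name] = float("inf") if r2 > 1 - 1e-10 else 1.0 / (1.0 - r2)
    return out


def cap_ordination(d: DistanceMatrix, soil: SoilTable, predictors,
                   n_perm: int = 999, seed: int = 0) -> OrdinationResult:
    """Constrained analysis of principal coordinates (db-RDA).

    PCoA axes of the (Lingoes-corrected) distance matrix are regressed on the
    standardised predictors; the SVD of the fitted matrix yields the
    constrained axes.  Marginal per-predictor and global significance come
    from row permutations of the response.
    """
    predictors = list(predictors)
    soil_sub = soil.align_to(d.sample_ids)
    if list(soil_sub.table.index) != list(d.sample_ids):
        raise ValueError("soil table does not cover all samples in the distance matrix")
    y, _ = pcoa_coordinates(d)
    y = y - y.mean(axis=0)
    x = _standardize(soil_sub.table[predictors].to_numpy())

    fitted, resid = _rda_fit(y, x)
    total = _rda_inertia(y)
    constrained = _rda_inertia(fitted)

    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eigs = s ** 2 / max(y.shape[0] - 1, 1)
    n_axes = min(len(predictors), int((eigs > 1e-10).sum()))
    eigs = eigs[:n_axes]
    scores = u[:, :n_axes] * s[:n_axes]
    axis_names = [f"CAP{i + 1}" for i in range(n_axes)]
    site_scores = pd.DataFrame(scores, index=d.sample_ids, columns=axis_names)

    biplot = pd.DataFrame(
        np.array([[_safe_corr(x[:, j], scores[:, a]) for a in range(n_axes)]
                  for j in range(len(predictors))]),
        index=predictors, columns=axis_names)

    rng = np.random.default_rng([int(seed), 29])
    global_p = _rda_perm_p(y, x, rng, n_perm)
    per_var = {}
    for j, name in enumerate(predictors):
        others = np.delete(x, j, axis=1)
        per_var[name] = _rda_added_perm_p(y, others, x[:, [j]], rng, n_perm)

    return OrdinationResult(
        sample_ids=list(d.sample_ids), site_scores=site_scores,
        eigenvalues=eigs, total_inertia=total,
        constrained_inertia=constrained, biplot_scores=biplot,
        predictors=predictors, permutation_p=per_var, global_p=global_p,
        vifs=vif(soil_sub, predictors))


def _safe_corr(a, b) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _pseudo_f(y, x) -> float:
    fitted, resid = _rda_fit(y, x)
    q = x.shape[1]
    df_res = y.shape[0] - q - 1
    ss_fit = (fitted ** 2).sum()
    ss_res = (resid ** 2).sum()
    if df_res <= 0 or ss_res <= 0:
        return np.inf
    return (ss_fit / q) / (ss_res / df_res)


def _rda_perm_p(y, x, rng, n_perm) -> float:
    f_obs = _pseudo_f(y, x)
    count = sum(
        _pseudo_f(y[rng.permutation(y.shape[0])], x) >= f_obs
        for _ in range(n_perm))
    return (1 + count) / (1 + n_perm)


def _rda_added_perm_p(y, x_base, x_new, rng, n_perm) -> float:
    """Permutation p for adding x_new given x_base (residualised permutation)."""
    if x_base.shape[1]:
        _, y_res = _rda_fit(y, x_base)
        _, xn = _rda_fit(x_new, x_base)
    else:
        y_res, xn = y, x_new
    f_obs = _pseudo_f(y_res, xn)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(y_res.shape[0])
        if _pseudo_f(y_res[perm], xn) >= f_obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def forward_select(d: DistanceMatrix, soil: SoilTable, candidates,
                   alpha: float = 0.05, n_perm: int = 999,
                   seed: int = 0) -> dict:
    """Greedy forward selection of soil predictors for db-RDA.

    At each step the candidate adding the most constrained inertia is tested
    by permutation; it enters if p < alpha, otherwise selection stops.
    Returns selected names, per-step p-values and added inertia, and the VIFs
    of the final selection.
    """
    soil_sub = soil.align_to(d.sample_ids)
    y, _ = pcoa_coordinates(d)
    y = y - y.mean(axis=0)
    rng = np.random.default_rng([int(seed), 31])
    remaining = list(candidates)
    selected: list[str] = []
    step_p: dict[str, float] = {}
    step_inertia: dict[str, float] = {}

    while remaining:
        x_base = (_standardize(soil_sub.table[selected].to_numpy())
                  if selected else np.empty((y.shape[0], 0)))
        base_fit = _rda_inertia(_rda_fit(y, x_base)[0]) if selected else 0.0
        best, best_gain = None, -np.inf
        for name in remaining:
            x_try = _standardize(soil_sub.table[selected + [name]].to_numpy())
            gain = _rda_inertia(_rda_fit(y, x_try)[0]) - base_fit
            if gain > best_gain:
                best, best_gain = name, gain
        x_new = _standardize(soil_sub.table[[best]].to_numpy())
        p = _rda_added_perm_p(y, x_base, x_new, rng, n_perm)
        if p < alpha:
            selected.append(best)
            remaining.remove(best)
            step_p[best] = p
            step_inertia[best] = best_gain
        else:
            break

    vifs = vif(soil_sub, selected) if selected else {}
    return {"selected": selected, "p_values": step_p,
            "added_inertia": step_inertia, "vifs": vifs}


# ---------------------------------------------------------------------------
# group comparison: ANOVA + Tukey HSD with compact letter display
# ---------------------------------------------------------------------------

def _compact_letters(group_names, sig_pairs) -> dict:
    """Insert-and-absorb compact letter display.

    Groups not significantly different share at least one letter; each
    significant pair shares none.
    """
    sets = [set(group_names)]
    for a, b in sig_pairs:
        new_sets = []
        changed = False
        for s in sets:
            if a in s and b in s:
                changed = True
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        if changed:
            # absorb subsets
            sets = []
            for s in sorted(new_sets, key=len, reverse=True):
                if s and not any(s <= t for t in sets):
                    sets.append(s)
    # letters ordered by the highest-mean member for readable output
    letters = {g: "" for g in group_names}
    for i, s in enumerate(sets):
        ch = chr(ord("a") + i) if i < 26 else f"l{i}"
        for g in group_names:
            if g in s:
                letters[g] += ch
    return letters


def group_compare(values, groups, alpha: float = 0.05) -> dict:
    """One-way ANOVA with Tukey HSD post hoc and a compact letter display."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": list(groups)}).dropna()
    names = list(pd.unique(df["group"]))
    samples = [df.loc[df["group"] == g, "value"].to_numpy() for g in names]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    if all(np.allclose(s, s[0]) for s in samples) and \
            len({float(s[0]) for s in samples}) == 1:
        # zero variance everywhere: nothing distinguishable
        return {"F": 0.0, "p": 1.0,
                "letters": {g: "a" for g in names},
                "tukey_p": {}}
    f_stat, p = stats.f_oneway(*samples)
    res = stats.tukey_hsd(*samples)
    sig_pairs = []
    tukey_p = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pij = float(res.pvalue[i, j])
            tukey_p[(names[i], names[j])] = pij
            if pij < alpha:
                sig_pairs.append((names[i], names[j]))
    # order groups by descending mean so 'a' labels the largest group
    order = sorted(names, key=lambda g: -df.loc[df["group"] == g, "value"].mean())
    letters = _compact_letters(order, sig_pairs)
    return {"F": float(f_stat), "p": float(p), "letters": letters,
            "tukey_p": tukey_p}
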