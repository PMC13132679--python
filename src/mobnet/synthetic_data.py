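"""Seeded synthetic wetland-methanotroph studies.

Emulates the downstream product of a pmoA amplicon survey over four wetland
sites x four soil depths: a count table of ASVs with site-structured
type I / type II composition, a soil table with opposed ion (pH, EC) and
nutrient (TOC, TN) gradients, qPCR copy numbers, and two-point headspace
CH4-depletion series whose implied oxidation rates rank the sites.

The causal structure generated (and recovered downstream) is:

* two sites are saline/alkaline and nutrient-poor, two are the reverse;
  pH and EC are positively correlated;
* the expected type I share rises with the soil ion score and the type II
  share falls with it (softmax with slopes ``beta_typeI_ion`` > 0 and
  ``beta_typeII_ion`` < 0);
* the potential methane oxidation rate rises with the type II share
  (``beta_pmor_typeII`` > 0) and falls with EC (``beta_pmor_ion`` < 0).

Counts are Dirichlet-multinomial (compositional with tunable overdispersion);
library sizes are log-normal around 16x the 1252-read rarefaction depth so
rarefaction is always feasible.  A fixed seed fully determines every table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import AsvTable, SoilTable, TaxonomyMap
from .pmor import (DEFAULT_PA, DEFAULT_T, DEFAULT_VH, DEFAULT_WS,
                   IncubationRecord, pmor_per_unit_dcdt)

DEFAULT_SITES = ("MQ", "LQ", "ZY", "SGH")
DEFAULT_DEPTHS = ("D1", "D2", "D3", "D4")

TYPE_I_GENERA = ("Methylobacter", "Methylomonas", "Methylosarcina", "TypeId")
TYPE_II_GENERA = ("Methylocystis", "TypeIIb")


@dataclass
class StudyDesign:
    n_sites: int = 4
    plots_per_site: int = 8
    n_depths: int = 4
    n_asvs: int = 300
    seed: int = 0
    site_names: tuple = DEFAULT_SITES
    depth_names: tuple = DEFAULT_DEPTHS

    def __post_init__(self) -> None:
        if len(self.site_names) != self.n_sites:
            self.site_names = tuple(f"S{i + 1}" for i in range(self.n_sites))
        if len(self.depth_names) != self.n_depths:
            self.depth_names = tuple(f"D{i + 1}" for i in range(self.n_depths))

    @property
    def n_samples(self) -> int:
        return self.n_sites * self.plots_per_site * self.n_depths

    def sample_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.site_names:
            for p in range(1, self.plots_per_site + 1):
                for d in self.depth_names:
                    rows.append({"sample_id": f"{s}_p{p}_{d}",
                                 "site": s, "depth": d, "plot": f"{s}_p{p}"})
        return pd.DataFrame(rows).set_index("sample_id")

    def rng(self, stream: int) -> np.random.Generator:
        # independent integer-seeded stream per table
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class EffectSpec:
    """Effect sizes and noise scales of the simulated study."""

    # per-site soil means, ordered as design.site_names
    site_ph: tuple = (7.0, 7.2, 8.6, 8.9)
    site_ec: tuple = (250.0, 320.0, 1500.0, 2100.0)      # uS/cm
    site_swc: tuple = (62.0, 55.0, 30.0, 24.0)           # %
    site_toc: tuple = (8.5, 6.0, 1.6, 1.0)               # %
    site_tn: tuple = (0.62, 0.48, 0.16, 0.10)            # %
    site_tp: tuple = (780.0, 700.0, 520.0, 450.0)        # mg/kg
    site_nh4: tuple = (28.0, 22.0, 9.0, 6.0)             # mg/kg
    site_no3: tuple = (14.0, 11.0, 6.0, 4.0)             # mg/kg
    rho_ph_ec: float = 0.8        # within-site pH-EC noise correlation
    sd_ph: float = 0.25
    sd_ec: float = 140.0
    rel_noise: float = 0.12       # relative SD of the other soil variables
    depth_toc_decay: float = 0.12  # fractional TOC/TN loss per depth layer

    # community effects (per SD of the soil ion score)
    beta_typeI_ion: float = 1.2
    beta_typeII_ion: float = -1.2
    unclassified_fraction: float = 0.06
    typeII_intercept: float = 0.25   # softmax intercept favouring type II overall
    dirichlet_concentration: float = 150.0   # inf -> pure multinomial
    library_size_mean: float = 1252.0 * 16   # reads, log-normal location
    library_size_sigma: float = 0.25

    # function effects
    pmor_base: float = 380.0      # ng g^-1 day^-1 at average conditions
    beta_pmor_typeII: float = 1.0  # per unit centred type II share (log scale)
    beta_pmor_ion: float = -0.30   # per SD of EC (log scale)
    pmor_noise: float = 0.08       # log-scale sample noise
    vial_noise: float = 0.04       # log-scale replicate-vial noise
    n_vials: int = 3

    # qPCR
    log10_copies_base: float = 6.8
    beta_copies_ion: float = -0.45
    copies_noise: float = 0.25

    def __post_init__(self) -> None:
        # slopes may be zeroed for null simulations but never sign-flipped
        if not (self.beta_typeI_ion >= 0 >= self.beta_typeII_ion):
            raise ValueError("ion slopes must satisfy beta_typeI_ion >= 0 >= beta_typeII_ion")
        if not (self.beta_pmor_typeII >= 0 >= self.beta_pmor_ion):
            raise ValueError("rate slopes must satisfy beta_pmor_typeII >= 0 >= beta_pmor_ion")
        for name in ("sd_ph", "sd_ec", "rel_noise", "pmor_noise", "vial_noise",
                     "copies_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise scale {name} must be >= 0")


def _site_values(design: StudyDesign, per_site: tuple) -> np.ndarray:
    vals = np.asarray(per_site, dtype=float)
    if len(vals) != design.n_sites:
        vals = np.resize(vals, design.n_sites)
    idx = {s: i for i, s in enumerate(design.site_names)}
    meta = design.sample_frame()
    return vals[[idx[s] for s in meta["site"]]]


def generate_soil(design: StudyDesign, effects: EffectSpec) -> SoilTable:
    """Soil table with correlated pH/EC noise and depth-decaying nutrients."""
    rng = design.rng(1)
    meta = design.sample_frame()
    n = len(meta)
    depth_rank = meta["depth"].map(
        {d: i for i, d in enumerate(design.depth_names)}).to_numpy()

    cov = np.array([[1.0, effects.rho_ph_ec], [effects.rho_ph_ec, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    ph = _site_values(design, effects.site_ph) + effects.sd_ph * z[:, 0]
    ec = _site_values(design, effects.site_ec) + effects.sd_ec * z[:, 1]

    def noisy(per_site, decay=0.0):
        mean = _site_values(design, per_site) * (1.0 - decay) ** depth_rank
        return mean * np.exp(rng.normal(0.0, effects.rel_noise, n)
                             if effects.rel_noise > 0 else np.zeros(n))

    table = pd.DataFrame({
        "pH": np.clip(ph, 3.5, 10.5),
        "EC": np.clip(ec, 10.0, None),
        "SWC": noisy(effects.site_swc),
        "TOC": noisy(effects.site_toc, effects.depth_toc_decay),
        "TN": noisy(effects.site_tn, effects.depth_toc_decay),
        "TP": noisy(effects.site_tp),
        "NH4": noisy(effects.site_nh4),
        "NO3": noisy(effects.site_no3),
    }, index=meta.index)
    return SoilTable(table)


def ion_score(soil: SoilTable) -> pd.Series:
    """Standardised soil ion score: mean of z(pH) and z(EC), re-standardised."""
    t = soil.table
    z = pd.DataFrame({
        "pH": (t["pH"] - t["pH"].mean()) / t["pH"].std(ddof=0),
        "EC": (t["EC"] - t["EC"].mean()) / t["EC"].std(ddof=0),
    })
    s = z.mean(axis=1)
    return (s - s.mean()) / s.std(ddof=0)


def _assign_taxonomy(design: StudyDesign, effects: EffectSpec,
                     rng: np.random.Generator) -> pd.DataFrame:
    n = design.n_asvs
    n_uncl = int(round(effects.unclassified_fraction * n))
    n_rest = n - n_uncl
    n_typeII = n_rest // 2
    n_typeI = n_rest - n_typeII
    genera, classes = [], []
    # Methylocystis dominates type II; type I splits across several genera
    g2 = rng.choice(TYPE_II_GENERA, size=n_typeII, p=[0.7, 0.3])
    g1 = rng.choice(TYPE_I_GENERA, size=n_typeI,
                    p=[0.4, 0.25, 0.2, 0.15])
    genera = list(g1) + list(g2) + ["unclassified"] * n_uncl
    classes = (["typeI"] * n_typeI + ["typeII"] * n_typeII
               + ["unclassified"] * n_uncl)
    asv_ids = [f"ASV{i + 1:04d}" for i in range(n)]
    perm = rng.permutation(n)
    return pd.DataFrame(
        {"genus": np.array(genera)[perm], "mob_class": np.array(classes)[perm]},
        index=asv_ids)


def expected_class_shares(effects: EffectSpec, z_ion: np.ndarray) -> pd.DataFrame:
    """Softmax expected share of each MOB class at each ion score."""
    z_ion = np.asarray(z_ion, dtype=float)
    logit_I = effects.beta_typeI_ion * z_ion
    logit_II = effects.beta_typeII_ion * z_ion + effects.typeII_intercept
    logit_U = np.full_like(z_ion, np.log(max(effects.unclassified_fraction, 1e-9))
                           - np.log(0.5))
    m = np.stack([logit_I, logit_II, logit_U], axis=1)
    m = np.exp(m - m.max(axis=1, keepdims=True))
    m /= m.sum(axis=1, keepdims=True)
    return pd.DataFrame(m, columns=["typeI", "typeII", "unclassified"])


def generate_asv_table(design: StudyDesign, effects: EffectSpec,
                       soil: SoilTable) -> tuple[AsvTable, TaxonomyMap]:
    """Dirichlet-multinomial counts whose class shares track the ion score."""
    rng = design.rng(2)
    meta = design.sample_frame()
    tax_df = _assign_taxonomy(design, effects, rng)
    tax = TaxonomyMap(tax_df)

    # fixed within-class ASV weights (log-normal rank-abundance)
    base_w = rng.lognormal(0.0, 1.5, design.n_asvs)
    cls = tax_df["mob_class"].to_numpy()
    class_cols = {"typeI": 0, "typeII": 1, "unclassified": 2}
    col_of = np.array([class_cols[c] for c in cls])
    # normalise weights within each class
    for c, j in class_cols.items():
        mask = col_of == j
        if mask.any():
            base_w[mask] /= base_w[mask].sum()

    z = ion_score(soil.align_to(meta.index)).to_numpy()
    shares = expected_class_shares(effects, z).to_numpy()

    lib_mu = np.log(effects.library_size_mean) - effects.library_size_sigma ** 2 / 2
    lib = np.maximum(
        rng.lognormal(lib_mu, effects.library_size_sigma, len(meta)), 1.0
    ).astype(np.int64)

    counts = np.zeros((len(meta), design.n_asvs), dtype=np.int64)
    for i in range(len(meta)):
        p = base_w * shares[i, col_of]
        p = p / p.sum()
        if np.isfinite(effects.dirichlet_concentration):
            alpha = np.maximum(effects.dirichlet_concentration * p, 1e-12)
            p = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(lib[i], p)

    counts_df = pd.DataFrame(counts, index=meta.index, columns=tax_df.index)
    return AsvTable(counts_df, meta), tax


def class_share(asv: AsvTable, tax: TaxonomyMap, mob_class: str) -> pd.Series:
    """Observed per-sample relative abundance of one MOB class."""
    classes = tax.class_series(asv.asv_ids)
    total = asv.counts.sum(axis=1).replace(0, np.nan)
    in_class = asv.counts.loc[:, (classes == mob_class).to_numpy()].sum(axis=1)
    return (in_class / total).fillna(0.0)


def expected_pmor(effects: EffectSpec, typeII_share: pd.Series,
                  soil: SoilTable) -> pd.Series:
    """Target mean PMOR per sample (ng g^-1 day^-1) before vial noise."""
    ec = soil.table.loc[typeII_share.index, "EC"]
    z_ec = (ec - ec.mean()) / ec.std(ddof=0)
    centred = typeII_share - typeII_share.mean()
    return effects.pmor_base * np.exp(
        effects.beta_pmor_typeII * centred + effects.beta_pmor_ion * z_ec)


def generate_incubation(design: StudyDesign, effects: EffectSpec,
                        asv: AsvTable, tax: TaxonomyMap,
                        soil: SoilTable, c_t1: float = 20.0) -> pd.DataFrame:
    """Two-point CH4 series per vial, back-computed from the target PMOR.

    The day-15 mixing ratio is c(t1) - dcdt * (t2 - t1) where dcdt inverts
    the headspace-flux formula at the vial's constants.  Targets implying a
    negative mixing ratio are unphysical and raise.
    """
    rng = design.rng(3)
    share2 = class_share(asv, tax, "typeII")
    target = expected_pmor(effects, share2, soil)
    if effects.pmor_noise > 0:
        target = target * np.exp(
            rng.normal(0.0, effects.pmor_noise, len(target)))

    rows = []
    for sample_id, mean_rate in target.items():
        for vial in range(1, effects.n_vials + 1):
            rate = mean_rate
            if effects.vial_noise > 0:
                rate = mean_rate * np.exp(rng.normal(0.0, effects.vial_noise))
            rec = IncubationRecord(sample_id, c_t1, c_t1)  # constants holder
            dcdt = rate / pmor_per_unit_dcdt(rec)
            c_t2 = c_t1 - dcdt * (rec.t2 - rec.t1)
            if c_t2 < 0:
                raise ValueError(
                    f"{sample_id}: target PMOR {rate:.1f} implies negative "
                    "day-15 mixing ratio")
            rows.append({"sample_id": sample_id, "vial": vial,
                         "c_t1": c_t1, "c_t2": c_t2,
                         "t1": rec.t1, "t2": rec.t2, "VH": DEFAULT_VH,
                         "PA": DEFAULT_PA, "Ws": DEFAULT_WS, "T": DEFAULT_T})
    return pd.DataFrame(rows)


def generate_qpcr(design: StudyDesign, effects: EffectSpec,
                  soil: SoilTable) -> pd.DataFrame:
    """pmoA copy numbers (copies per g dry soil), log-normal around a site trend."""
    rng = design.rng(4)
    z = ion_score(soil)
    log10_copies = (effects.log10_copies_base + effects.beta_copies_ion * z
                    + rng.normal(0.0, effects.copies_noise, len(z)))
    return pd.DataFrame({"copies_per_g": 10.0 ** log10_copies},
                        index=soil.table.index)


@dataclass
class SyntheticStudy:
    design: StudyDesign
    effects: EffectSpec
    soil: SoilTable
    asv: AsvTable
    taxonomy: TaxonomyMap
    incubation: pd.DataFrame
    qpcr: pd.DataFrame


def generate_study(design: StudyDesign | None = None,
                   effects: EffectSpec | None = None) -> SyntheticStudy:
    """Generate the full four-table study from one seed."""
    design = design or StudyDesign()
    effects = effects or EffectSpec()
    soil = generate_soil(design, effects)
    asv, tax = generate_asv_table(design, effects, soil)
    inc = generate_incubation(design, effects, asv, tax, soil)
    qpcr = generate_qpcr(design, effects, soil)
    return SyntheticStudy(design, effects, soil, asv, tax, inc, qpcr)
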