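"""End-to-end orchestration: simulate -> pmor -> community -> drivers ->
network -> plspm, from a single resolved configuration.

Every stage communicates through files in the output directory only; the
resolved configuration (with every seed and threshold explicit) and a run
manifest are written alongside the results so a rerun with the same config
is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, conetwork, drivers, io_tables, plspm, pmor
from .io_tables import AsvTable, SoilTable, TaxonomyMap
from .synthetic_data import EffectSpec, StudyDesign, generate_study

log = logging.getLogger("mobnet")

SOIL_PREDICTORS = ("pH", "EC", "SWC", "TOC", "TN", "TP", "NH4", "NO3")


@dataclass
class RunConfig:
    outdir: str = "mobnet_run"
    seed: int = 0
    # simulation design (used when no input paths are given)
    n_asvs: int = 300
    plots_per_site: int = 8
    # input paths (all four required to skip simulation)
    asv_counts: str | None = None
    asv_meta: str | None = None
    taxonomy: str | None = None
    soil: str | None = None
    incubation: str | None = None
    qpcr: str | None = None
    # thresholds
    min_reads: int = community.DEFAULT_MIN_READS
    rarefaction_depth: int = community.DEFAULT_RAREFACTION_DEPTH
    r_threshold: float = conetwork.DEFAULT_R_THRESHOLD
    p_threshold: float = conetwork.DEFAULT_P_THRESHOLD
    min_prevalence: int = conetwork.DEFAULT_MIN_PREVALENCE
    zi_threshold: float = conetwork.ZI_THRESHOLD
    pi_threshold: float = conetwork.PI_THRESHOLD
    n_perm: int = 999
    n_boot: int = 1000
    rf_trees: int = 500
    rf_null_perms: int = 50

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def load_or_simulate(cfg: RunConfig):
    """Return (asv, tax, soil, incubation, qpcr) from files or simulation."""
    paths = (cfg.asv_counts, cfg.asv_meta, cfg.taxonomy, cfg.soil,
             cfg.incubation)
    if any(paths) and not all(paths):
        missing = [n for n, p in zip(
            ("asv_counts", "asv_meta", "taxonomy", "soil", "incubation"),
            paths) if p is None]
        raise ValueError(f"incomplete input specification; missing: {missing}")
    if all(paths):
        asv = io_tables.read_asv_table(cfg.asv_counts, cfg.asv_meta)
        tax = io_tables.read_taxonomy(cfg.taxonomy)
        soil = io_tables.read_soil_table(cfg.soil)
        inc = io_tables.read_incubation(cfg.incubation)
        qpcr = (pd.read_csv(cfg.qpcr, index_col=0) if cfg.qpcr else None)
        return asv, tax, soil, inc, qpcr
    study = generate_study(StudyDesign(seed=cfg.seed, n_asvs=cfg.n_asvs,
                                       plots_per_site=cfg.plots_per_site))
    return study.asv, study.taxonomy, study.soil, study.incubation, study.qpcr


def write_simulated_study(outdir, seed: int = 0, n_asvs: int = 300,
                          plots_per_site: int = 8) -> dict:
    """Simulate a study and write its four input tables to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study = generate_study(StudyDesign(seed=seed, n_asvs=n_asvs,
                                       plots_per_site=plots_per_site))
    io_tables.write_asv_table(study.asv, out / "asv_counts.tsv",
                              out / "sample_meta.tsv")
    io_tables.write_taxonomy(study.taxonomy, out / "taxonomy.tsv")
    io_tables.write_soil_table(study.soil, out / "soil.csv")
    io_tables.write_incubation(study.incubation, out / "incubation.csv")
    study.qpcr.to_csv(out / "qpcr.csv")
    return {"outdir": str(out), "n_samples": study.asv.shape[0],
            "n_asvs": study.asv.shape[1]}


def assemble_plspm_data(asv: AsvTable, tax: TaxonomyMap, soil: SoilTable,
                        qpcr: pd.DataFrame, pmor_means: pd.Series,
                        cap1: pd.Series) -> pd.DataFrame:
    """Per-sample manifest table for the wetland path model."""
    shares = community.relative_abundance(asv, tax, level="mob_class")
    rich = community.richness(asv)
    data = soil.table[["TOC", "TN", "TP", "NH4", "NO3", "pH", "EC"]].copy()
    data["typeI_share"] = shares.get("typeI", 0.0)
    data["typeII_share"] = shares.get("typeII", 0.0)
    data["richness"] = rich
    data["CAP1"] = cap1
    data["log10_copies"] = community.log10_copies(qpcr)
    data["pmor"] = pmor_means
    return data.dropna()


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = cfg.resolved()
    _dump_json(resolved, out / "config.json")
    param_hash = hashlib.sha256(
        json.dumps(resolved, sort_keys=True).encode()).hexdigest()[:16]
    stages = []

    def fail(stage, exc):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage 1: inputs -------------------------------------------------
    try:
        asv, tax, soil, inc, qpcr = load_or_simulate(cfg)
        io_tables.write_asv_table(asv, out / "asv_counts.tsv",
                                  out / "sample_meta.tsv")
        io_tables.write_taxonomy(tax, out / "taxonomy.tsv")
        io_tables.write_soil_table(soil, out / "soil.csv")
        io_tables.write_incubation(inc, out / "incubation.csv")
        if qpcr is not None:
            qpcr.to_csv(out / "qpcr.csv")
    except Exception as exc:  # noqa: BLE001
        fail("inputs", exc)
    stages.append("inputs")
    log.info("inputs ready: %d samples x %d ASVs", *asv.shape)

    # --- stage 2: pmor ---------------------------------------------------
    try:
        pmor_table = pmor.compute_pmor_table(inc)
        pmor_table.to_csv(out / "pmor.csv", index=False)
        pmor_means = pmor_table.groupby("sample_id")["pmor"].mean()
    except Exception as exc:  # noqa: BLE001
        fail("pmor", exc)
    stages.append("pmor")

    # --- stage 3: community ----------------------------------------------
    try:
        filtered = community.filter_low_count(asv, cfg.min_reads)
        rare = community.rarefy(filtered, cfg.rarefaction_depth, seed=cfg.seed)
        rich = community.richness(rare)
        rich.rename("richness").to_csv(out / "richness.csv")
        shares = community.relative_abundance(rare, tax, level="mob_class")
        shares.to_csv(out / "class_shares.csv")
        genus_ra = community.relative_abundance(rare, tax, level="genus")
        genus_ra.to_csv(out / "genus_shares.csv")
        dist = community.bray_curtis(rare)
        dist.to_frame().to_csv(out / "bray_curtis.csv")
        site_groups = rare.sample_meta["site"]
        f_site, p_site = community.permanova(dist, site_groups,
                                             n_perm=cfg.n_perm, seed=cfg.seed)
        selection = community.forward_select(
            dist, soil, SOIL_PREDICTORS, n_perm=cfg.n_perm, seed=cfg.seed)
        cap_vars = selection["selected"] or list(SOIL_PREDICTORS[:2])
        cap = community.cap_ordination(dist, soil, cap_vars,
                                       n_perm=cfg.n_perm, seed=cfg.seed)
        cap.site_scores.to_csv(out / "cap_scores.csv")
        _dump_json({"permanova_site": {"F": f_site, "p": p_site},
                    "forward_selection": {
                        "selected": selection["selected"],
                        "p_values": selection["p_values"],
                        "vifs": selection["vifs"]},
                    "cap": {"eigenvalues": cap.eigenvalues,
                            "constrained_inertia": cap.constrained_inertia,
                            "total_inertia": cap.total_inertia,
                            "global_p": cap.global_p}},
                   out / "ordination.json")
    except Exception as exc:  # noqa: BLE001
        fail("community", exc)
    stages.append("community")

    # --- stage 4: drivers ------------------------------------------------
    try:
        soil_x = soil.align_to(rare.sample_ids).table[list(SOIL_PREDICTORS)]
        imp_rows = {}
        for name, y in (("typeI", shares.get("typeI")),
                        ("typeII", shares.get("typeII")),
                        ("PMOR", pmor_means.reindex(rare.sample_ids))):
            res = drivers.rf_importance(soil_x, y, n_trees=cfg.rf_trees,
                                        n_perm=cfg.rf_null_perms,
                                        seed=cfg.seed)
            imp_rows[name] = {"importance": res.importance,
                              "p": res.p_values,
                              "var_explained": res.var_explained}
        pd.concat({k: pd.DataFrame({"importance": v["importance"],
                                    "p": v["p"]})
                   for k, v in imp_rows.items()}).to_csv(out / "rf_importance.csv")
        corr, pval, stars = drivers.correlation_heatmap(
            soil_x, shares.join(pmor_means.rename("PMOR")))
        corr.to_csv(out / "heatmap_corr.csv")
        stars.to_csv(out / "heatmap_stars.csv")
    except Exception as exc:  # noqa: BLE001
        fail("drivers", exc)
    stages.append("drivers")

    # --- stage 5: network ------------------------------------------------
    try:
        nets = conetwork.build_site_networks(
            rare, tax, r_threshold=cfg.r_threshold,
            p_threshold=cfg.p_threshold, min_prevalence=cfg.min_prevalence)
        topo = {}
        zipi_rows = []
        for site, net in nets.items():
            io_tables.write_network(net, out / f"network_{site}.graphml")
            io_tables.write_network(net, out / f"network_{site}.edges.tsv",
                                    format="edgelist")
            topo[site] = conetwork.topology_summary(net, seed=cfg.seed)
            modules, _ = conetwork.detect_modules(net, seed=cfg.seed)
            for r in conetwork.zi_pi(net, modules,
                                     zi_threshold=cfg.zi_threshold,
                                     pi_threshold=cfg.pi_threshold):
                zipi_rows.append({"site": site, "node": r.node, "zi": r.zi,
                                  "pi": r.pi, "role": r.role,
                                  "module": r.module, "degree": r.degree})
        _dump_json(topo, out / "topology.json")
        pd.DataFrame(zipi_rows).to_csv(out / "zipi.csv", index=False)
        # pooled complexity over the whole-study network
        global_net = conetwork.build_network(
            rare, tax, r_threshold=cfg.r_threshold,
            p_threshold=cfg.p_threshold, min_prevalence=cfg.min_prevalence)
        props = conetwork.subnetwork_properties(global_net, rare,
                                                seed=cfg.seed)
        idx = conetwork.complexity_index(props)
        props.assign(complexity=idx).to_csv(out / "subnetwork_complexity.csv")
    except Exception as exc:  # noqa: BLE001
        fail("network", exc)
    stages.append("network")

    # --- stage 6: plspm --------------------------------------------------
    try:
        if qpcr is None:
            raise ValueError("plspm stage requires a qPCR table "
                             "(dependency: qpcr)")
        cap1 = cap.site_scores.iloc[:, 0]
        data = assemble_plspm_data(rare, tax, soil, qpcr, pmor_means, cap1)
        model = plspm.wetland_path_model()
        boot = plspm.bootstrap_paths(data, model, n_boot=cfg.n_boot,
                                     seed=cfg.seed)
        fit = plspm.fit_plspm(data, model)
        _dump_json({
            "paths": {f"{a}->{b}": v
                      for (a, b), v in fit.path_coefficients.items()},
            "stars": {f"{a}->{b}": v for (a, b), v in boot.stars.items()},
            "ci": {f"{a}->{b}": [boot.ci_lower[(a, b)], boot.ci_upper[(a, b)]]
                   for (a, b) in fit.path_coefficients},
            "r_squared": fit.r_squared, "gof": fit.gof,
            "n_boot_effective": boot.n_effective},
            out / "plspm.json")
    except Exception as exc:  # noqa: BLE001
        fail("plspm", exc)
    stages.append("plspm")

    manifest = {"stages": stages, "seed": cfg.seed,
                "parameter_hash": param_hash,
                "n_samples": asv.shape[0], "n_asvs": asv.shape[1]}
    _dump_json(manifest, out / "manifest.json")
    return manifest
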