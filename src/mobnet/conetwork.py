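"""Co-occurrence networks of methanotroph ASVs.

Edges are strong, significant Spearman correlations between ASV count
vectors (|rho| > 0.6 and p < 0.01 by default); the absolute value admits the
negative edges seen in real per-site networks.  On the resulting simple
undirected graph the module computes the full topology summary (edge/node
counts, signed-edge percentages, average degree, natural connectivity,
neighbourhood connectivity, modularity, geodesic distance, density,
connectance, clustering, three centralisation statistics), a log-log
power-law degree fit for scale-free classification, module detection and
Zi-Pi keystone roles, robustness under random node removal, per-sample
induced subnetworks and the composite complexity index.

Natural connectivity is ln((1/N) sum_i exp(lambda_i)) over the adjacency
eigenvalues: the log-average weighted count of closed walks, a redundancy
(robustness) measure that declines smoothly as nodes are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .io_tables import AsvTable, TaxonomyMap

DEFAULT_R_THRESHOLD = 0.6
DEFAULT_P_THRESHOLD = 0.01
DEFAULT_MIN_PREVALENCE = 5

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

#: the ten standardised subnetwork properties averaged into the complexity index
COMPLEXITY_PROPERTIES = (
    "nodes", "edges", "average_degree", "average_neighbour_degree",
    "graph_density", "connectance", "global_clustering",
    "betweenness_centralization", "degree_centralization",
    "average_degree_centralization",
)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_network(asv: AsvTable, tax: TaxonomyMap | None = None,
                  r_threshold: float = DEFAULT_R_THRESHOLD,
                  p_threshold: float = DEFAULT_P_THRESHOLD,
                  min_prevalence: int = DEFAULT_MIN_PREVALENCE,
                  fdr: bool = False, site: str | None = None) -> nx.Graph:
    """Spearman co-occurrence network over the ASVs of a sample subset.

    ASVs present in fewer than ``min_prevalence`` samples (or constant across
    samples) are excluded before correlation; edges require
    |rho| > r_threshold and p < p_threshold (optionally BH-adjusted);
    isolated ASVs are dropped from the node set.
    """
    counts = asv.counts
    if counts.shape[0] < 5:
        raise ValueError("need at least 5 samples to build a network")
    prevalent = (counts > 0).sum(axis=0) >= min_prevalence
    sub = counts.loc[:, prevalent]
    variable = sub.nunique(axis=0) > 1
    sub = sub.loc[:, variable]
    ids = list(sub.columns)
    g = nx.Graph(site=site or "")
    if len(ids) < 2:
        return g
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, pval = stats.spearmanr(sub.to_numpy(dtype=float))
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to scalars
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        pval = np.array([[0.0, float(pval)], [float(pval), 0.0]])
    iu = np.triu_indices(len(ids), 1)
    if fdr:
        flat = pval[iu]
        order = np.argsort(flat)
        ranked = flat[order] * len(flat) / (np.arange(len(flat)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adjusted = np.empty_like(flat)
        adjusted[order] = np.minimum(adj, 1.0)
        pv = adjusted
    else:
        pv = pval[iu]
    keep = (np.abs(rho[iu]) > r_threshold) & (pv < p_threshold)
    for i, j, r in zip(iu[0][keep], iu[1][keep], rho[iu][keep]):
        g.add_edge(ids[i], ids[j], rho=float(r),
                   sign="+" if r > 0 else "-")
    if tax is not None:
        for node in g.nodes:
            g.nodes[node]["genus"] = tax.genus(node)
            g.nodes[node]["mob_class"] = tax.mob_class(node)
    return g


def build_site_networks(asv: AsvTable, tax: TaxonomyMap | None = None,
                        **kwargs) -> dict[str, nx.Graph]:
    """One network per site over that site's samples."""
    out = {}
    for site in pd.unique(asv.sample_meta["site"]):
        ids = asv.sample_meta.index[asv.sample_meta["site"] == site]
        out[str(site)] = build_network(asv.subset_samples(ids), tax,
                                       site=str(site), **kwargs)
    return out


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def natural_connectivity(net: nx.Graph) -> float:
    """ln of the average exponentiated adjacency eigenvalue (unweighted)."""
    n = net.number_of_nodes()
    if n == 0:
        return 0.0
    a = nx.to_numpy_array(net, weight=None)
    lam = np.linalg.eigvalsh(a)
    return float(logsumexp(lam) - np.log(n))


def _freeman_degree_centralization(net: nx.Graph) -> float:
    n = net.number_of_nodes()
    if n < 3:
        return 0.0
    deg = np.array([d for _, d in net.degree()])
    # normalised degree centrality, Freeman denominator (n-1)(n-2)/(n-1)
    c = deg / (n - 1)
    return float((c.max() - c).sum() / (n - 2))


def _betweenness_centralization(net: nx.Graph) -> float:
    n = net.number_of_nodes()
    if n < 3:
        return 0.0
    bc = np.array(list(nx.betweenness_centrality(net, normalized=True).values()))
    denom = n - 1  # max of sum (c_max - c_i) for normalised betweenness
    return float((bc.max() - bc).sum() / denom)


def _mean_geodesic(net: nx.Graph) -> float:
    """Average shortest-path length over connected pairs only."""
    total, pairs = 0, 0
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        k = len(comp)
        if k < 2:
            continue
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
        pairs += k * (k - 1)
    return total / pairs if pairs else 0.0


def _average_neighbour_degree(net: nx.Graph) -> float:
    """Mean over nodes of the average degree of their neighbours."""
    vals = [v for node, v in nx.average_neighbor_degree(net).items()
            if net.degree(node) > 0]
    return float(np.mean(vals)) if vals else 0.0


def detect_modules(net: nx.Graph, seed: int = 0) -> tuple[dict, float]:
    """Louvain community detection with fixed seed; returns (node->module, Q)."""
    if net.number_of_edges() == 0:
        return ({node: i for i, node in enumerate(net.nodes)}, 0.0)
    comms = nx.community.louvain_communities(net, weight=None, seed=int(seed))
    membership = {}
    for i, c in enumerate(comms):
        for node in c:
            membership[node] = i
    q = nx.community.modularity(net, comms, weight=None)
    return membership, float(q)


def topology_summary(net: nx.Graph, seed: int = 0) -> dict:
    """The full topology panel of one network (simple unweighted graph)."""
    n, e = net.number_of_nodes(), net.number_of_edges()
    signs = [d.get("sign", "+") for _, _, d in net.edges(data=True)]
    pos = sum(s == "+" for s in signs)
    neg = sum(s == "-" for s in signs)
    density = nx.density(net) if n > 1 else 0.0
    _, modularity = detect_modules(net, seed=seed)
    deg = np.array([d for _, d in net.degree()]) if n else np.array([])
    return {
        "nodes": n,
        "edges": e,
        "positive_edge_pct": 100.0 * pos / e if e else 0.0,
        "negative_edge_pct": 100.0 * neg / e if e else 0.0,
        "average_degree": float(deg.mean()) if n else 0.0,
        "natural_connectivity": natural_connectivity(net),
        "average_neighbour_degree": _average_neighbour_degree(net),
        "modularity": modularity,
        "average_geodesic_distance": _mean_geodesic(net),
        "graph_density": float(density),
        "connectance": float(density),
        "global_clustering": float(nx.transitivity(net)) if n else 0.0,
        "betweenness_centralization": _betweenness_centralization(net),
        "degree_centralization": _freeman_degree_centralization(net),
        "average_degree_centralization":
            float((deg / (n - 1)).mean()) if n > 1 else 0.0,
    }


def fit_degree_distribution(net: nx.Graph, r2_threshold: float = 0.8
                            ) -> dict:
    """OLS fit of log10 P(k) on log10 k; scale-free iff R^2 >= threshold
    and the exponent is negative."""
    degrees = np.array([d for _, d in net.degree() if d > 0])
    if len(degrees) == 0:
        return {"exponent": np.nan, "r_squared": np.nan,
                "classification": "random", "warning": "no positive degrees"}
    ks = np.unique(degrees)
    if len(ks) < 3:
        return {"exponent": np.nan, "r_squared": np.nan,
                "classification": "random",
                "warning": "degenerate degree distribution"}
    # logarithmic binning tames the noisy high-degree tail before the OLS fit
    kmin, kmax = degrees.min(), degrees.max()
    n_bins = max(int(np.ceil(np.log2(kmax / kmin))) + 1, 3)
    edges = np.unique(np.round(
        np.geomspace(kmin, kmax + 1, n_bins + 1)).astype(int))
    counts, _ = np.histogram(degrees, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * (edges[1:] - 1).clip(min=1))
    occupied = counts > 0
    if occupied.sum() < 3:
        return {"exponent": np.nan, "r_squared": np.nan,
                "classification": "random",
                "warning": "degenerate degree distribution"}
    pk = counts[occupied] / counts.sum() / widths[occupied]
    kc = centers[occupied]
    # a power law holds from the modal degree outward; drop bins below it
    start = int(np.argmax(pk))
    if len(pk) - start >= 3:
        pk, kc = pk[start:], kc[start:]
    res = stats.linregress(np.log10(kc), np.log10(pk))
    r2 = float(res.rvalue ** 2)
    cls = "scale_free" if (r2 >= r2_threshold and res.slope < 0) else "random"
    return {"exponent": float(res.slope), "r_squared": r2,
            "classification": cls}


# ---------------------------------------------------------------------------
# Zi-Pi keystone roles
# ---------------------------------------------------------------------------

@dataclass
class ZiPiRecord:
    node: str
    zi: float
    pi: float
    role: str
    module: int
    degree: int


def classify_role(zi: float, pi: float, zi_threshold: float = ZI_THRESHOLD,
                  pi_threshold: float = PI_THRESHOLD) -> str:
    """Quadrant rule: module hubs have high Zi, connectors high Pi,
    network hubs both; everything else is peripheral."""
    if zi >= zi_threshold:
        return "network_hub" if pi >= pi_threshold else "module_hub"
    return "connector" if pi >= pi_threshold else "peripheral"


def zi_pi(net: nx.Graph, modules: dict | None = None, seed: int = 0,
          zi_threshold: float = ZI_THRESHOLD,
          pi_threshold: float = PI_THRESHOLD) -> list[ZiPiRecord]:
    """Within-module degree z-score and participation coefficient per node.

    Zi standardises a node's within-module degree against its module
    (Zi = 0 when the module's within-degree SD is zero); Pi = 1 - sum over
    modules of (fraction of the node's edges into that module)^2.
    Degree-zero nodes are excluded.
    """
    if modules is None:
        modules, _ = detect_modules(net, seed=seed)
    within = {}
    for node in net.nodes:
        m = modules[node]
        within[node] = sum(1 for nb in net.neighbors(node)
                           if modules[nb] == m)
    by_module: dict[int, list] = {}
    for node, m in modules.items():
        if net.degree(node) > 0:
            by_module.setdefault(m, []).append(node)
    stats_by_module = {}
    for m, members in by_module.items():
        w = np.array([within[x] for x in members], dtype=float)
        stats_by_module[m] = (w.mean(), w.std(ddof=0))
    records = []
    for node in net.nodes:
        k = net.degree(node)
        if k == 0:
            continue
        m = modules[node]
        mu, sd = stats_by_module[m]
        zi = (within[node] - mu) / sd if sd > 0 else 0.0
        per_module: dict[int, int] = {}
        for nb in net.neighbors(node):
            per_module[modules[nb]] = per_module.get(modules[nb], 0) + 1
        pi = 1.0 - sum((c / k) ** 2 for c in per_module.values())
        records.append(ZiPiRecord(
            node=str(node), zi=float(zi), pi=float(pi),
            role=classify_role(zi, pi, zi_threshold, pi_threshold),
            module=int(m), degree=int(k)))
    return records


def keystone_report(records: list[ZiPiRecord],
                    tax: TaxonomyMap | None = None) -> dict:
    """Counts of each role and the class composition of keystone nodes
    (keystones = connectors, module hubs and network hubs)."""
    roles = {"peripheral": 0, "connector": 0, "module_hub": 0,
             "network_hub": 0}
    keystones = []
    for r in records:
        roles[r.role] += 1
        if r.role != "peripheral":
            keystones.append(r.node)
    out = {"role_counts": roles, "n_keystones": len(keystones),
           "keystones": keystones}
    if tax is not None:
        classes = pd.Series([tax.mob_class(k) for k in keystones])
        out["keystone_class_counts"] = classes.value_counts().to_dict()
    return out


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------

@dataclass
class RobustnessCurve:
    fractions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_iterations: int
    seed: int


def robustness(net: nx.Graph, fractions=None, n_iter: int = 100,
               seed: int = 0) -> RobustnessCurve:
    """Decline of natural connectivity under random node removal.

    For each removal fraction f, ``n_iter`` random subsets of ceil(f*N)
    nodes are removed and the remnant's natural connectivity recorded.
    """
    if fractions is None:
        fractions = np.arange(0.0, 0.85, 0.05)
    fractions = np.asarray(fractions, dtype=float)
    rng = np.random.default_rng([int(seed), 53])
    nodes = list(net.nodes)
    n = len(nodes)
    base = natural_connectivity(net)
    means, sds = [], []
    for f in fractions:
        k = int(np.ceil(f * n))
        if k == 0:
            means.append(base)
            sds.append(0.0)
            continue
        vals = []
        for _ in range(n_iter):
            drop = set(rng.choice(n, size=k, replace=False).tolist())
            remnant = net.subgraph([nodes[i] for i in range(n)
                                    if i not in drop])
            vals.append(natural_connectivity(remnant))
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals, ddof=0)))
    return RobustnessCurve(fractions, np.array(means), np.array(sds),
                           n_iter, seed)


# ---------------------------------------------------------------------------
# per-sample subnetworks and the complexity index
# ---------------------------------------------------------------------------

def sample_subnetwork(net: nx.Graph, sample_counts: pd.Series) -> nx.Graph:
    """Induced subgraph on the network nodes present (count > 0) in a sample."""
    present = set(sample_counts.index[sample_counts > 0])
    return net.subgraph([n for n in net.nodes if n in present]).copy()


def subnetwork_properties(net: nx.Graph, asv: AsvTable,
                          seed: int = 0) -> pd.DataFrame:
    """The ten complexity-index properties of every sample's subnetwork."""
    rows = {}
    for sid in asv.sample_ids:
        sub = sample_subnetwork(net, asv.counts.loc[sid])
        t = topology_summary(sub, seed=seed)
        rows[sid] = {k: t[k] for k in COMPLEXITY_PROPERTIES}
    return pd.DataFrame.from_dict(rows, orient="index")


def complexity_index(properties: pd.DataFrame) -> pd.Series:
    """Mean of the z-standardised topological properties per sample.

    Properties with zero variance across samples contribute 0 for everyone.
    """
    z = pd.DataFrame(0.0, index=properties.index, columns=properties.columns)
    for col in properties.columns:
        sd = properties[col].std(ddof=0)
        if sd > 0:
            z[col] = (properties[col] - properties[col].mean()) / sd
    return z.mean(axis=1)
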