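"""Tabular and graph I/O with validation.

The pipeline exchanges five kinds of artefacts on disk: ASV feature tables
(samples x ASVs integer counts plus site/depth/plot metadata), taxonomy maps
(ASV -> genus -> type I/II class), soil-property tables, incubation records,
and co-occurrence networks.  Everything is plain TSV/CSV except networks,
which round-trip through GraphML or an edge-list TSV.  Sample alignment
across tables is always by declared sample id, never by row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

MOB_CLASSES = ("typeI", "typeII", "unclassified")

#: genus -> MOB class lookup used when a taxonomy file omits the class column.
GENUS_TO_CLASS = {
    "Methylobacter": "typeI",
    "Methylomonas": "typeI",
    "Methylosarcina": "typeI",
    "Methylomicrobium": "typeI",
    "Methylococcus": "typeI",
    "Methylocaldum": "typeI",
    "TypeIa": "typeI",
    "TypeIb": "typeI",
    "TypeId": "typeI",
    "Methylocystis": "typeII",
    "Methylosinus": "typeII",
    "Methylocapsa": "typeII",
    "TypeIIb": "typeII",
    "unclassified": "unclassified",
}

METADATA_COLUMNS = ("site", "depth", "plot")

SOIL_VARIABLES = ("pH", "EC", "SWC", "TOC", "TN", "TP", "NH4", "NO3")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AsvTable:
    """Samples x ASVs integer count matrix with per-sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer reads, index = sample ids, columns = ASV ids.
    sample_meta : pandas.DataFrame
        Index = sample ids; must contain ``site``, ``depth`` and ``plot``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate sample ids in count table")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate ASV ids in count table")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0):
                raise ValidationError("non-integer cells in count table")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("negative counts in count table")
        for col in METADATA_COLUMNS:
            if col not in self.sample_meta.columns:
                raise ValidationError(f"missing metadata column: {col!r}")
        missing = self.counts.index.difference(self.sample_meta.index)
        if len(missing):
            raise ValidationError(
                f"samples without metadata: {list(missing)[:5]}"
            )
        # keep metadata aligned to the count rows
        self.sample_meta = self.sample_meta.loc[self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids) -> "AsvTable":
        ids = [s for s in sample_ids if s in self.counts.index]
        return AsvTable(self.counts.loc[ids].copy(), self.sample_meta.loc[ids].copy())


@dataclass
class TaxonomyMap:
    """ASV -> (genus, MOB class, optional subtype).

    ASVs absent from the map resolve to ``("unclassified", "unclassified")``.
    """

    table: pd.DataFrame  # index = asv_id; columns genus, mob_class[, subtype]

    def __post_init__(self) -> None:
        if "genus" not in self.table.columns:
            raise ValidationError("taxonomy table needs a 'genus' column")
        if "mob_class" not in self.table.columns:
            self.table = self.table.copy()
            self.table["mob_class"] = [
                GENUS_TO_CLASS.get(g, "unclassified") for g in self.table["genus"]
            ]
        bad = set(self.table["mob_class"]) - set(MOB_CLASSES)
        if bad:
            raise ValidationError(f"unknown mob_class values: {sorted(bad)}")
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate ASV ids in taxonomy table")

    def genus(self, asv_id: str) -> str:
        if asv_id in self.table.index:
            return str(self.table.at[asv_id, "genus"])
        return "unclassified"

    def mob_class(self, asv_id: str) -> str:
        if asv_id in self.table.index:
            return str(self.table.at[asv_id, "mob_class"])
        return "unclassified"

    def genus_series(self, asv_ids) -> pd.Series:
        return pd.Series([self.genus(a) for a in asv_ids], index=list(asv_ids))

    def class_series(self, asv_ids) -> pd.Series:
        return pd.Series([self.mob_class(a) for a in asv_ids], index=list(asv_ids))


@dataclass
class SoilTable:
    """Per-sample soil physicochemistry.

    Columns: pH (unitless), EC (uS/cm), SWC (%), TOC (%), TN (%),
    TP / NH4 / NO3 (mg/kg).  Missing values stay as NaN and are excluded
    pairwise in correlation stages.
    """

    table: pd.DataFrame  # index = sample_id

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate sample ids in soil table")
        if "pH" in self.table.columns:
            ph = self.table["pH"].dropna()
            if ((ph <= 0) | (ph >= 14)).any():
                raise ValidationError("pH outside (0, 14)")
        conc = [c for c in self.table.columns if c != "pH"]
        vals = self.table[conc].to_numpy(dtype=float)
        if np.nan_to_num(vals, nan=0.0).min() < 0:
            raise ValidationError("negative concentration in soil table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def align_to(self, sample_ids) -> "SoilTable":
        ids = [s for s in sample_ids if s in self.table.index]
        return SoilTable(self.table.loc[ids].copy())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_asv_table(counts_path, meta_path, orientation: str = "samples_as_rows") -> AsvTable:
    """Read a feature table plus its sample-metadata table.

    ``orientation`` must name which axis holds samples; it is never guessed
    from shape (a subset of a 104 x 1338 table is ambiguous).
    """
    if orientation not in ("samples_as_rows", "samples_as_cols"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    counts = pd.read_csv(counts_path, sep=_sep_for(counts_path), index_col=0)
    if orientation == "samples_as_cols":
        counts = counts.T
    meta = pd.read_csv(meta_path, sep=_sep_for(meta_path), index_col=0)
    return AsvTable(counts, meta)


def write_asv_table(asv: AsvTable, counts_path, meta_path) -> None:
    asv.counts.to_csv(counts_path, sep=_sep_for(counts_path))
    asv.sample_meta.to_csv(meta_path, sep=_sep_for(meta_path))


def read_taxonomy(path) -> TaxonomyMap:
    return TaxonomyMap(pd.read_csv(path, sep=_sep_for(path), index_col=0))


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    tax.table.to_csv(path, sep=_sep_for(path))


def read_soil_table(path) -> SoilTable:
    return SoilTable(pd.read_csv(path, sep=_sep_for(path), index_col=0))


def write_soil_table(soil: SoilTable, path) -> None:
    soil.table.to_csv(path, sep=_sep_for(path))


def read_incubation(path) -> pd.DataFrame:
    """Incubation records: one row per vial with CH4 mixing ratios and constants."""
    return pd.read_csv(path, sep=_sep_for(path))


def write_incubation(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep=_sep_for(path), index=False)


NETWORK_FORMATS = ("graphml", "edgelist")


def write_network(net: nx.Graph, path, format: str = "graphml") -> None:
    """Serialise a co-occurrence network.

    Edges carry ``rho`` (Spearman) and ``sign`` attributes; nodes carry
    ``genus`` and ``mob_class`` where known.
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format: {format!r}")
    if format == "graphml":
        nx.write_graphml(net, path)
    else:
        rows = [
            {"source": u, "target": v, "rho": d.get("rho", np.nan),
             "sign": d.get("sign", "")}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "rho", "sign"]).to_csv(
            path, sep="\t", index=False
        )


def read_network(path, format: str = "graphml") -> nx.Graph:
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format: {format!r}")
    if format == "graphml":
        return nx.read_graphml(path)
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(row["source"], row["target"], rho=float(row["rho"]),
                   sign=str(row["sign"]))
    return g
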