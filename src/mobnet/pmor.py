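"""Potential methane oxidation rates (PMORs) from two-point headspace depletion.

Soil is incubated in sealed serum vials whose headspace starts near 2% CH4
(20 mmol mol^-1); the mixing ratio is measured on day 1 and day 15.  The
depletion slope is converted to a mass rate through the ideal gas law:

    PMOR = dc/dt * MM * (PA * VH) / (R * (TST + T)) / Ws

with dc/dt in mmol mol^-1 day^-1, MM the molar mass of CH4 (g mol^-1), PA the
atmospheric pressure (kPa), VH the headspace volume (L), R the gas constant
(m^3 Pa K^-1 mol^-1), TST = 273.15 K, T the incubation temperature (deg C) and
Ws the soil dry weight (g).  Unit conversions (mmol->mol, kPa->Pa, L->m^3,
g->ng) make the output ng CH4 g^-1 (dry soil) day^-1.  A positive PMOR means
net CH4 consumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default physical constants for a 120 mL vial with 5 g dry soil at 25 degC
DEFAULT_MM = 16.04       # g mol^-1, CH4
DEFAULT_TST = 273.15     # K
DEFAULT_R = 8.314        # m^3 Pa K^-1 mol^-1
DEFAULT_VH = 0.115       # L headspace
DEFAULT_PA = 101.325     # kPa
DEFAULT_T = 25.0         # degC incubation
DEFAULT_WS = 5.0         # g dry soil


@dataclass
class IncubationRecord:
    """One vial's constants and the CH4 mixing ratios at the two time points."""

    sample_id: str
    c_t1: float            # mmol mol^-1 at t1
    c_t2: float            # mmol mol^-1 at t2
    t1: float = 1.0        # day
    t2: float = 15.0       # day
    VH: float = DEFAULT_VH
    PA: float = DEFAULT_PA
    Ws: float = DEFAULT_WS
    T: float = DEFAULT_T
    MM: float = DEFAULT_MM
    TST: float = DEFAULT_TST
    R: float = DEFAULT_R

    def __post_init__(self) -> None:
        if self.t2 <= self.t1:
            raise ValueError(f"{self.sample_id}: t2 must exceed t1")
        if min(self.VH, self.PA, self.Ws) <= 0:
            raise ValueError(f"{self.sample_id}: VH, PA, Ws must be positive")
        if self.c_t1 < 0 or self.c_t2 < 0:
            raise ValueError(f"{self.sample_id}: mixing ratios must be >= 0")


@dataclass
class PmorResult:
    sample_id: str
    dcdt: float   # mmol mol^-1 day^-1, positive = consumption
    pmor: float   # ng CH4 g^-1 dry soil day^-1


def compute_dcdt(rec: IncubationRecord) -> float:
    """Two-point depletion slope (mmol mol^-1 day^-1); positive when CH4 falls."""
    return (rec.c_t1 - rec.c_t2) / (rec.t2 - rec.t1)


def headspace_air_moles(rec: IncubationRecord) -> float:
    """Moles of air in the headspace at the incubation temperature."""
    pa_pascal = rec.PA * 1e3
    vh_m3 = rec.VH * 1e-3
    return pa_pascal * vh_m3 / (rec.R * (rec.TST + rec.T))


def compute_pmor(rec: IncubationRecord, blank_dcdt: float = 0.0) -> PmorResult:
    """PMOR for one vial.

    ``blank_dcdt`` optionally subtracts a sterilised-blank depletion slope
    (default 0: blanks show no significant depletion).
    """
    dcdt = compute_dcdt(rec) - blank_dcdt
    n_air = headspace_air_moles(rec)
    # mmol/mol -> mol/mol (1e-3), g -> ng (1e9)
    pmor = dcdt * 1e-3 * n_air * rec.MM * 1e9 / rec.Ws
    return PmorResult(rec.sample_id, dcdt, pmor)


def pmor_per_unit_dcdt(rec: IncubationRecord) -> float:
    """ng g^-1 day^-1 produced by a slope of 1 mmol mol^-1 day^-1."""
    return headspace_air_moles(rec) * 1e-3 * rec.MM * 1e9 / rec.Ws


def records_from_frame(df: pd.DataFrame) -> list[IncubationRecord]:
    """Build vial records from an incubation table (one row per vial)."""
    defaults = {"t1": 1.0, "t2": 15.0, "VH": DEFAULT_VH, "PA": DEFAULT_PA,
                "Ws": DEFAULT_WS, "T": DEFAULT_T, "MM": DEFAULT_MM,
                "TST": DEFAULT_TST, "R": DEFAULT_R}
    recs = []
    for _, row in df.iterrows():
        kwargs = {k: float(row[k]) for k in defaults if k in df.columns}
        recs.append(IncubationRecord(
            sample_id=str(row["sample_id"]),
            c_t1=float(row["c_t1"]), c_t2=float(row["c_t2"]), **kwargs))
    return recs


def compute_pmor_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-vial PMORs plus the per-sample mean and SD across replicate vials.

    Replicates are averaged after the rate computation; columns
    ``pmor_mean`` / ``pmor_sd`` repeat the per-sample summary on each vial row.
    """
    results = [compute_pmor(r) for r in records_from_frame(df)]
    out = pd.DataFrame(
        {"sample_id": [r.sample_id for r in results],
         "dcdt": [r.dcdt for r in results],
         "pmor": [r.pmor for r in results]}
    )
    grp = out.groupby("sample_id")["pmor"]
    out["pmor_mean"] = out["sample_id"].map(grp.mean())
    out["pmor_sd"] = out["sample_id"].map(grp.std(ddof=1)).fillna(0.0)
    return out


def sample_mean_pmor(df: pd.DataFrame) -> pd.Series:
    """Mean PMOR per sample id (replicate vials averaged)."""
    table = compute_pmor_table(df)
    return table.groupby("sample_id")["pmor"].mean()
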