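import numpy as np
import pandas as pd
import pytest

from mobnet.io_tables import AsvTable, SoilTable, TaxonomyMap
from mobnet.synthetic_data import EffectSpec, StudyDesign, generate_study


@pytest.fixture(scope="session")
def study():
    """Default synthetic study (full design, seeded once per session)."""
    return generate_study(StudyDesign(seed=7))


@pytest.fixture(scope="session")
def small_study():
    """Reduced study for fast structural tests."""
    return generate_study(StudyDesign(seed=11, n_asvs=60, plots_per_site=3))


@pytest.fixture
def toy_asv():
    counts = pd.DataFrame(
        [[5, 0, 3], [2, 7, 0], [1, 1, 1], [0, 4, 9]],
        index=["s1", "s2", "s3", "s4"],
        columns=["A1", "A2", "A3"],
    )
    meta = pd.DataFrame(
        {"site": ["X", "X", "Y", "Y"], "depth": ["D1", "D2", "D1", "D2"],
         "plot": ["p1", "p1", "p2", "p2"]},
        index=counts.index,
    )
    return AsvTable(counts, meta)


@pytest.fixture
def toy_taxonomy():
    return TaxonomyMap(pd.DataFrame(
        {"genus": ["Methylobacter", "Methylocystis", "unclassified"],
         "mob_class": ["typeI", "typeII", "unclassified"]},
        index=["A1", "A2", "A3"],
    ))


@pytest.fixture
def toy_soil():
    rng = np.random.default_rng(3)
    n = 12
    return SoilTable(pd.DataFrame(
        {"pH": rng.uniform(6, 9, n), "EC": rng.uniform(100, 2000, n),
         "SWC": rng.uniform(20, 70, n), "TOC": rng.uniform(1, 9, n),
         "TN": rng.uniform(0.1, 0.7, n), "TP": rng.uniform(400, 800, n),
         "NH4": rng.uniform(5, 30, n), "NO3": rng.uniform(3, 15, n)},
        index=[f"s{i}" for i in range(n)],
    ))
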