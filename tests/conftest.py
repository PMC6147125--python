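import numpy as np
import pandas as pd
import pytest

from paddyweb.conet import AbundanceTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_metadata(samples, days, temperature=30.0):
    rows = []
    for s, d in zip(samples, days):
        rep = sum(1 for x in rows if x["day"] == d) + 1
        rows.append({"sample": s, "day": d, "temperature_C": temperature, "replicate": rep})
    return pd.DataFrame(rows).set_index("sample")


@pytest.fixture
def small_table():
    """4 OTUs (3 with family assignment, 1 order-level) x 6 samples."""
    counts = pd.DataFrame(
        {
            "s1": [5, 7, 8, 2],
            "s2": [1, 2, 3, 4],
            "s3": [10, 0, 5, 1],
            "s4": [3, 3, 3, 3],
            "s5": [6, 1, 2, 8],
            "s6": [2, 9, 4, 0],
        },
        index=["otu1", "otu2", "otu3", "otu4"],
    )
    lineage = {
        "otu1": "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae",
        "otu2": "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae",
        "otu3": "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;Methanosarcinaceae",
        "otu4": "Bacteria;Firmicutes;Clostridia;Clostridiales",  # order level only
    }
    meta = make_metadata(counts.columns, days=[5, 5, 11, 11, 16, 16])
    return AbundanceTable(counts, lineage, meta)


@pytest.fixture
def chem_frame():
    """Two days x 2 replicates of plausible slurry chemistry at 30 degC."""
    return pd.DataFrame(
        {
            "day": [5, 5, 30, 30],
            "replicate": [1, 2, 1, 2],
            "temperature_C": [30.0] * 4,
            "pH": [7.0] * 4,
            "acetate_mM": [8.4, 8.0, 0.5, 0.6],
            "propionate_mM": [0.6, 0.7, 0.3, 0.3],
            "pH2_kPa": [0.05, 0.04, 0.002, 0.002],
            "pCO2_kPa": [20.0] * 4,
            "pCH4_kPa": [0.15, 0.2, 48.5, 48.0],
        }
    )
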