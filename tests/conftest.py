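import numpy as np
import pandas as pd
import pytest

from ki67flow import load_rule_catalog
from ki67flow.io import EventTable, SamplePair
from ki67flow.simulate import default_tumor_populations, simulate_pair
from ki67flow.standins import (
    collagen_standin_panel,
    cytokeratin_standin_panel,
    ki67_standin_isoform1,
    ki67_standin_isoform2,
)


@pytest.fixture(scope="session")
def catalog():
    return load_rule_catalog()


@pytest.fixture(scope="session")
def ki67_isoforms():
    return ki67_standin_isoform1(), ki67_standin_isoform2()


@pytest.fixture(scope="session")
def panels():
    return cytokeratin_standin_panel(), collagen_standin_panel()


@pytest.fixture(scope="session")
def tumor_pair():
    """Mid-size tumour mixture pair with ground truth (true LI 20%)."""
    return simulate_pair(default_tumor_populations(0.20), 40_000, seed=11)


def make_table(values: dict, stain: str = "antibody", **extra) -> EventTable:
    """Small hand-built event table; values maps role -> list."""
    names = {"FSC": "FSC-A", "SSC": "SSC-A", "DNA": "DAPI-A",
             "CK": "FITC-A", "KI67": "APC-A"}
    n = max(len(v) for v in values.values())
    data = {}
    cmap = {}
    for role, vals in values.items():
        data[names[role]] = list(vals)
        cmap[role] = names[role]
    for role in ("FSC", "SSC", "DNA"):
        if role not in cmap:
            data[names[role]] = [1.0] * n
            cmap[role] = names[role]
    return EventTable(data=pd.DataFrame(data), channel_map=cmap,
                      stain=stain, **extra)


@pytest.fixture()
def make_event_table():
    return make_table
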