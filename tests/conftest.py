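import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mafitkit.data import FitnessTable

settings.register_profile(
    "ci", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20251)


def make_table(anc=None, ma=None, ctrl=None, trait="liquid_growth", G=994):
    """Build a small single-trait FitnessTable from plain value lists.

    ``ma``/``ctrl`` may be dicts line_id -> list of replicate values or a
    flat list (one replicate per line).
    """
    rows = []
    for i, v in enumerate(anc or []):
        rows.append(dict(line_id="ANC", group="ancestor", trait=trait,
                         block=np.nan, replicate=i, value=v))
    for group, data, prefix in (("MA", ma, "MA"), ("control", ctrl, "C")):
        if data is None:
            continue
        if not isinstance(data, dict):
            data = {f"{prefix}{i + 1:03d}": [v] for i, v in enumerate(data)}
        for lid, vals in data.items():
            for r, v in enumerate(vals):
                rows.append(dict(line_id=lid, group=group, trait=trait,
                                 block=np.nan, replicate=r, value=v))
    return FitnessTable(df=pd.DataFrame(rows), G=G)


@pytest.fixture
def small_table():
    return make_table(anc=[12.0, 12.0, 12.0], ma=[10.0, 14.0])
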