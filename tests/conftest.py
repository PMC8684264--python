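import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mxifhet.classify import assign_surrogate_subtype
from mxifhet.synthetic import CoreSpec, generate_core


@pytest.fixture(scope="session")
def luma_bundle():
    """One LumA core with a mixed composition, fixed seed, full ground truth."""
    spec = CoreSpec(
        core_id="spotA",
        case_id="case1",
        pair_id="case1",
        subtype="LumA",
        n_cells=800,
        class_fractions={13: 0.5, 9: 0.3, 1: 0.2},
    )
    return generate_core(spec, seed=42)


@pytest.fixture(scope="session")
def luma_meta(luma_bundle):
    return assign_surrogate_subtype(luma_bundle.metadata.drop(columns=["subtype"]))


def make_cells(rows: list[dict]) -> pd.DataFrame:
    """Minimal cell table from partial row dicts (defaults fill the schema)."""
    defaults = {
        "core_id": "core1",
        "centroid_x": 0.0,
        "centroid_y": 0.0,
        "perimeter_px": 120.0,
        "cell_area_px": 500.0,
        "nuclear_area_px": 30.0,
        "qc_pass": True,
    }
    out = []
    for i, row in enumerate(rows):
        r = dict(defaults)
        r["cell_id"] = f"c{i}"
        r.update(row)
        out.append(r)
    return pd.DataFrame(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
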