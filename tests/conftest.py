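import numpy as np
import pandas as pd
import pytest

from gmapkit.manifest import BarcodeLibrary
from gmapkit import simulate as sim


def random_seq(rng: np.random.Generator, length: int = 21) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def small_library() -> BarcodeLibrary:
    """Deterministic 50-barcode library with two duplicated sequences."""
    return sim.make_library(50, n_duplicated=2, seed=42)


@pytest.fixture(scope="session")
def desk_library() -> BarcodeLibrary:
    """Desk-scale 1000-barcode library used by matcher tests."""
    return sim.make_library(1000, n_duplicated=5, seed=7)


@pytest.fixture
def feature_table() -> pd.DataFrame:
    """Tiny hand-built feature-intensity table with GC-background probes."""
    rows = []
    fid = 0
    for bc, gc, vals in [("b1", 8, (100.0, 120.0, 110.0)), ("b2", 12, (300.0, 280.0, 5000.0))]:
        for k, v in enumerate(vals, start=1):
            rows.append((f"F{fid}", "HP", bc, k, gc, v))
            fid += 1
    for gc, vals in [(8, (40.0, 44.0, 36.0)), (12, (60.0, 58.0, 62.0))]:
        for v in vals:
            rows.append((f"F{fid}", "GCBG", "", 1, gc, v))
            fid += 1
    return pd.DataFrame(
        rows,
        columns=["feature_id", "class_id", "barcode_id", "replicate_index", "gc_count", "intensity"],
    )
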