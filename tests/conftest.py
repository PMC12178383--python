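import numpy as np
import pandas as pd
import pytest

from npxbio.npx_core import AssayDefinition, NpxMatrix
from npxbio.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (168 samples, 276 assays) reused across tests."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture(scope="session")
def signal_cohort():
    """Cohort with a planted AdvSM signature on 20 proteins (+1.5 NPX)."""
    effects = {(f"P{i:04d}", "AdvSM"): 1.5 for i in range(1, 21)}
    return generate_cohort(CohortConfig(seed=7, effect_table=effects))


def make_matrix(values, below_lod=None, names=None, panels=None, flagged=None):
    """Small-matrix helper: build an NpxMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    names = names or [f"A{j}" for j in range(p)]
    panels = panels or ["panel1"] * p
    assays = [AssayDefinition(name=nm, panel=pn) for nm, pn in zip(names, panels)]
    idx = pd.Index([f"S{i}" for i in range(n)], name="SampleID")
    below = np.zeros((n, p), dtype=bool) if below_lod is None else np.asarray(below_lod)
    below = below & ~np.isnan(values)
    return NpxMatrix(
        assays=assays,
        values=pd.DataFrame(values, index=idx),
        below_lod=pd.DataFrame(below, index=idx),
        low_detection_flagged=set(flagged or ()),
    )
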