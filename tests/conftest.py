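import numpy as np
import pandas as pd
import pytest

from crossde.io import ExpressionStudy, MICROARRAY, RNASEQ
from crossde.simulate import SimulationConfig, generate_dual_study


def make_study(values, platform=MICROARRAY, groups=None, study="study1", region="macular"):
    """Build a small ExpressionStudy from a nested list / array."""
    arr = np.asarray(values, dtype=float)
    genes = [f"g{i+1}" for i in range(arr.shape[0])]
    samples = [f"s{i+1}" for i in range(arr.shape[1])]
    if platform == RNASEQ:
        arr = arr.astype(np.int64)
    df = pd.DataFrame(arr, index=pd.Index(genes, name="gene"), columns=samples)
    meta = None
    if groups is not None:
        meta = pd.DataFrame(
            {"study": study, "group": list(groups), "region": region},
            index=pd.Index(samples, name="sample"),
        )
    return ExpressionStudy(df, platform, meta)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down simulation preserving the default study conditions."""
    return SimulationConfig(
        n_genes=2000, group_sizes=(12, 14, 10, 20), dropout_fraction=0.01, seed=42
    )


@pytest.fixture(scope="session")
def small_simulation(small_config):
    return generate_dual_study(small_config)


@pytest.fixture(scope="session")
def default_simulation():
    """One realization at the full default study conditions."""
    return generate_dual_study(SimulationConfig(seed=7))
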