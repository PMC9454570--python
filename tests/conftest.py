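import numpy as np
import pandas as pd
import pytest

from mirrescue.matrix import GROUPS, ExpressionMatrix
from mirrescue.simulate import SimulationConfig, simulate_dataset


def make_matrix(values: np.ndarray, probe_prefix: str = "G",
                flags: np.ndarray | None = None) -> ExpressionMatrix:
    """Wrap a raw array (rows x 4*reps columns) into an ExpressionMatrix."""
    n, m = values.shape
    assert m % len(GROUPS) == 0
    reps = m // len(GROUPS)
    samples = [f"{g}_{r + 1}" for g in GROUPS for r in range(reps)]
    vdf = pd.DataFrame(values, index=[f"{probe_prefix}{i}" for i in range(n)],
                       columns=samples)
    groups = pd.Series({s: s.rsplit("_", 1)[0] for s in samples})
    fdf = None
    if flags is not None:
        fdf = pd.DataFrame(flags, index=vdf.index, columns=samples)
    return ExpressionMatrix(values=vdf, groups=groups, flags=fdf)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic bundle reused across read-only tests."""
    cfg = SimulationConfig(n_genes=300, n_mirnas=80, n_true_pairs=15,
                           dropout_p=0.0, seed=11)
    mrna, mirna, truth, tables = simulate_dataset(cfg)
    return cfg, mrna, mirna, truth, tables
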