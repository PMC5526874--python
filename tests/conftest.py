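import numpy as np
import pandas as pd
import pytest

from cresig.model import ExpressionMatrix
from cresig.simulate import SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20170725)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_genes=600, n_core=30, n_specific=30, n_down=30,
        delta=1.0, sigma=0.25, n_reps=3, promoter_len=200,
        q1_enrich=0.9, seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture
def toy_expr():
    genes = ["g1", "g2", "g3"]
    samples = ["c1", "c2", "t1", "t2"]
    values = pd.DataFrame(
        [[1.0, 1.0, 2.0, 2.0], [5.0, 5.0, 5.0, 5.0], [3.0, 4.0, 1.0, 2.0]],
        index=genes, columns=samples,
    )
    cond = pd.Series({"c1": "CT", "c2": "CT", "t1": "FSK", "t2": "FSK"})
    return ExpressionMatrix(values, cond)


def make_deg_table(genes, logfc, t_mod=None, p_raw=None, p_adj=None):
    """Hand-rolled DEG table builder used across test modules."""
    n = len(genes)
    logfc = np.asarray(logfc, dtype=float)
    t_mod = np.asarray(t_mod if t_mod is not None else logfc * 3.0, dtype=float)
    p_raw = np.asarray(p_raw if p_raw is not None else np.full(n, 0.01), dtype=float)
    p_adj = np.asarray(p_adj if p_adj is not None else p_raw, dtype=float)
    return pd.DataFrame(
        {
            "gene": list(genes),
            "logFC": logfc,
            "t_mod": t_mod,
            "p_raw": p_raw,
            "p_adj": np.maximum(p_adj, p_raw),
            "direction": np.where(logfc > 0, "UP", "DOWN"),
            "mean_expr": np.full(n, 8.0),
        }
    )
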