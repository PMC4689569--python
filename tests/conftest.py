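import numpy as np
import pandas as pd
import pytest

from codonshift.simulate import SyntheticConfig, generate_all


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic universe with planted effects (fixed seed)."""
    cfg = SyntheticConfig(n_genes=400, master_seed=11)
    return cfg, generate_all(cfg)


def make_calls(n_down: int, n_up: int, n_total: int, prefix: str = "p") -> pd.DataFrame:
    """A DE-call table with the given composition (fold/p filled consistently)."""
    calls = ["down"] * n_down + ["up"] * n_up + ["unchanged"] * (n_total - n_down - n_up)
    fold = np.where(np.array(calls) == "down", 0.5, np.where(np.array(calls) == "up", 2.0, 1.0))
    p = np.where(np.array(calls) == "unchanged", 0.9, 0.001)
    return pd.DataFrame(
        {
            "gene_id": [f"{prefix}{i:05d}" for i in range(n_total)],
            "fold_change": fold,
            "p_value": p,
            "call": calls,
        }
    )
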