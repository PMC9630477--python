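import numpy as np
import pandas as pd
import pytest

import mrscreen as m


def harmonized_frame(beta_exp, se_exp, beta_out, se_out):
    """Build a harmonized instrument table directly from aligned arrays."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    return pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(len(beta_exp))],
            "beta_exp": beta_exp,
            "se_exp": np.broadcast_to(np.asarray(se_exp, dtype=float), beta_exp.shape),
            "beta_out": np.asarray(beta_out, dtype=float),
            "se_out": np.broadcast_to(np.asarray(se_out, dtype=float), beta_exp.shape),
        }
    )


def harmonized_from_sim(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Harmonized table for simulator output generated without allele flips
    (tables are row-aligned by construction, so no alignment is needed)."""
    return pd.DataFrame(
        {
            "SNP": exposure["SNP"],
            "beta_exp": exposure["BETA"],
            "se_exp": exposure["SE"],
            "beta_out": outcome["BETA"],
            "se_out": outcome["SE"],
        }
    )


def random_harmonized(rng: np.random.Generator, j: int) -> pd.DataFrame:
    """Random small instrument instance for oracle-equivalence checks."""
    beta_exp = rng.uniform(0.05, 0.5, j) * rng.choice([-1.0, 1.0], j)
    return harmonized_frame(
        beta_exp,
        rng.uniform(0.005, 0.05, j),
        rng.normal(0.0, 0.2, j),
        rng.uniform(0.005, 0.1, j),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def sim_pair():
    """A small causal exposure/outcome simulation with truth (beta = 0.3)."""
    cfg = m.SimulationConfig(n_snps=40, n_exp=50000, causal_beta=0.3, seed=11)
    return m.simulate_summary_stats(cfg)
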