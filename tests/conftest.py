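import numpy as np
import pandas as pd
import pytest

from cortmr import SimulationConfig, simulate_pair


def make_harmonized(ratios=None, *, beta_exp=None, se_exp=None, beta_out=None,
                    se_out=None, eaf=None, ids=None):
    """Build a harmonized instrument table from ratio-level ingredients.

    With only ``ratios`` given, beta_exp is 1 and se_out is 1 for every
    variant, so the Wald ratios equal ``ratios`` with unit standard
    errors.
    """
    if ratios is not None:
        n = len(ratios)
        beta_exp = np.ones(n) if beta_exp is None else np.asarray(beta_exp, float)
        beta_out = np.asarray(ratios, float) * beta_exp
    else:
        beta_exp = np.asarray(beta_exp, float)
        beta_out = np.asarray(beta_out, float)
        n = len(beta_exp)
    se_exp = np.full(n, 0.01) if se_exp is None else np.asarray(se_exp, float)
    se_out = np.ones(n) if se_out is None else np.asarray(se_out, float)
    eaf = np.full(n, 0.3) if eaf is None else np.asarray(eaf, float)
    ids = [f"rs{i+1}" for i in range(n)] if ids is None else list(ids)
    return pd.DataFrame({
        "variant_id": ids,
        "chrom": ["1"] * n,
        "pos": np.arange(1, n + 1) * 1000,
        "effect_allele": ["A"] * n,
        "other_allele": ["G"] * n,
        "beta_exp": beta_exp, "se_exp": se_exp, "eaf_exp": eaf,
        "beta_out": beta_out, "se_out": se_out,
        "r2_exp": 2 * beta_exp ** 2 * eaf * (1 - eaf),
        "f_stat": np.full(n, 100.0),
        "flipped": [False] * n, "proxy_of": [""] * n,
    })


@pytest.fixture(scope="session")
def default_sim():
    """One simulated pair under a modest causal effect, shared across tests."""
    cfg = SimulationConfig(theta=0.1, seed=11)
    return cfg, simulate_pair(cfg)


@pytest.fixture(scope="session")
def clean_sim():
    """No palindromes, no nulls: every instrument should survive selection."""
    cfg = SimulationConfig(theta=0.1, seed=5, n_null_snps=0,
                           palindrome_frac=0.0, swap_frac=0.0,
                           complement_frac=0.0)
    return cfg, simulate_pair(cfg)
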