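import numpy as np
import pandas as pd
import pytest

from polyarch.synthdata import (
    ArchitectureSpec,
    make_ld_profile,
    simulate_genotypes,
    uniform_layout,
)


@pytest.fixture(scope="session")
def small_panel():
    """2000 x 500 panel with moderate LD, one chromosome."""
    layout = uniform_layout(500, n_chromosomes=1, bp_spacing=2000, cm_per_mb=1.0)
    return simulate_genotypes(2000, layout, ld_decay=0.5, seed=101)


@pytest.fixture(scope="session")
def two_chrom_panel():
    layout = uniform_layout(400, n_chromosomes=2, bp_spacing=5000, cm_per_mb=1.0)
    return simulate_genotypes(1500, layout, ld_decay=0.3, seed=7)


@pytest.fixture(scope="session")
def tiny_profile():
    return make_ld_profile(5000, block_size=50, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def base_spec():
    return ArchitectureSpec(pi1=0.01, h2=0.3)


def make_assoc_frame(n, seed=0, n_obs=1000):
    """Synthetic association frame with valid columns for unit tests."""
    r = np.random.default_rng(seed)
    se = r.uniform(0.01, 0.05, n)
    beta = r.standard_normal(n) * se
    t = beta / se
    from scipy import stats

    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "chrom": "chr1",
        "pos_bp": np.arange(1, n + 1) * 100,
        "maf": r.uniform(0.01, 0.5, n),
        "info": 1.0,
        "n_obs": n_obs,
        "beta": beta,
        "se": se,
        "t_stat": t,
        "p": 2 * stats.norm.sf(np.abs(t)),
    })
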