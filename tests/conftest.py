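import numpy as np
import pandas as pd
import pytest

from sfactor import ldsc, synthetic

# canonical study conditions: four items loading on one factor with h2 7.6%
LOADINGS = np.array([0.9, 1.0, 0.7, 0.5])
RESIDUAL_H2 = np.array([0.01, 0.01, 0.01, 0.01])
FACTOR_H2 = 0.076
PI_C = 0.005
N_GWAS = 100_000


@pytest.fixture(scope="session")
def ld_panel():
    """Heterogeneous LD panel (M=20k) shared across the LDSC/factor tests."""
    return synthetic.simulate_ld_panel(20_000, seed=99)


@pytest.fixture(scope="session")
def ld_free():
    """LD-free reference: every LD score exactly 1."""
    return synthetic.simulate_ld_blocks(20_000, 1, 0.0, seed=99)


@pytest.fixture(scope="session")
def true_model():
    return synthetic.TrueModel(
        n_snps=20_000,
        loadings=LOADINGS,
        residual_h2=RESIDUAL_H2,
        factor_h2=FACTOR_H2,
        pi_c=PI_C,
        seed=11,
    )


@pytest.fixture(scope="session")
def true_S():
    return FACTOR_H2 * np.outer(LOADINGS, LOADINGS) + np.diag(RESIDUAL_H2)


@pytest.fixture(scope="session")
def item_sumstats(true_model, ld_panel):
    """One realization of the four indicator GWAS under full sample overlap."""
    return synthetic.simulate_sumstats(
        true_model, ld_panel, N_GWAS, overlap_fraction=1.0
    )


@pytest.fixture(scope="session")
def cov_struct(item_sumstats, ld_panel):
    return ldsc.genetic_covariance(
        item_sumstats, ld_panel, names=["tlnwl", "tsh", "ash", "attempt"]
    )


@pytest.fixture()
def exact_cov():
    """A CovStruct whose S is exactly one-factor: lam=(0.8,1,0.6,0.4)-pattern."""
    lam = np.array([0.8, 1.0, 0.6, 0.4])
    phi = 0.07
    theta = np.array([0.02, 0.015, 0.01, 0.03])
    S = phi * np.outer(lam, lam) + np.diag(theta)
    V = np.diag(np.full(10, 1e-4))
    return ldsc.CovStruct(names=["a", "b", "c", "d"], S=S, V=V), lam, phi, theta


@pytest.fixture(scope="session")
def toy_weights():
    rng = np.random.default_rng(5)
    m = 400
    pairs = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
    idx = rng.integers(0, 4, m)
    return pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(m)],
            "A1": [pairs[i][0] for i in idx],
            "A2": [pairs[i][1] for i in idx],
            "BETA": rng.standard_normal(m) * 0.02,
        }
    )
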