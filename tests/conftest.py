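import numpy as np
import pandas as pd
import pytest

from mrpath.sumstats import InstrumentTable


def make_table(beta_exp, se_exp, beta_out, se_out, eaf=None, n_exp=50_000, n_out=50_000):
    """Build an InstrumentTable directly from effect arrays (test fixture)."""
    k = len(beta_exp)
    eaf = eaf if eaf is not None else np.full(k, 0.3)
    data = pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(k)],
            "chrom": ["1"] * k,
            "pos": np.arange(1, k + 1) * 1000,
            "beta_exp": np.asarray(beta_exp, float),
            "se_exp": np.asarray(se_exp, float),
            "beta_out": np.asarray(beta_out, float),
            "se_out": np.asarray(se_out, float),
            "eaf": np.asarray(eaf, float),
            "n_exp": np.full(k, n_exp),
            "n_out": np.full(k, n_out),
        }
    )
    return InstrumentTable(data, provenance="test-fixture")


def random_table(rng, k=10, n=50_000):
    """A random but well-conditioned instrument table."""
    bx = rng.uniform(0.05, 0.3, k) * rng.choice([-1.0, 1.0], k)
    sx = rng.uniform(0.005, 0.02, k)
    by = 0.3 * bx + rng.normal(0, 0.01, k)
    sy = rng.uniform(0.005, 0.02, k)
    return make_table(bx, sx, by, sy, n_exp=n, n_out=n)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ivw_hand_table():
    """The two-SNP table whose fixed-effect IVW is exactly 0.4, se 1/sqrt(200)."""
    return make_table([0.1, 0.2], [0.01, 0.01], [0.05, 0.06], [0.01, 0.02])
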