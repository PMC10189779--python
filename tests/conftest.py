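import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrchain import HarmonizedSet, PhenotypePanel

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_panel(
    phenotype_id="trait",
    snp=("rs1", "rs2", "rs3"),
    effect_allele=("A", "C", "G"),
    other_allele=("G", "T", "T"),
    eaf=(0.3, 0.5, 0.7),
    beta=(0.1, -0.05, 0.02),
    se=(0.01, 0.01, 0.01),
    pval=None,
    n=100_000,
    trait_type="continuous",
):
    k = len(snp)
    from scipy import stats

    def fit(x):
        x = np.atleast_1d(np.asarray(x, float))
        return x[:k] if len(x) >= k else np.resize(x, k)

    eaf = fit(eaf)
    beta = fit(beta)
    se = fit(se)
    effect_allele = list(effect_allele)[:k]
    other_allele = list(other_allele)[:k]
    if pval is None:
        pval = np.clip(2 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)
    else:
        pval = fit(pval)
    df = pd.DataFrame(
        {
            "snp": list(snp),
            "effect_allele": list(effect_allele),
            "other_allele": list(other_allele),
            "eaf": list(eaf),
            "beta": beta,
            "se": se,
            "pval": np.asarray(pval, float),
            "n": [n] * k if np.isscalar(n) else list(n),
        }
    )
    return PhenotypePanel(phenotype_id, trait_type, df)


def make_harmonized(beta_x, se_x, beta_y, se_y, **kw) -> HarmonizedSet:
    return HarmonizedSet.from_arrays(beta_x, se_x, beta_y, se_y, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clean_harmonized(rng):
    """30 strong instruments, planted effect 0.3, no pleiotropy."""
    k = 30
    bx0 = rng.uniform(0.03, 0.08, k) * rng.choice([-1, 1], k)
    se_x = np.full(k, 0.0025)
    se_y = np.full(k, 0.0086)
    by = 0.3 * bx0 + rng.normal(0, se_y)
    bx = bx0 + rng.normal(0, se_x)
    return make_harmonized(bx, se_x, by, se_y)
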