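import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrpipe.sumstats import HarmonizedSet, SumStatsTable

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(rows, trait="trait", cohort="cohort1", binary=False, validate=True):
    """Build a SumStatsTable from (vid, ea, oa, eaf, beta, se, pval, n) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"],
    )
    return SumStatsTable.from_frame(
        df, trait_label=trait, cohort_label=cohort, binary=binary, validate=validate
    )


def make_harmonized(bx, sx, by, sy, eaf=None, n_x=100_000, n_y=100_000):
    bx = np.asarray(bx, dtype=float)
    return HarmonizedSet(
        variant_ids=[f"rs{i}" for i in range(len(bx))],
        beta_x=bx,
        se_x=np.asarray(sx, dtype=float),
        beta_y=np.asarray(by, dtype=float),
        se_y=np.asarray(sy, dtype=float),
        n_x=n_x,
        n_y=n_y,
        eaf=None if eaf is None else np.asarray(eaf, dtype=float),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_harmonized(rng, k=20, theta=0.3, noise=True):
    """Random but well-behaved instrument set with true slope ``theta``."""
    bx = rng.uniform(0.05, 0.3, k)
    sx = rng.uniform(0.005, 0.02, k)
    sy = rng.uniform(0.01, 0.05, k)
    by = theta * bx + (rng.normal(0, sy) if noise else 0.0)
    return make_harmonized(bx, sx, by, sy)
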