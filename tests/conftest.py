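import numpy as np
import pytest
from hypothesis import settings

from mrpipe import HarmonizedSet

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_h(bx, by, sy, sx=None, ids=None, eaf=None) -> HarmonizedSet:
    """Assemble a single-exposure HarmonizedSet from raw arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.zeros_like(bx) if sx is None else np.asarray(sx, dtype=float)
    j = len(bx)
    return HarmonizedSet(
        snp_ids=list(ids) if ids is not None else [f"rs{i}" for i in range(j)],
        exposure_names=["exposure"],
        beta_exp=bx.reshape(-1, 1),
        se_exp=sx.reshape(-1, 1),
        beta_out=by,
        se_out=sy,
        eaf=np.asarray(eaf, dtype=float) if eaf is not None else np.full(j, np.nan),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_h(rng):
    """A generic 20-instrument harmonized set with a true effect of 0.2."""
    j = 20
    bx = rng.normal(0.1, 0.03, j)
    sx = np.full(j, 0.004)
    bx = rng.normal(bx, sx)
    sy = rng.uniform(0.01, 0.05, j)
    by = rng.normal(0.2 * bx, sy)
    return make_h(bx, by, sy, sx=sx)
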