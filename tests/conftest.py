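import numpy as np
import pytest

from poolscan.io import PoolInfo, SampleSheet


@pytest.fixture
def paired_sheet() -> SampleSheet:
    """The study design: 4 replicate pairs of E/M pools of 40 females."""
    pools = [PoolInfo(f"E{r}", "E", r, 40) for r in range(1, 5)]
    pools += [PoolInfo(f"M{r}", "M", r, 40) for r in range(1, 5)]
    return SampleSheet(pools)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def classical_tajimas_d(hap: np.ndarray) -> float:
    """Textbook Tajima's D from a 0/1 haplotype matrix (n sequences x L).

    Independent of the pool-seq estimator under test: computed directly
    from the sample frequency spectrum with the standard constants.
    """
    n, _ = hap.shape
    f = hap.mean(axis=0)
    seg = (f > 0) & (f < 1)
    S = int(seg.sum())
    if S < 2:
        return np.nan
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = (2.0 * f[seg] * (1.0 - f[seg]) * n / (n - 1.0)).sum()
    theta = S / a1
    return float((pi - theta) / np.sqrt(e1 * S + e2 * S * (S - 1)))
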