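import numpy as np
import pytest

from lpbtflim import LaserConfig, SimConfig, generate_ground_truth


@pytest.fixture(scope="session")
def laser():
    return LaserConfig()


@pytest.fixture(scope="session")
def small_stream(laser):
    """A modest 80 Mcps ground-truth stream shared across read-only tests."""
    cfg = SimConfig(lifetime=1.0, target_rate=8e7, max_photons=30_000, seed=42)
    return generate_ground_truth(cfg, laser)


def chi2_two_sample(a, b, min_pooled=10):
    """Two-sample chi-square homogeneity statistic and p-value.

    Standard statistic for comparing two histograms of (possibly) different
    totals; bins with fewer than ``min_pooled`` pooled counts are dropped.
    """
    from scipy.stats import chi2 as chi2_dist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = (a + b) >= min_pooled
    a, b = a[keep], b[keep]
    n_a, n_b = a.sum(), b.sum()
    stat = np.sum((np.sqrt(n_b / n_a) * a - np.sqrt(n_a / n_b) * b) ** 2 / (a + b))
    dof = len(a) - 1
    return stat, float(chi2_dist.sf(stat, dof))
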