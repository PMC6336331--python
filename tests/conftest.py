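import pytest

from premasig import SimConfig, simulate_catalog


@pytest.fixture(scope="session")
def small_catalog():
    """12-sample catalog drawn from 3 known signatures (~500 mutations each)."""
    cfg = SimConfig(seed=5, n_samples=12, mutations_per_sample_mean=500)
    return simulate_catalog(cfg)


def enumeration_fisher_2x2(table, rel_tol=1e-7):
    """Independent oracle: two-sided Fisher p by explicit enumeration of all
    2x2 tables with the observed margins, using log-factorials directly."""
    import math

    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lf = [math.lgamma(i + 1) for i in range(n + 1)]
    const = lf[r1] + lf[r2] + lf[c1] + lf[n - c1] - lf[n]

    def logp(x):
        return const - lf[x] - lf[r1 - x] - lf[c1 - x] - lf[r2 - (c1 - x)]

    lo, hi = max(0, c1 - r2), min(r1, c1)
    lp_obs = logp(a)
    cutoff = lp_obs + math.log1p(rel_tol)
    return min(1.0, sum(math.exp(logp(x)) for x in range(lo, hi + 1) if logp(x) <= cutoff))
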