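import numpy as np
import pytest

from polygrm import GenotypeMatrix, ReadCounts


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


def random_read_counts(rng, n=8, m=30, psi=4, mean_depth=5.0, eps=0.0, p=None):
    """Small random dataset under the binomial read model (test helper)."""
    if p is None:
        p = rng.uniform(0.1, 0.9, m)
    x = rng.binomial(psi, np.broadcast_to(p, (n, m)))
    d = rng.negative_binomial(psi, psi / (mean_depth + psi), size=(n, m))
    pi = (x / psi) * (1 - eps) + (1 - x / psi) * eps
    y = rng.binomial(d, pi)
    rc = ReadCounts(y, d, [f"i{i}" for i in range(n)], [f"s{j}" for j in range(m)])
    g = GenotypeMatrix(x.astype(float), rc.individual_ids, rc.snp_ids)
    return rc, g, p
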