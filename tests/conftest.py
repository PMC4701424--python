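import numpy as np
import pytest

from ordspear.core import CountTable, ProbabilityTable


@pytest.fixture
def rng():
    return np.random.default_rng(20210914)


def random_prob_table(rng, max_dim=6, min_dim=2, alpha=1.0) -> ProbabilityTable:
    I, J = rng.integers(min_dim, max_dim + 1, size=2)
    h = rng.dirichlet(np.full(I * J, alpha)).reshape(I, J)
    return ProbabilityTable(h)


def random_interior_table(rng, max_dim=6, min_dim=2) -> ProbabilityTable:
    """Random table with all cells bounded away from zero.

    Suitable for finite-difference gradient checks, where perturbed cells
    must stay inside the simplex.
    """
    I, J = rng.integers(min_dim, max_dim + 1, size=2)
    h = rng.dirichlet(np.ones(I * J)).reshape(I, J)
    h = 0.9 * h + 0.1 / (I * J)
    return ProbabilityTable(h / h.sum())


def random_count_table(rng, max_dim=6, max_n=60) -> CountTable:
    """Random count table guaranteed nondegenerate in both margins."""
    while True:
        I, J = rng.integers(2, max_dim + 1, size=2)
        n = int(rng.integers(4, max_n + 1))
        p = rng.dirichlet(np.ones(I * J))
        counts = rng.multinomial(n, p).reshape(I, J)
        if (counts.sum(axis=1) > 0).sum() >= 2 and (counts.sum(axis=0) > 0).sum() >= 2:
            return CountTable(counts)
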