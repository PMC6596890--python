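"""Shared fixtures and independent test oracles."""

from functools import lru_cache

import numpy as np
import pytest

from admixpair import Cohort, generate_base


def brute_force_min_gd(gd: np.ndarray) -> float:
    """Minimum total GD over all (n-1)!! perfect matchings, by enumeration.

    Independent oracle for the greedy matchers; feasible for n <= 10.
    """
    n = gd.shape[0]
    assert n % 2 == 0 and n <= 10

    @lru_cache(maxsize=None)
    def best(remaining: frozenset) -> float:
        if not remaining:
            return 0.0
        rem = sorted(remaining)
        i = rem[0]
        rest = remaining - {i}
        return min(gd[i, j] + best(rest - {j}) for j in rem[1:])

    return best(frozenset(range(n)))


def random_cohort(
    n: int, K: int = 9, seed: int = 0, with_demo: bool = True
) -> Cohort:
    """A cohort of n independent Dirichlet(1) individuals."""
    rng = np.random.default_rng(seed)
    q = rng.dirichlet(np.ones(K), size=n)
    ages = rng.integers(18, 81, size=n).astype(float) if with_demo else [None] * n
    genders = rng.integers(1, 3, size=n).tolist() if with_demo else [None] * n
    return Cohort.from_arrays(q, ages=list(ages) if with_demo else ages, genders=genders)


@pytest.fixture(scope="session")
def dataset1():
    """The 500-clone-pair base cohort with matched demographics."""
    return generate_base(500, K=9, seed=11)
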