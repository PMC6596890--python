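"""Synthetic Q-format cohorts with known ground-truth pairs.

The generator emulates the validation design used throughout this package:
a base cohort of exact clone pairs (each individual's admixture vector is
copied to its partner, demographics matched), a controlled heterogeneity
ramp obtained by perturbing one member of every pair, and ablations that
delete random individuals so some partners become unrecoverable.

The perturbation scales the odd-numbered admixture components of the
perturbed member by (1 - x) and the even-numbered ones by (1 + x), then
renormalizes the row.  The signs alternate so that renormalization cannot
undo the perturbation (a uniformly scaled row renormalizes back to itself).
With x <= 0.2 no component can leave [0, 1], but values are clipped
defensively before renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Cohort, Individual

__all__ = [
    "SimulatedDataset",
    "DEFAULT_PERTURBATION_LEVELS",
    "generate_base",
    "perturb",
    "remove_individuals",
    "build_suite",
]

#: perturbation grid for the 24-dataset validation suite (fractions).
#: The ramp spans the full [0, 0.20] design range and includes the 0.05 and
#: 0.11 levels at which behaviour changes qualitatively.
DEFAULT_PERTURBATION_LEVELS: tuple[float, ...] = (
    0.0, 0.02, 0.05, 0.08, 0.11, 0.14, 0.17, 0.20,
)

MAX_PERTURBATION = 0.20


@dataclass
class SimulatedDataset:
    """A cohort plus its ground-truth pair map and generation parameters.

    ``truth`` maps every cohort ID to its true partner's ID, or to None when
    the partner has been removed.  It is a symmetric involution over the
    IDs whose partner is present.
    """

    cohort: Cohort
    truth: dict[str, str | None]
    perturbation_x: float = 0.0
    removed: list[str] = field(default_factory=list)
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.cohort.n

    def recoverable_pairs(self) -> int:
        """Number of ground-truth pairs with both members still present."""
        return sum(1 for v in self.truth.values() if v is not None) // 2


def generate_base(
    n_pairs: int,
    K: int = 9,
    seed: int | None = None,
    age_range: tuple[int, int] = (18, 80),
) -> SimulatedDataset:
    """Cohort of ``n_pairs`` exact clone pairs with matched demographics.

    Each pair's admixture vector is drawn from a symmetric Dirichlet(1) over
    K components — i.i.d. positives rescaled to sum to 1 — and copied to the
    partner, so every true pair has GD 0 and the top score of K + 1.  Ages
    (uniform integers over ``age_range``) and genders (1/2, equiprobable)
    are shared within each pair.  Rows are interleaved: rows 2p and 2p + 1
    form true pair p.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.ones(K), size=n_pairs)
    ages = rng.integers(age_range[0], age_range[1] + 1, size=n_pairs)
    genders = rng.integers(1, 3, size=n_pairs)
    q = np.repeat(base, 2, axis=0)
    individuals = []
    truth: dict[str, str | None] = {}
    for p in range(n_pairs):
        id_a, id_b = f"P{p + 1:05d}A", f"P{p + 1:05d}B"
        for iid, row in ((id_a, q[2 * p]), (id_b, q[2 * p + 1])):
            individuals.append(
                Individual(iid, row, age=float(ages[p]), gender=int(genders[p]))
            )
        truth[id_a] = id_b
        truth[id_b] = id_a
    return SimulatedDataset(cohort=Cohort(individuals), truth=truth, seed=seed)


def perturb(ds: SimulatedDataset, x: float) -> SimulatedDataset:
    """Perturb the second member of every true pair by the fraction ``x``.

    Component k of the perturbed row is scaled by (1 - x) when k is
    odd-numbered (1st, 3rd, ... — even 0-based index) and by (1 + x) when
    even-numbered, alternating signs so renormalization cannot reverse the
    change; the row is then clipped to [0, 1] and renormalized to sum 1.
    The first member of each pair and the truth map are untouched.
    """
    if not 0.0 <= x <= MAX_PERTURBATION:
        raise ValueError(f"perturbation x={x} outside [0, {MAX_PERTURBATION}]")
    if x == 0.0:
        return replace(ds, perturbation_x=0.0)
    K = ds.cohort.K
    signs = np.where(np.arange(K) % 2 == 0, -1.0, 1.0)  # 1st component loses
    factors = 1.0 + x * signs
    individuals = []
    for idx, ind in enumerate(ds.cohort):
        if idx % 2 == 1:  # second member of its pair
            row = np.clip(ind.admixture * factors, 0.0, 1.0)
            row /= row.sum()
            ind = Individual(ind.id, row, age=ind.age, gender=ind.gender)
        individuals.append(ind)
    return replace(ds, cohort=Cohort(individuals), perturbation_x=x)


def remove_individuals(
    ds: SimulatedDataset, k: int, seed: int | None = None
) -> SimulatedDataset:
    """Delete ``k`` uniformly random individuals, widowing their partners.

    Truth entries pointing at a removed ID become None (partnerless); the
    remaining entries are unchanged.
    """
    n = ds.cohort.n
    if not 0 <= k < n:
        raise ValueError(f"cannot remove {k} of {n} individuals")
    if k == 0:
        return replace(ds)
    rng = np.random.default_rng(seed)
    drop = set(rng.choice(n, size=k, replace=False).tolist())
    dropped_ids = {ds.cohort.ids[i] for i in drop}
    individuals = [ind for i, ind in enumerate(ds.cohort) if i not in drop]
    truth = {
        ind.id: (
            None
            if ds.truth[ind.id] is None or ds.truth[ind.id] in dropped_ids
            else ds.truth[ind.id]
        )
        for ind in individuals
    }
    return replace(
        ds,
        cohort=Cohort(individuals),
        truth=truth,
        removed=ds.removed + sorted(dropped_ids),
    )


def build_suite(
    seed: int | None = None,
    n_pairs: int = 500,
    K: int = 9,
    levels: tuple[float, ...] = DEFAULT_PERTURBATION_LEVELS,
) -> list[SimulatedDataset]:
    """The 24-dataset validation suite.

    One base cohort of ``n_pairs`` clone pairs is perturbed at each level in
    ``levels`` (datasets 1-8, full size), then each perturbed dataset is
    ablated by removing 1 individual (datasets 9-16) and 20 individuals
    (datasets 17-24).  With the defaults the sizes are 1000, 999 and 980.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=1 + 2 * len(levels))
    base = generate_base(n_pairs, K=K, seed=int(sub[0]))
    full = [perturb(base, x) for x in levels]
    rm1 = [
        remove_individuals(ds, 1, seed=int(sub[1 + i])) for i, ds in enumerate(full)
    ]
    rm20 = [
        remove_individuals(ds, 20, seed=int(sub[1 + len(levels) + i]))
        for i, ds in enumerate(full)
    ]
    return full + rm1 + rm20
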