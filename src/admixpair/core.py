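"""Pairwise ancestry distances, match scores and the greedy pairing algorithms.

Individuals are described by a vector of K admixture proportions (one row of
an ADMIXTURE Q file, summing to 1).  The genetic distance (GD) between two
individuals is the sum of squared differences of their admixture vectors —
deliberately the *squared* Euclidean distance, no square root.  The match
score is an integer in [0, K+1]: one point if the pair is jointly age- and
gender-matched, plus one point for every admixture component that agrees
within a tolerance (1% by default).  For the canonical nine-component
ancestry model the maximum score is 10.

Two matchers are provided:

``pam_simple``
    A single greedy sweep over the GD matrix in row order: each still-active
    row is paired with its minimum-GD active column (ties broken toward the
    lowest column index).  With a score threshold, a row whose best candidate
    scores below the threshold forms no pair; it remains claimable as the
    minimum-GD column of a later row and is reported unpaired if never
    claimed at an acceptable score.

``pam_full``
    An iterative extension: the cohort is re-sorted ascending by each
    admixture component in turn and the greedy sweep is re-run from several
    random start rows per sort; the candidate solution with the strictly
    lowest total GD wins.  Individuals left unpaired by one sweep re-enter
    the search on the next.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AdmixPairError",
    "DimensionMismatchError",
    "CohortTooSmallError",
    "Individual",
    "Cohort",
    "MatchConfig",
    "Pair",
    "PairingSolution",
    "genetic_distance",
    "pair_score",
    "build_gd_matrix",
    "build_score_matrix",
    "pam_simple",
    "pam_full",
]

#: tolerance on the sum of admixture proportions
_SUM_TOL = 1e-6

#: guard so the inclusive component tolerance survives binary float
#: representation (e.g. 0.51 - 0.50 exceeds 0.01 by ~9e-18)
_EPS = 1e-12


class AdmixPairError(Exception):
    """Base class for all domain errors raised by this package."""


class DimensionMismatchError(AdmixPairError, ValueError):
    """Two individuals (or files) disagree on the number of components K."""


class CohortTooSmallError(AdmixPairError, ValueError):
    """A pairing operation needs at least two individuals."""


@dataclass(frozen=True)
class Individual:
    """One cohort member: an ID, optional demographics and K admixture proportions.

    Parameters
    ----------
    id
        Unique sample identifier.
    admixture
        Vector of K >= 2 ancestry proportions in [0, 1] summing to 1
        (within 1e-6).
    age
        Age in years, or None if unknown.
    gender
        Two-level categorical (any hashable, e.g. PLINK's 1/2 coding), or
        None if unknown.
    """

    id: str
    admixture: np.ndarray
    age: float | None = None
    gender: object | None = None

    def __post_init__(self) -> None:
        vec = np.asarray(self.admixture, dtype=float)
        if vec.ndim != 1 or vec.size < 2:
            raise ValueError(f"{self.id}: admixture must be a vector with K >= 2")
        if np.any(vec < -_SUM_TOL) or np.any(vec > 1 + _SUM_TOL):
            raise ValueError(f"{self.id}: admixture proportions must lie in [0, 1]")
        if abs(float(vec.sum()) - 1.0) > _SUM_TOL:
            raise ValueError(
                f"{self.id}: admixture proportions sum to {vec.sum():.8f}, not 1"
            )
        if self.age is not None and self.age < 0:
            raise ValueError(f"{self.id}: age must be non-negative")
        vec = np.clip(vec, 0.0, 1.0)
        vec.flags.writeable = False
        object.__setattr__(self, "admixture", vec)

    @property
    def K(self) -> int:
        return int(self.admixture.size)


@dataclass
class Cohort:
    """An ordered collection of individuals sharing a component count K.

    Row order is meaningful: it is the row order of the Q file, and the
    greedy matcher sweeps rows in this order.
    """

    individuals: list[Individual]

    def __post_init__(self) -> None:
        if not self.individuals:
            raise ValueError("cohort must contain at least one individual")
        ks = {ind.K for ind in self.individuals}
        if len(ks) != 1:
            raise DimensionMismatchError(f"mixed component counts in cohort: {sorted(ks)}")
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual IDs in cohort")

    @classmethod
    def from_arrays(
        cls,
        admixture: np.ndarray,
        ids: Sequence[str] | None = None,
        ages: Sequence[float | None] | None = None,
        genders: Sequence[object | None] | None = None,
    ) -> "Cohort":
        """Build a cohort from an n x K proportion matrix plus optional metadata."""
        q = np.asarray(admixture, dtype=float)
        if q.ndim != 2:
            raise ValueError("admixture must be an n x K matrix")
        n = q.shape[0]
        if ids is None:
            ids = [f"I{i + 1:06d}" for i in range(n)]
        if len(ids) != n:
            raise ValueError(f"{len(ids)} ids for {n} admixture rows")
        ages = [None] * n if ages is None else list(ages)
        genders = [None] * n if genders is None else list(genders)
        return cls(
            [
                Individual(str(ids[i]), q[i], age=ages[i], gender=genders[i])
                for i in range(n)
            ]
        )

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def K(self) -> int:
        return self.individuals[0].K

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def admixture_matrix(self) -> np.ndarray:
        return np.vstack([ind.admixture for ind in self.individuals])

    def ages(self) -> np.ndarray:
        """Ages as a float vector with NaN for unknown."""
        return np.array(
            [np.nan if ind.age is None else float(ind.age) for ind in self.individuals]
        )

    def gender_codes(self) -> np.ndarray:
        """Genders factorized to integer codes; -1 marks unknown."""
        levels: dict[object, int] = {}
        codes = np.empty(self.n, dtype=int)
        for i, ind in enumerate(self.individuals):
            if ind.gender is None:
                codes[i] = -1
            else:
                codes[i] = levels.setdefault(ind.gender, len(levels))
        return codes

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __getitem__(self, i: int) -> Individual:
        return self.individuals[i]


@dataclass
class MatchConfig:
    """Tunable matching parameters.

    Parameters
    ----------
    threshold
        Minimum acceptable match score, or None for no filtering.  A
        candidate pair scoring below the threshold is not formed; an
        individual none of whose candidates reach the threshold ends up
        unpaired.
    age_window
        Maximum age difference (years, inclusive) for the demographic point.
    component_tolerance
        Maximum per-component difference (inclusive) for a component point.
    full_mode_starts
        Number of random start rows per sort pass in ``pam_full``.
    seed
        Seed for the random starts of ``pam_full``.
    """

    threshold: int | None = None
    age_window: float = 5.0
    component_tolerance: float = 0.01
    full_mode_starts: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.threshold is not None and not 0 <= self.threshold <= 10:
            raise ValueError("threshold must lie in [0, 10]")
        if self.age_window < 0:
            raise ValueError("age_window must be >= 0")
        if not 0 <= self.component_tolerance <= 1:
            raise ValueError("component_tolerance must lie in [0, 1]")
        if self.full_mode_starts < 1:
            raise ValueError("full_mode_starts must be >= 1")


class Pair(NamedTuple):
    id_a: str
    id_b: str
    gd: float
    score: int


@dataclass
class PairingSolution:
    """A matching: accepted pairs, unpaired individuals and their totals.

    Every cohort ID appears exactly once across pairs and the unpaired list.
    """

    pairs: list[Pair]
    unpaired: list[str]
    total_gd: float = field(init=False)
    total_score: int = field(init=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.pairs:
            for pid in (p.id_a, p.id_b):
                if pid in seen:
                    raise ValueError(f"{pid} appears more than once in the solution")
                seen.add(pid)
        for pid in self.unpaired:
            if pid in seen:
                raise ValueError(f"{pid} appears both paired and unpaired")
            seen.add(pid)
        self.total_gd = float(sum(p.gd for p in self.pairs))
        self.total_score = int(sum(p.score for p in self.pairs))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def ids(self) -> set[str]:
        """All IDs covered by the solution (paired or unpaired)."""
        out = set(self.unpaired)
        for p in self.pairs:
            out.add(p.id_a)
            out.add(p.id_b)
        return out

    def partner_of(self) -> dict[str, str | None]:
        """Map each covered ID to its assigned partner (None if unpaired)."""
        out: dict[str, str | None] = {u: None for u in self.unpaired}
        for p in self.pairs:
            out[p.id_a] = p.id_b
            out[p.id_b] = p.id_a
        return out


def genetic_distance(a: Individual, b: Individual) -> float:
    """Squared-difference genetic distance between two admixture vectors.

    GD(a, b) = sum_k (a_k - b_k)^2.  Symmetric, zero iff the vectors are
    identical, and at most 2 (two disjoint unit vectors).
    """
    if a.K != b.K:
        raise DimensionMismatchError(f"K mismatch: {a.K} vs {b.K}")
    d = a.admixture - b.admixture
    return float(d @ d)


def pair_score(a: Individual, b: Individual, cfg: MatchConfig | None = None) -> int:
    """Integer match score: demographic point + per-component points.

    The demographic point requires BOTH |age_a - age_b| <= age_window and
    equal gender; if age or gender is missing on either individual the point
    is not awarded.  Each admixture component k with
    |a_k - b_k| <= component_tolerance adds one point, so the maximum is
    K + 1 (10 in the nine-component model).
    """
    cfg = cfg or MatchConfig()
    if a.K != b.K:
        raise DimensionMismatchError(f"K mismatch: {a.K} vs {b.K}")
    demo = 0
    if (
        a.age is not None
        and b.age is not None
        and a.gender is not None
        and b.gender is not None
        and abs(a.age - b.age) <= cfg.age_window
        and a.gender == b.gender
    ):
        demo = 1
    comp = int(
        np.sum(np.abs(a.admixture - b.admixture) <= cfg.component_tolerance + _EPS)
    )
    return demo + comp


def build_gd_matrix(cohort: Cohort) -> np.ndarray:
    """n x n matrix of pairwise genetic distances (symmetric, zero diagonal)."""
    if cohort.n < 2:
        raise CohortTooSmallError("need at least 2 individuals to build a GD matrix")
    q = cohort.admixture_matrix()
    gd = cdist(q, q, metric="sqeuclidean")
    gd = 0.5 * (gd + gd.T)  # exact symmetry despite float summation order
    np.fill_diagonal(gd, 0.0)
    return gd


def build_score_matrix(cohort: Cohort, cfg: MatchConfig | None = None) -> np.ndarray:
    """n x n integer matrix of pairwise match scores."""
    cfg = cfg or MatchConfig()
    if cohort.n < 2:
        raise CohortTooSmallError("need at least 2 individuals to build a score matrix")
    q = cohort.admixture_matrix()
    n, k = q.shape
    comp = np.zeros((n, n), dtype=int)
    for c in range(k):  # loop over K keeps peak memory at O(n^2), not O(n^2 K)
        col = q[:, c]
        comp += np.abs(col[:, None] - col[None, :]) <= cfg.component_tolerance + _EPS
    ages = cohort.ages()
    with np.errstate(invalid="ignore"):
        age_ok = np.abs(ages[:, None] - ages[None, :]) <= cfg.age_window
    codes = cohort.gender_codes()
    gender_ok = (codes[:, None] == codes[None, :]) & (codes[:, None] >= 0)
    return comp + (age_ok & gender_ok).astype(int)


def _greedy_sweep(
    gd: np.ndarray,
    score: np.ndarray,
    start: int,
    threshold: int | None,
) -> tuple[list[tuple[int, int]], list[int]]:
    """One greedy minimum-GD sweep over matrix rows, cyclically from `start`.

    Returns (pairs, unpaired) as matrix indices.  A row whose minimum-GD
    candidate scores below the threshold forms no pair but stays claimable
    as a column; whatever is still active after the sweep is unpaired.
    """
    n = gd.shape[0]
    active = np.ones(n, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for step in range(n):
        i = (start + step) % n
        if not active[i]:
            continue
        row = np.where(active, gd[i], np.inf)
        row[i] = np.inf
        j = int(np.argmin(row))  # ties resolve to the lowest column index
        if not np.isfinite(row[j]):
            continue  # i is the last one standing; collected below
        if threshold is not None and score[i, j] < threshold:
            # reject the candidate but keep i in the matrix: it may still be
            # claimed as the minimum-GD column of a later row with an
            # acceptable score; if nobody claims it, it ends up unpaired.
            # Removing i here instead lets its (rejected) nearest neighbour
            # drift to a genetically close stranger and accept it, which is
            # exactly the misassignment the threshold exists to prevent.
            continue
        active[i] = False
        active[j] = False
        pairs.append((i, j))
    unpaired = [int(x) for x in np.flatnonzero(active)]
    return pairs, unpaired


def _assemble(
    cohort: Cohort,
    gd: np.ndarray,
    score: np.ndarray,
    pairs_idx: list[tuple[int, int]],
    unpaired_idx: list[int],
) -> PairingSolution:
    ids = cohort.ids
    pairs = [
        Pair(ids[i], ids[j], float(gd[i, j]), int(score[i, j])) for i, j in pairs_idx
    ]
    return PairingSolution(pairs=pairs, unpaired=[ids[i] for i in unpaired_idx])


def pam_simple(cohort: Cohort, cfg: MatchConfig | None = None) -> PairingSolution:
    """Single greedy sweep: pair each row with its minimum-GD remaining column.

    Rows are visited in cohort order starting from row 0.  Without a
    threshold an even cohort is fully paired; an odd cohort leaves exactly
    one individual unpaired.
    """
    cfg = cfg or MatchConfig()
    if cohort.n < 2:
        raise CohortTooSmallError("pairing needs at least 2 individuals")
    gd = build_gd_matrix(cohort)
    score = build_score_matrix(cohort, cfg)
    pairs_idx, unpaired_idx = _greedy_sweep(gd, score, start=0, threshold=cfg.threshold)
    return _assemble(cohort, gd, score, pairs_idx, unpaired_idx)


def pam_full(
    cohort: Cohort,
    cfg: MatchConfig | None = None,
    return_trace: bool = False,
) -> PairingSolution | tuple[PairingSolution, list[float]]:
    """Iterative greedy search over component-sorted orderings and random starts.

    For each admixture component in turn, the cohort is sorted ascending by
    that component and the greedy sweep is run from ``cfg.full_mode_starts``
    random start rows.  The candidate with the strictly smallest total GD
    becomes the incumbent; on ties the earlier incumbent is kept.  Every
    sweep considers the full cohort, so individuals discarded by one sweep
    re-enter the next.

    With ``return_trace=True`` also returns the list of candidate total GDs
    in the order they were examined (the result never exceeds any of them).
    """
    cfg = cfg or MatchConfig()
    if cohort.n < 2:
        raise CohortTooSmallError("pairing needs at least 2 individuals")
    rng = np.random.default_rng(cfg.seed)
    gd = build_gd_matrix(cohort)
    score = build_score_matrix(cohort, cfg)
    q = cohort.admixture_matrix()
    n = cohort.n
    best: PairingSolution | None = None
    trace: list[float] = []
    for c in range(cohort.K):
        order = np.argsort(q[:, c], kind="stable")
        gd_s = gd[np.ix_(order, order)]
        score_s = score[np.ix_(order, order)]
        for _ in range(cfg.full_mode_starts):
            start = int(rng.integers(n))
            p_idx, u_idx = _greedy_sweep(gd_s, score_s, start, cfg.threshold)
            sol = _assemble(
                cohort,
                gd,
                score,
                [(int(order[i]), int(order[j])) for i, j in p_idx],
                [int(order[i]) for i in u_idx],
            )
            trace.append(sol.total_gd)
            if best is None or sol.total_gd < best.total_gd:
                best = sol
    assert best is not None
    return (best, trace) if return_trace else best
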