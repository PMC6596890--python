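"""Comparator pairing strategies.

These are the strawmen the distance matcher is judged against: uniformly
random assignment within demographic constraints, three self-reported-race
models of increasing resolution, and random pairing within k-means clusters
of a 2-D PCA projection.

The race label is inferred from the nine-component ancestry model by fixed
rules applied in order (first match wins): 'African' when Sub-Saharan
Africa + South Africa exceeds 50%, 'Asian' when North East Asia exceeds
10%, 'Latino' when Native America exceeds 50%, otherwise 'White'.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import (
    Cohort,
    Individual,
    MatchConfig,
    Pair,
    PairingSolution,
    genetic_distance,
    pair_score,
    pam_simple,
)

__all__ = [
    "COMPONENT_ROLES",
    "infer_race",
    "macro_ancestry",
    "race_match",
    "random_match",
    "pca_kmeans_match",
]

#: role -> column index in the canonical nine-component ancestry model
#: (North East Asia, Mediterranean, South Africa, South West Asia,
#: Native America, Oceania, South East Asia, Northern Europe,
#: Sub-Saharan Africa).
COMPONENT_ROLES: dict[str, int] = {
    "north_east_asia": 0,
    "mediterranean": 1,
    "south_africa": 2,
    "south_west_asia": 3,
    "native_america": 4,
    "oceania": 5,
    "south_east_asia": 6,
    "northern_europe": 7,
    "sub_saharan_africa": 8,
}

_REQUIRED_ROLES = (
    "sub_saharan_africa",
    "south_africa",
    "north_east_asia",
    "south_east_asia",
    "native_america",
)


def _check_roles(ind_or_k, roles: Mapping[str, int]) -> None:
    k = ind_or_k if isinstance(ind_or_k, int) else ind_or_k.K
    missing = [r for r in _REQUIRED_ROLES if r not in roles]
    if missing:
        raise ValueError(f"component-role mapping lacks roles: {missing}")
    if any(roles[r] >= k for r in _REQUIRED_ROLES):
        raise ValueError("component-role mapping indexes past K components")


def infer_race(ind: Individual, roles: Mapping[str, int] | None = None) -> str:
    """Self-reported-race surrogate inferred from admixture components.

    Rules are applied in order, first match wins: African (Sub-Saharan
    Africa + South Africa > 50%), Asian (North East Asia > 10%), Latino
    (Native America > 50%), else White.
    """
    roles = COMPONENT_ROLES if roles is None else roles
    _check_roles(ind, roles)
    a = ind.admixture
    if a[roles["sub_saharan_africa"]] + a[roles["south_africa"]] > 0.50:
        return "African"
    if a[roles["north_east_asia"]] > 0.10:
        return "Asian"
    if a[roles["native_america"]] > 0.50:
        return "Latino"
    return "White"


def macro_ancestry(
    ind: Individual, roles: Mapping[str, int] | None = None
) -> np.ndarray:
    """Collapse the K components to 4 macro-ancestry fractions.

    African = Sub-Saharan Africa + South Africa, Asian = North East Asia +
    South East Asia, Latino = Native America, White = the remainder; the
    four fractions sum to 1.
    """
    roles = COMPONENT_ROLES if roles is None else roles
    _check_roles(ind, roles)
    a = ind.admixture
    african = a[roles["sub_saharan_africa"]] + a[roles["south_africa"]]
    asian = a[roles["north_east_asia"]] + a[roles["south_east_asia"]]
    latino = a[roles["native_america"]]
    white = max(0.0, 1.0 - african - asian - latino)
    v = np.array([african, asian, latino, white])
    return v / v.sum()


def _constrained_random_match(
    cohort: Cohort,
    labels: Sequence[object] | None,
    cfg: MatchConfig,
    rng: np.random.Generator,
) -> PairingSolution:
    """Uniform random pairing subject to gender/age-window (and label) equality."""
    n = cohort.n
    order = rng.permutation(n)
    active = np.ones(n, dtype=bool)
    pairs: list[Pair] = []
    unpaired: list[int] = []
    inds = cohort.individuals
    for i in order:
        if not active[i]:
            continue
        a = inds[i]
        compatible = [
            j
            for j in np.flatnonzero(active)
            if j != i
            and a.age is not None
            and inds[j].age is not None
            and a.gender is not None
            and inds[j].gender is not None
            and abs(a.age - inds[j].age) <= cfg.age_window
            and a.gender == inds[j].gender
            and (labels is None or labels[i] == labels[j])
        ]
        active[i] = False
        if not compatible:
            unpaired.append(int(i))
            continue
        j = int(rng.choice(compatible))
        active[j] = False
        b = inds[j]
        pairs.append(
            Pair(a.id, b.id, genetic_distance(a, b), pair_score(a, b, cfg))
        )
    ids = cohort.ids
    return PairingSolution(pairs=pairs, unpaired=[ids[i] for i in unpaired])


def random_match(
    cohort: Cohort, cfg: MatchConfig | None = None, seed: int | None = None
) -> PairingSolution:
    """Random assignment: age/gender must match but ancestry is ignored."""
    cfg = cfg or MatchConfig()
    rng = np.random.default_rng(seed)
    return _constrained_random_match(cohort, None, cfg, rng)


def race_match(
    cohort: Cohort,
    model: int,
    cfg: MatchConfig | None = None,
    seed: int | None = None,
    roles: Mapping[str, int] | None = None,
) -> PairingSolution:
    """Pairing by self-reported-race surrogate, three models.

    Model 1 pairs randomly within (age window, gender, 4-way race) strata;
    model 2 collapses the label to African / non-African; model 3 runs the
    greedy minimum-distance matcher on the 4-vector of macro-ancestry
    fractions (no score threshold on the collapsed scale).  Reported GD and
    score are always computed on the full K-component vectors.
    """
    cfg = cfg or MatchConfig()
    if model not in (1, 2, 3):
        raise ValueError(f"unknown race model {model!r}; expected 1, 2 or 3")
    rng = np.random.default_rng(seed)
    if model in (1, 2):
        labels = [infer_race(ind, roles) for ind in cohort]
        if model == 2:
            labels = ["African" if lab == "African" else "non-African" for lab in labels]
        return _constrained_random_match(cohort, labels, cfg, rng)
    # model 3: distance matching on the collapsed macro-ancestry vectors
    collapsed = Cohort(
        [
            Individual(ind.id, macro_ancestry(ind, roles), age=ind.age, gender=ind.gender)
            for ind in cohort
        ]
    )
    sub_cfg = MatchConfig(
        threshold=None,
        age_window=cfg.age_window,
        component_tolerance=cfg.component_tolerance,
    )
    sol4 = pam_simple(collapsed, sub_cfg)
    by_id = {ind.id: ind for ind in cohort}
    pairs = [
        Pair(
            p.id_a,
            p.id_b,
            genetic_distance(by_id[p.id_a], by_id[p.id_b]),
            pair_score(by_id[p.id_a], by_id[p.id_b], cfg),
        )
        for p in sol4.pairs
    ]
    return PairingSolution(pairs=pairs, unpaired=list(sol4.unpaired))


def pca_kmeans_match(
    features: np.ndarray,
    n_clusters: int,
    seed: int | None = None,
    cohort: Cohort | None = None,
    cfg: MatchConfig | None = None,
) -> PairingSolution:
    """Random pairing within k-means clusters of the top-2 PCA projection.

    ``features`` is any numeric per-individual matrix (admixture vectors in
    the shipped pipeline, or externally computed genotype PCs).  When a
    ``cohort`` is supplied its IDs are used and per-pair GD/score are
    computed on the admixture vectors; otherwise rows are keyed by index
    and GD is the squared Euclidean distance on the features (score 0).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("features must be an n x d matrix with n >= 2, d >= 2")
    n = x.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters={n_clusters} outside [1, {n}]")
    if cohort is not None and cohort.n != n:
        raise ValueError("cohort size does not match feature rows")
    cfg = cfg or MatchConfig()
    rng = np.random.default_rng(seed)
    proj = PCA(n_components=2, random_state=int(rng.integers(2**31 - 1))).fit_transform(x)
    km = KMeans(
        n_clusters=n_clusters, n_init=10, random_state=int(rng.integers(2**31 - 1))
    ).fit(proj)
    pairs: list[Pair] = []
    unpaired: list[int] = []
    for c in range(n_clusters):
        members = np.flatnonzero(km.labels_ == c)
        members = members[rng.permutation(members.size)]
        for a, b in zip(members[0::2], members[1::2]):
            i, j = int(a), int(b)
            if cohort is not None:
                ia, ib = cohort[i], cohort[j]
                pairs.append(
                    Pair(ia.id, ib.id, genetic_distance(ia, ib), pair_score(ia, ib, cfg))
                )
            else:
                d = x[i] - x[j]
                pairs.append(Pair(str(i), str(j), float(d @ d), 0))
        if members.size % 2:
            unpaired.append(int(members[-1]))
    ids = cohort.ids if cohort is not None else [str(i) for i in range(n)]
    return PairingSolution(pairs=pairs, unpaired=[ids[i] for i in unpaired])
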