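"""Scoring pairing solutions against ground truth, plus geographic metrics."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import AdmixPairError, PairingSolution

__all__ = [
    "EvaluationReport",
    "evaluate_solution",
    "haversine_km",
    "mean_pair_distance_km",
    "pair_label_concordance",
    "write_evaluation_tsv",
]

EARTH_RADIUS_KM = 6371.0


class TruthMismatchError(AdmixPairError, ValueError):
    """The solution contains an ID the truth map does not cover."""


@dataclass
class EvaluationReport:
    """Accuracy of a pairing solution against a known pair map.

    ``n_misassigned`` counts paired *individuals* whose assigned partner
    differs from their true one (both members of a wrong pair count).  An
    individual left unpaired is never misassigned — in particular one whose
    true partner was removed from the cohort is correctly unpaired.
    ``pct_recovered`` is the fraction of recoverable truth pairs (both
    members present) that were returned intact, in [0, 1].
    """

    n_misassigned: int
    n_correct_pairs: int
    n_unpaired: int
    total_gd: float
    total_score: int
    pct_recovered: float


def evaluate_solution(
    sol: PairingSolution, truth: Mapping[str, str | None]
) -> EvaluationReport:
    """Compare a solution with the ground-truth partner map.

    ``truth`` must cover every ID in the solution; values are the true
    partner's ID or None for individuals whose partner is absent.
    """
    missing = sol.ids() - set(truth)
    if missing:
        raise TruthMismatchError(
            f"solution IDs absent from truth map: {sorted(missing)[:5]}"
        )
    correct = sum(1 for p in sol.pairs if truth[p.id_a] == p.id_b)
    misassigned = 2 * (len(sol.pairs) - correct)
    present = sol.ids()
    recoverable = (
        sum(1 for i in present if truth[i] is not None and truth[i] in present) // 2
    )
    return EvaluationReport(
        n_misassigned=misassigned,
        n_correct_pairs=correct,
        n_unpaired=len(sol.unpaired),
        total_gd=sol.total_gd,
        total_score=sol.total_score,
        pct_recovered=correct / recoverable if recoverable else 0.0,
    )


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude {lon} outside [-180, 180]")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def mean_pair_distance_km(
    sol: PairingSolution, coords: Mapping[str, tuple[float, float]]
) -> float:
    """Mean within-pair great-circle distance, a geographic homogeneity metric.

    ``coords`` maps IDs to (latitude, longitude) in degrees.  Returns NaN
    for a solution with no pairs.
    """
    if not sol.pairs:
        return math.nan
    dists = [
        haversine_km(*coords[p.id_a], *coords[p.id_b]) for p in sol.pairs
    ]
    return sum(dists) / len(dists)


def pair_label_concordance(
    sol: PairingSolution, labels: Mapping[str, object]
) -> tuple[int, int]:
    """(n_same, n_different) split of pairs by an external label.

    Labels (e.g. externally computed genotype-similarity cluster
    memberships) are supplied per ID; pairs whose members share a label
    count as concordant.
    """
    same = sum(1 for p in sol.pairs if labels[p.id_a] == labels[p.id_b])
    return same, len(sol.pairs) - same


def write_evaluation_tsv(
    rows: Sequence[tuple[str, str, int | None, EvaluationReport]], path
) -> None:
    """Write evaluation reports as a TSV: one row per (dataset, method) run."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "dataset\tmethod\tthreshold\tn_misassigned\ttotal_gd\t"
            "total_score\tn_unpaired\n"
        )
        for dataset, method, threshold, rep in rows:
            thr = "" if threshold is None else str(threshold)
            fh.write(
                f"{dataset}\t{method}\t{thr}\t{rep.n_misassigned}\t"
                f"{rep.total_gd:.6g}\t{rep.total_score}\t{rep.n_unpaired}\n"
            )
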