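"""Text-format readers and writers.

Formats handled:

* ADMIXTURE Q files — headerless whitespace-delimited n x K proportion
  matrices, one row per individual.
* fam-style demographic files — whitespace-delimited, one row per Q row in
  the same order.  The dialect used here takes the individual ID from
  column 2, age from column 4 and gender from column 6 (1-based); pass
  ``plink_standard=True`` for stock PLINK .fam files, which carry sex in
  column 5 and no age.
* truth maps, solutions and coordinates as TSV with a header line.

All files are UTF-8 with LF line endings.  Q rows whose sum is within 1e-3
of 1 are renormalized; rows further off are rejected.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import AdmixPairError, Cohort, Pair, PairingSolution

__all__ = [
    "FileFormatError",
    "read_q",
    "write_q",
    "read_fam",
    "write_fam",
    "load_cohort",
    "read_truth",
    "write_truth",
    "write_dataset",
    "write_solution",
    "read_solution",
    "read_coords",
]

_ROW_SUM_TOL = 1e-3
_MISSING_AGE_CODES = {"-9", "NA", "na", ".", ""}


class FileFormatError(AdmixPairError, ValueError):
    """A file does not conform to its expected text format."""


def read_q(path) -> np.ndarray:
    """Read an ADMIXTURE Q file into an n x K matrix with rows summing to 1."""
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: non-numeric field") from exc
            if not all(math.isfinite(v) for v in rows[-1]):
                raise FileFormatError(f"{path}:{lineno}: non-finite value")
    if not rows:
        raise FileFormatError(f"{path}: empty Q file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FileFormatError(f"{path}: ragged rows (column counts {sorted(widths)})")
    q = np.array(rows, dtype=float)
    sums = q.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > _ROW_SUM_TOL)
    if bad.size:
        raise FileFormatError(
            f"{path}: row {bad[0] + 1} sums to {sums[bad[0]]:.6f}, not 1"
        )
    return q / sums[:, None]


def write_q(q: np.ndarray, path) -> None:
    """Write a proportion matrix as a headerless space-delimited Q file."""
    q = np.asarray(q, dtype=float)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for row in q:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def _parse_age(token: str) -> float | None:
    if token in _MISSING_AGE_CODES:
        return None
    try:
        age = float(token)
    except ValueError:
        return None
    return age if age > 0 else None


def _parse_gender(token: str) -> int | None:
    return int(token) if token in {"1", "2"} else None


def read_fam(
    path,
    age_col: int = 4,
    gender_col: int = 6,
    plink_standard: bool = False,
) -> list[tuple[str, float | None, int | None]]:
    """Read a fam-style file into (id, age, gender) records in file order.

    Columns are 1-based; the individual ID is column 2.  With
    ``plink_standard=True`` gender is read from column 5 (PLINK sex) and no
    age is read.  Age codes <= 0 or -9 and genders outside {1, 2} map to
    None (missing).
    """
    if plink_standard:
        age_col, gender_col = 0, 5
    records: list[tuple[str, float | None, int | None]] = []
    need = max(2, age_col, gender_col)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < need:
                raise FileFormatError(
                    f"{path}:{lineno}: {len(fields)} columns, need >= {need}"
                )
            iid = fields[1]
            age = _parse_age(fields[age_col - 1]) if age_col else None
            gender = _parse_gender(fields[gender_col - 1]) if gender_col else None
            records.append((iid, age, gender))
    if not records:
        raise FileFormatError(f"{path}: empty fam file")
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        raise FileFormatError(f"{path}: duplicate individual IDs")
    return records


def write_fam(cohort: Cohort, path) -> None:
    """Write cohort demographics in the fam dialect read by :func:`read_fam`.

    Columns: family ID (= individual ID), individual ID, 0, age, 0, gender;
    missing age/gender are encoded as -9 and 0.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for ind in cohort:
            age = "-9" if ind.age is None else f"{ind.age:g}"
            gender = "0" if ind.gender is None else str(ind.gender)
            fh.write(f"{ind.id} {ind.id} 0 {age} 0 {gender}\n")


def load_cohort(
    q_path,
    fam_path=None,
    age_col: int = 4,
    gender_col: int = 6,
    plink_standard: bool = False,
) -> Cohort:
    """Assemble a cohort from a Q file and an optional fam-style file.

    Rows are keyed by file order; the fam file must have exactly one record
    per Q row.  Without a fam file individuals get sequential IDs and no
    demographics.
    """
    q = read_q(q_path)
    if fam_path is None:
        return Cohort.from_arrays(q)
    records = read_fam(
        fam_path, age_col=age_col, gender_col=gender_col, plink_standard=plink_standard
    )
    if len(records) != q.shape[0]:
        raise FileFormatError(
            f"{fam_path}: {len(records)} records for {q.shape[0]} Q rows"
        )
    ids, ages, genders = zip(*records)
    return Cohort.from_arrays(q, ids=ids, ages=ages, genders=genders)


def write_truth(truth: Mapping[str, str | None], path) -> None:
    """Write a ground-truth partner map as a two-column TSV (id_a, id_b).

    Each pair is written once (lexicographically smaller ID first);
    partnerless individuals get NA in the second column.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id_a\tid_b\n")
        for iid in truth:
            partner = truth[iid]
            if partner is None:
                fh.write(f"{iid}\tNA\n")
            elif iid < partner:
                fh.write(f"{iid}\t{partner}\n")


def read_truth(path) -> dict[str, str | None]:
    """Read a truth TSV back into a symmetric id -> partner map."""
    truth: dict[str, str | None] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("id_a"):
            raise FileFormatError(f"{path}: missing truth header")
        for lineno, line in enumerate(fh, start=2):
            fields = line.split("\t")
            if len(fields) != 2:
                if line.strip():
                    raise FileFormatError(f"{path}:{lineno}: expected 2 columns")
                continue
            a, b = fields[0].strip(), fields[1].strip()
            if b == "NA":
                truth[a] = None
            else:
                truth[a] = b
                truth[b] = a
    return truth


def write_dataset(ds, prefix) -> dict[str, Path]:
    """Write a simulated dataset as <prefix>.Q, <prefix>.fam, <prefix>.truth.tsv."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "q": prefix.with_suffix(".Q"),
        "fam": prefix.with_suffix(".fam"),
        "truth": Path(str(prefix) + ".truth.tsv"),
    }
    write_q(ds.cohort.admixture_matrix(), paths["q"])
    write_fam(ds.cohort, paths["fam"])
    write_truth(ds.truth, paths["truth"])
    return paths


def write_solution(sol: PairingSolution, prefix) -> dict[str, Path]:
    """Write <prefix>.paired.tsv (id_a, id_b, gd, score) and <prefix>.unpaired.tsv."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paired = Path(str(prefix) + ".paired.tsv")
    unpaired = Path(str(prefix) + ".unpaired.tsv")
    with open(paired, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id_a\tid_b\tgd\tscore\n")
        for p in sol.pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{p.gd:.6g}\t{p.score}\n")
    with open(unpaired, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\n")
        for iid in sol.unpaired:
            fh.write(f"{iid}\n")
    return {"paired": paired, "unpaired": unpaired}


def read_solution(prefix) -> PairingSolution:
    """Read a solution written by :func:`write_solution`."""
    prefix = Path(prefix)
    pairs: list[Pair] = []
    unpaired: list[str] = []
    paired_path = Path(str(prefix) + ".paired.tsv")
    with open(paired_path, encoding="utf-8") as fh:
        if not fh.readline().startswith("id_a"):
            raise FileFormatError(f"{paired_path}: missing header")
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise FileFormatError(f"{paired_path}: expected 4 columns")
            pairs.append(Pair(fields[0], fields[1], float(fields[2]), int(fields[3])))
    with open(Path(str(prefix) + ".unpaired.tsv"), encoding="utf-8") as fh:
        fh.readline()
        unpaired = [line.strip() for line in fh if line.strip()]
    return PairingSolution(pairs=pairs, unpaired=unpaired)


def read_coords(path) -> dict[str, tuple[float, float]]:
    """Read a TSV of id, latitude, longitude (header required) for geo metrics."""
    coords: dict[str, tuple[float, float]] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise FileFormatError(f"{path}:{lineno}: expected 3 columns")
            coords[fields[0]] = (float(fields[1]), float(fields[2]))
    return coords
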