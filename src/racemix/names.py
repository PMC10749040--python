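"""Natal-sex probability assignment from declared category, lookup labels and name frequencies.

Every athlete receives a probability of being natal male (``prob_male``).
Athletes registered as male or female are assigned 1 or 0 directly.  Athletes
registered as non-binary are resolved, in order of precedence, from an optional
partial lookup table of known natal sexes and otherwise from the relative
frequency of their given name among male and female births in the two calendar
years compatible with their registered age on race day.  Athletes for whom no
source yields information remain unassigned and are excluded downstream.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass
from datetime import date as _date
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GENDER_CATEGORIES",
    "NATAL_SEXES",
    "NameFrequencyTable",
    "SexAssignment",
    "assign_prob_male",
    "assign_probabilities",
    "candidate_birth_years",
    "cross_validate",
    "given_name",
    "normalize_name",
    "prob_male_from_name",
    "read_lookup",
    "widen_uncertainty",
    "write_lookup",
]

GENDER_CATEGORIES = ("male", "female", "non-binary")
NATAL_SEXES = ("male", "female")


def normalize_name(name: str) -> str:
    """Normalize a full name for identity comparison.

    Case-folds, strips accents (NFKD, combining marks removed) and collapses
    internal whitespace.  Two athletes whose normalized full names are equal
    are treated as the same person.
    """
    decomposed = unicodedata.normalize("NFKD", name)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return " ".join(stripped.casefold().split())


def given_name(name: str) -> str:
    """First whitespace-separated token of the normalized name."""
    tokens = normalize_name(name).split()
    return tokens[0] if tokens else ""


class NameFrequencyTable:
    """Birth counts by (given name, birth year, sex).

    Absent keys are distinguishable from explicit ``(0, 0)`` entries: ``get``
    returns ``None`` for the former.  Names are stored normalized (via
    :func:`given_name`); queries are normalized the same way.
    """

    def __init__(self, entries: Mapping[tuple[str, int], tuple[int, int]] | None = None):
        self._entries: dict[tuple[str, int], tuple[int, int]] = {}
        if entries:
            for (name, year), (m, f) in entries.items():
                self.add(name, int(year), int(m), int(f))

    def add(self, name: str, year: int, male: int, female: int) -> None:
        if male < 0 or female < 0:
            raise ValueError("birth counts must be nonnegative")
        key = (given_name(name), int(year))
        prev = self._entries.get(key, (0, 0))
        self._entries[key] = (prev[0] + int(male), prev[1] + int(female))

    def get(self, name: str, year: int) -> tuple[int, int] | None:
        return self._entries.get((given_name(name), int(year)))

    def male_share(self, name: str, year: int) -> float | None:
        entry = self.get(name, year)
        if entry is None or entry[0] + entry[1] == 0:
            return None
        return entry[0] / (entry[0] + entry[1])

    @property
    def years(self) -> list[int]:
        return sorted({y for (_, y) in self._entries})

    @property
    def names(self) -> list[str]:
        return sorted({n for (n, _) in self._entries})

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: tuple[str, int]) -> bool:
        name, year = key
        return (given_name(name), int(year)) in self._entries

    def items(self):
        return self._entries.items()

    @classmethod
    def from_ssa_dir(cls, path: str | Path) -> "NameFrequencyTable":
        """Read a directory of ``yobYYYY.txt`` files (lines ``Name,M|F,count``)."""
        path = Path(path)
        table = cls()
        files = sorted(path.glob("yob*.txt"))
        if not files:
            raise FileNotFoundError(f"no yob*.txt files under {path}")
        for f in files:
            year = int(f.stem[3:])
            with open(f, newline="") as fh:
                for row in csv.reader(fh):
                    if not row:
                        continue
                    name, sex, count = row[0], row[1].strip().upper(), int(row[2])
                    if sex == "M":
                        table.add(name, year, count, 0)
                    elif sex == "F":
                        table.add(name, year, 0, count)
                    else:
                        raise ValueError(f"unexpected sex code {sex!r} in {f}")
        return table

    def to_ssa_dir(self, path: str | Path) -> None:
        """Write one ``yobYYYY.txt`` file per year, lines ``Name,M|F,count``.

        Zero counts are written explicitly so that a (0, 0) entry round-trips
        as present-but-empty is NOT possible in the SSA layout; zero rows are
        skipped, matching the real files which only list names with births.
        """
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        by_year: dict[int, list[tuple[str, str, int]]] = {}
        for (name, year), (m, f) in sorted(self._entries.items()):
            rows = by_year.setdefault(year, [])
            if m > 0:
                rows.append((name.title(), "M", m))
            if f > 0:
                rows.append((name.title(), "F", f))
        for year, rows in by_year.items():
            with open(path / f"yob{year}.txt", "w", newline="") as fh:
                writer = csv.writer(fh)
                for row in rows:
                    writer.writerow(row)


def candidate_birth_years(age_years: int, race_date: _date | str) -> tuple[int, int]:
    """The two calendar years compatible with a registered age on race day.

    An athlete aged ``a`` on a race in year ``Y`` was born either in ``Y - a``
    (birthday already passed) or ``Y - a - 1`` (birthday still to come).
    """
    if age_years < 0:
        raise ValueError("age must be nonnegative")
    if isinstance(race_date, str):
        race_date = _date.fromisoformat(race_date)
    year = race_date.year
    return (year - age_years, year - age_years - 1)


def prob_male_from_name(
    name: str, years: Iterable[int], table: NameFrequencyTable
) -> float | None:
    """Proportion of male births with this given name, pooled over ``years``.

    Counts are summed over the candidate years before forming the proportion.
    Returns ``None`` (unassigned) when the name is absent in every year or the
    pooled total is zero — absence is a value, not an error.
    """
    male = 0
    female = 0
    for year in years:
        entry = table.get(name, year)
        if entry is not None:
            male += entry[0]
            female += entry[1]
    total = male + female
    if total == 0:
        return None
    return male / total


def widen_uncertainty(prob: float, epsilon: float) -> float:
    """Shrink a probability toward 0.5 by a factor ``1 - epsilon``.

    Models extra uncertainty (e.g. name changes) not captured by the birth
    frequencies: ``(1 - epsilon) * prob + epsilon / 2``.  ``epsilon = 0`` is
    the identity and 0.5 is a fixed point for every epsilon.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    if not 0.0 <= prob <= 1.0:
        raise ValueError("prob must be in [0, 1]")
    return (1.0 - epsilon) * prob + epsilon / 2.0


@dataclass(frozen=True)
class SexAssignment:
    """A per-athlete natal-sex probability with its provenance.

    ``prob_male`` is ``None`` exactly when ``source == "none"``; declared and
    lookup sources always yield a degenerate 0/1 probability.
    """

    prob_male: float | None
    source: str  # declared | lookup | name_model | none


def assign_prob_male(
    record: Mapping,
    lookup: Mapping[str, str] | None,
    table: NameFrequencyTable | None,
    epsilon: float = 0.0,
) -> SexAssignment:
    """Assign prob_male to one record with precedence declared > lookup > name model.

    ``record`` must expose ``gender_id``, ``name``, ``age`` and ``date``.  The
    uncertainty widening ``epsilon`` applies only to name-model probabilities;
    declared and lookup assignments stay exactly 0 or 1.
    """
    gender = record["gender_id"]
    if gender not in GENDER_CATEGORIES:
        raise ValueError(f"unknown gender_id {gender!r}")
    if gender == "male":
        return SexAssignment(1.0, "declared")
    if gender == "female":
        return SexAssignment(0.0, "declared")
    key = normalize_name(record["name"])
    if lookup is not None and key in lookup:
        label = lookup[key]
        if label not in NATAL_SEXES:
            raise ValueError(f"unknown natal sex label {label!r}")
        return SexAssignment(1.0 if label == "male" else 0.0, "lookup")
    if table is not None:
        years = candidate_birth_years(int(record["age"]), record["date"])
        prob = prob_male_from_name(record["name"], years, table)
        if prob is not None:
            return SexAssignment(widen_uncertainty(prob, epsilon), "name_model")
    return SexAssignment(None, "none")


def assign_probabilities(
    df: pd.DataFrame,
    lookup: Mapping[str, str] | None,
    table: NameFrequencyTable | None,
    epsilon: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign prob_male to every row of a result table.

    Returns a copy of ``df`` with ``prob_male`` and ``prob_source`` columns
    plus a summary of how the natal sex of non-binary athletes was resolved
    (lookup / name model / unassigned / total).
    """
    probs: list[float | None] = []
    sources: list[str] = []
    for _, row in df.iterrows():
        a = assign_prob_male(row, lookup, table, epsilon)
        probs.append(a.prob_male)
        sources.append(a.source)
    out = df.copy()
    out["prob_male"] = probs
    out["prob_source"] = sources
    nb = out["gender_id"] == "non-binary"
    summary = {
        "nb_lookup": int((nb & (out["prob_source"] == "lookup")).sum()),
        "nb_name_model": int((nb & (out["prob_source"] == "name_model")).sum()),
        "nb_unassigned": int((nb & (out["prob_source"] == "none")).sum()),
        "nb_total": int(nb.sum()),
    }
    return out, summary


def cross_validate(
    lookup: Mapping[str, str],
    table: NameFrequencyTable,
    records: pd.DataFrame,
    threshold: float = 0.05,
) -> tuple[int, int]:
    """Compare lookup labels against confident name-model predictions.

    Among unique athletes having both a lookup label and a name-model
    probability below ``threshold`` or above ``1 - threshold``, counts the
    comparisons and the agreements (probability > 0.5 side matches the label).
    """
    if not 0.0 < threshold < 0.5:
        raise ValueError("threshold must be in (0, 0.5)")
    n_compared = 0
    n_agree = 0
    seen: set[str] = set()
    for _, row in records.iterrows():
        key = normalize_name(row["name"])
        if key in seen or key not in lookup:
            continue
        seen.add(key)
        years = candidate_birth_years(int(row["age"]), row["date"])
        prob = prob_male_from_name(row["name"], years, table)
        if prob is None or threshold <= prob <= 1.0 - threshold:
            continue
        n_compared += 1
        predicted = "male" if prob > 0.5 else "female"
        if predicted == lookup[key]:
            n_agree += 1
    return n_compared, n_agree


def read_lookup(path: str | Path) -> dict[str, str]:
    """Read a partial natal-sex lookup CSV (``name,natal_sex``)."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            sex = row["natal_sex"].strip().lower()
            if sex not in NATAL_SEXES:
                raise ValueError(f"unknown natal sex {sex!r} in {path}")
            out[normalize_name(row["name"])] = sex
    return out


def write_lookup(lookup: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "natal_sex"])
        for name in sorted(lookup):
            writer.writerow([name, lookup[name]])
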