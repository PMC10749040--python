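"""Synthetic race results, name-frequency tables and partial sex lookups.

The generator mirrors the structure the downstream analysis assumes: log race
times are linear in event, natal sex, centred age and its square, and
non-binary status, with Gaussian residuals; athletes' given names are drawn
conditionally on natal sex from a year-specific frequency table; a partial
lookup resolves the natal sex of a tunable fraction of non-binary athletes.
Ground truth (including the unobserved natal sex) is retained so that recovery
tests can compare estimates against the generating coefficients.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from datetime import date as _date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .names import NameFrequencyTable

__all__ = [
    "SyntheticTruth",
    "default_event_log_means",
    "default_truth",
    "generate_athletes",
    "generate_lookup",
    "generate_name_table",
    "generate_race_results",
    "read_results_csv",
    "read_truth",
    "simulate_bundle",
    "write_results_csv",
    "write_truth",
]

MARATHON = "marathon"

# Age support for the athlete population (uniform integers, inclusive).
AGE_MIN, AGE_MAX = 18, 70


@dataclass
class SyntheticTruth:
    """Generating parameters: the ground truth a recovery test targets."""

    event_log_means: dict[str, float] = field(default_factory=lambda: default_event_log_means())
    beta_female: float = 0.12224
    beta_age: float = 0.00375
    beta_age2: float = 0.00012
    beta_nb: float = 0.03225
    beta_nbp: float = 0.0
    sigma: float = 0.20
    frac_nonbinary: float = 0.002
    n_athletes: int = 10_000
    seed: int = 0
    race_year: int = 2022

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.frac_nonbinary <= 1.0:
            raise ValueError("frac_nonbinary must be in [0, 1]")
        if self.n_athletes < 1:
            raise ValueError("n_athletes must be >= 1")
        if MARATHON not in self.event_log_means:
            raise ValueError("event_log_means must include the marathon")


def default_event_log_means(n_events: int = 21) -> dict[str, float]:
    """Event log-mean times spread from a short road race up to the marathon.

    21 events by default; log-means run from ~40 min (4-mile pace) up to the
    marathon mean of ~4.5 h, with the marathon holding the largest mean.
    """
    if n_events < 1:
        raise ValueError("need at least one event")
    lo, hi = math.log(2400.0), math.log(16200.0)
    grid = np.linspace(lo, hi, n_events)
    means = {f"race_{i:02d}": float(v) for i, v in enumerate(grid[:-1], start=1)}
    means[MARATHON] = float(grid[-1])
    return means


def default_truth(**overrides) -> SyntheticTruth:
    return SyntheticTruth(**overrides)


def generate_name_table(
    n_names: int,
    year_range: tuple[int, int],
    seed: int,
    ambiguous_frac: float = 0.2,
    absent_frac: float = 0.15,
    sex_exclusive: bool = False,
) -> NameFrequencyTable:
    """Generate a name-frequency table with sex-typed and ambiguous names.

    The table always contains strongly-male names (male share > 0.95),
    strongly-female names (share < 0.05) and, unless ``ambiguous_frac`` is
    zero, ambiguous names; a fraction of names is absent in some years.  With
    ``sex_exclusive`` the minority-sex count of sex-typed names is exactly
    zero, so an athlete's name can never point to the wrong sex.
    """
    lo, hi = int(year_range[0]), int(year_range[1])
    if hi < lo:
        raise ValueError("year_range must be nonempty")
    if n_names < 4:
        raise ValueError("need at least 4 names")
    if not 0.0 <= ambiguous_frac <= 1.0:
        raise ValueError("ambiguous_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    years = list(range(lo, hi + 1))

    n_ambig = int(round(ambiguous_frac * n_names))
    if ambiguous_frac > 0:
        n_ambig = max(1, min(n_ambig, n_names - 2))
    n_sexed = n_names - n_ambig
    n_male = max(1, n_sexed // 2)
    n_female = max(1, n_sexed - n_male)

    names: list[tuple[str, float]] = []  # (name, male share)
    for i in range(n_male):
        share = 1.0 if sex_exclusive else float(rng.uniform(0.965, 0.995))
        names.append((f"jon{i:03d}", share))
    for i in range(n_female):
        share = 0.0 if sex_exclusive else float(rng.uniform(0.005, 0.035))
        names.append((f"ann{i:03d}", share))
    for i in range(n_ambig):
        names.append((f"sam{i:03d}", float(rng.uniform(0.25, 0.75))))

    # The first male-typed and first female-typed name anchor every year so
    # that athlete name sampling never finds an empty year.
    always_present = {"jon000", "ann000"}
    n_absent = int(round(absent_frac * n_names))
    absentable = [n for n, _ in names if n not in always_present]
    absent_names = set(
        rng.choice(absentable, size=min(n_absent, len(absentable)), replace=False)
    ) if n_absent and absentable else set()

    table = NameFrequencyTable()
    for name, share in names:
        base = int(rng.integers(300, 5000))
        missing_years: set[int] = set()
        if name in absent_names and len(years) > 1:
            k = max(1, len(years) // 3)
            missing_years = set(rng.choice(years, size=k, replace=False))
        for year in years:
            if year in missing_years:
                continue
            total = max(2, int(rng.poisson(base)))
            male = int(round(total * share))
            if not sex_exclusive:
                # keep both sexes represented so shares stay strictly in (0,1)
                male = min(max(male, 1), total - 1)
            female = total - male
            table.add(name, year, male, female)
    return table


def generate_athletes(
    truth: SyntheticTruth,
    name_table: NameFrequencyTable,
    seed: int,
) -> pd.DataFrame:
    """Sample the athlete population with its unobserved ground truth.

    Columns: ``name`` (unique full name), ``given`` , ``birth_year``, ``age``
    (registered age in the race year), ``natal_sex`` and ``gender_id``.  Natal
    sex is a fair coin; the non-binary gender identity is independent of natal
    sex; given names are drawn proportionally to the sex-specific birth counts
    of the athlete's birth year.
    """
    rng = np.random.default_rng(seed)
    n = truth.n_athletes
    ages = rng.integers(AGE_MIN, AGE_MAX + 1, size=n)
    # birth year is race_year - age or race_year - age - 1 with a fair coin,
    # exercising the two-candidate-year logic downstream
    offsets = rng.integers(0, 2, size=n)
    birth_years = truth.race_year - ages - offsets
    need_lo, need_hi = int(birth_years.min()), int(birth_years.max())
    have = set(name_table.years)
    missing = [y for y in range(need_lo, need_hi + 1) if y not in have]
    if missing:
        raise ValueError(f"name table does not cover birth years {missing[:5]}...")

    natal = np.where(rng.random(n) < 0.5, "male", "female")
    gender = np.where(rng.random(n) < truth.frac_nonbinary, "non-binary", natal)

    # per-year sampling distributions over names, by sex
    per_year: dict[int, dict[str, tuple[list[str], np.ndarray]]] = {}
    for year in range(need_lo, need_hi + 1):
        entries = [(nm, c) for (nm, y), c in name_table.items() if y == year]
        by_sex: dict[str, tuple[list[str], np.ndarray]] = {}
        for sex, idx in (("male", 0), ("female", 1)):
            nms = [nm for nm, c in entries if c[idx] > 0]
            wts = np.array([c[idx] for nm, c in entries if c[idx] > 0], dtype=float)
            if len(nms) == 0:
                raise ValueError(f"no {sex} names available for birth year {year}")
            by_sex[sex] = (nms, wts / wts.sum())
        per_year[year] = by_sex

    givens = []
    for i in range(n):
        nms, p = per_year[int(birth_years[i])][natal[i]]
        givens.append(nms[rng.choice(len(nms), p=p)])
    full = [f"{g.title()} Athlete{i:06d}" for i, g in enumerate(givens)]

    return pd.DataFrame(
        {
            "name": full,
            "given": givens,
            "birth_year": birth_years.astype(int),
            "age": ages.astype(int),
            "natal_sex": natal,
            "gender_id": gender,
        }
    )


def _latent_terms(natal_sex: str, gender_id: str) -> tuple[int, int]:
    """(nb_predictor, is_nb) for the generative model."""
    if gender_id != "non-binary":
        return 0, 0
    return (1 if natal_sex == "male" else -1), 1


def generate_race_results(
    athletes: pd.DataFrame,
    truth: SyntheticTruth,
    events: list[str] | None = None,
    races_per_athlete: int = 1,
    seed: int = 0,
    marathon_frac: float = 0.35,
) -> pd.DataFrame:
    """Simulate race results for each athlete.

    log(time) = event mean + beta_female·[natal female] + beta_age·(age−40)
    + beta_age2·(age−40)² + beta_nb·[non-binary] + beta_nbp·nb_predictor
    + N(0, sigma²).  Each athlete runs ``races_per_athlete`` distinct events;
    a fraction ``marathon_frac`` of athletes is guaranteed to include the
    marathon.  All races fall in ``truth.race_year``; the registered age is
    the athlete's age for that year.
    """
    if races_per_athlete < 1:
        raise ValueError("races_per_athlete must be >= 1")
    if events is None:
        events = list(truth.event_log_means)
    if MARATHON not in events:
        raise ValueError("events must include the marathon")
    unknown = [e for e in events if e not in truth.event_log_means]
    if unknown:
        raise ValueError(f"events without a log-mean: {unknown}")
    rng = np.random.default_rng(seed)

    # one fixed date per event within the race year
    year_start = _date(truth.race_year, 1, 1)
    event_dates = {
        e: (year_start + timedelta(days=int(d))).isoformat()
        for e, d in zip(sorted(events), rng.integers(0, 365, size=len(events)))
    }

    others = [e for e in events if e != MARATHON]
    k = min(races_per_athlete, len(events))
    rows: list[tuple] = []
    for row in athletes.itertuples(index=False):
        if others and rng.random() >= marathon_frac and k <= len(others):
            chosen = list(rng.choice(others, size=k, replace=False))
        else:
            extra = min(k - 1, len(others))
            chosen = [MARATHON] + (
                list(rng.choice(others, size=extra, replace=False)) if extra else []
            )
        age_c = row.age - 40
        nbp, is_nb = _latent_terms(row.natal_sex, row.gender_id)
        base = (
            truth.beta_female * (row.natal_sex == "female")
            + truth.beta_age * age_c
            + truth.beta_age2 * age_c**2
            + truth.beta_nb * is_nb
            + truth.beta_nbp * nbp
        )
        for event in chosen:
            log_t = truth.event_log_means[event] + base + truth.sigma * rng.standard_normal()
            rows.append(
                (row.name, event, event_dates[event], row.age, row.gender_id, math.exp(log_t))
            )
    return pd.DataFrame(
        rows, columns=["name", "event", "date", "age", "gender_id", "time_seconds"]
    )


def generate_lookup(athletes: pd.DataFrame, coverage: float, seed: int) -> dict[str, str]:
    """Label a random fraction of non-binary athletes with their true natal sex.

    Emulates a partial external source: each non-binary athlete is included
    independently with probability ``coverage``; labels equal ground truth.
    Keys are normalized full names.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    from .names import normalize_name

    rng = np.random.default_rng(seed)
    nb = athletes[athletes["gender_id"] == "non-binary"]
    out: dict[str, str] = {}
    for row in nb.itertuples(index=False):
        if rng.random() < coverage:
            out[normalize_name(row.name)] = row.natal_sex
    return out


def write_results_csv(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["name", "event", "date", "age", "gender_id", "time_seconds"]
    df.to_csv(path, columns=cols, index=False)


def read_results_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"name": str, "event": str, "date": str})
    required = {"name", "event", "date", "age", "gender_id", "time_seconds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"results CSV missing columns {sorted(missing)}")
    return df


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(truth), fh, sort_keys=False)


def read_truth(path: str | Path) -> SyntheticTruth:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SyntheticTruth(**data)


def simulate_bundle(
    truth: SyntheticTruth,
    out_dir: str | Path,
    n_names: int = 60,
    lookup_coverage: float = 0.55,
    races_per_athlete: int = 2,
    marathon_frac: float = 0.35,
    ambiguous_frac: float = 0.2,
    sex_exclusive: bool = False,
) -> dict[str, Path]:
    """Write a complete synthetic input bundle to ``out_dir``.

    Produces ``results.csv``, an SSA-layout ``names/`` directory,
    ``lookup.csv``, the ground-truth sidecar ``truth.yaml`` and
    ``athletes.csv`` (with the unobserved natal sex, for recovery tests).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]

    year_range = (truth.race_year - AGE_MAX - 1, truth.race_year - AGE_MIN)
    table = generate_name_table(
        n_names, year_range, sub[0], ambiguous_frac=ambiguous_frac, sex_exclusive=sex_exclusive
    )
    athletes = generate_athletes(truth, table, sub[1])
    results = generate_race_results(
        athletes,
        truth,
        races_per_athlete=races_per_athlete,
        seed=sub[2],
        marathon_frac=marathon_frac,
    )
    lookup = generate_lookup(athletes, lookup_coverage, sub[3])

    paths = {
        "results": out_dir / "results.csv",
        "names": out_dir / "names",
        "lookup": out_dir / "lookup.csv",
        "truth": out_dir / "truth.yaml",
        "athletes": out_dir / "athletes.csv",
    }
    write_results_csv(results, paths["results"])
    table.to_ssa_dir(paths["names"])
    from .names import write_lookup

    write_lookup(lookup, paths["lookup"])
    write_truth(truth, paths["truth"])
    athletes.to_csv(paths["athletes"], index=False)
    return paths
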