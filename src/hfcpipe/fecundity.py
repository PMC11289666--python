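"""De-lifing fecundity contributions from sighting and calving histories.

Population fecundity in a year is the number of calves observed divided by
the estimated number of adult females alive.  A female's de-lifing
contribution for a year centres her (windowed) birth indicator on that
population fecundity and scales by the number of *other* adult females:

    contribution_i,y = (reproduced_i,y - popfecundity_y) / (N_y - 1)

where ``reproduced_i,y`` is 1 if she calved within a sliding window around
year ``y`` (half-width 1 by default, reflecting the species' three-year
calving cycle) and ``N_y`` is the adult-female abundance.  A female's
fitness score is the mean of her yearly contributions over the years she
was both adult and alive within the analysis range; females with fewer
than a minimum number of usable years (default 6) are flagged as excluded.

Adulthood rules: a female is adult from age nine if her birth year is
known, from eight years after first sighting otherwise, or from the year
of her first calf if that comes earlier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "IndividualHistory",
    "YearlyPopulationRecord",
    "FecundityResult",
    "adult_onset_year",
    "population_fecundity",
    "reproduced_in_window",
    "individual_contribution",
    "mean_individual_fecundity",
    "compute_fecundity",
    "read_histories",
    "write_histories",
    "read_population",
    "write_population",
    "results_to_frame",
]

DEFAULT_RANGE = (1990, 2020)
DEFAULT_WINDOW = 1
DEFAULT_MIN_YEARS = 6


@dataclass(frozen=True)
class IndividualHistory:
    """One female's life record: the unit of fecundity calculation."""

    id: str
    birth_year: int | None = None
    first_sighting_year: int | None = None
    calving_years: frozenset[int] = field(default_factory=frozenset)
    last_year_alive: int | None = None  # None = record open (alive at last update)

    def __post_init__(self) -> None:
        object.__setattr__(self, "calving_years", frozenset(self.calving_years))
        if self.birth_year is None and self.first_sighting_year is None:
            raise ValueError(f"{self.id}: needs a birth year or a first-sighting year")

    def validate(self, min_age_first_calf: int = 5) -> None:
        """Sanity-check calving years against the observed lifespan."""
        first_seen = self.birth_year if self.birth_year is not None else self.first_sighting_year
        for year in self.calving_years:
            if self.last_year_alive is not None and year > self.last_year_alive:
                raise ValueError(f"{self.id}: calf in {year} after last year alive")
            if self.birth_year is not None and year < self.birth_year + min_age_first_calf:
                raise ValueError(f"{self.id}: calf in {year} implausibly early")
            if self.birth_year is None and year < first_seen:
                raise ValueError(f"{self.id}: calf in {year} before first sighting")

    def alive_in(self, year: int, presumed_alive_lag: int = 0) -> bool:
        """Alive through the last recorded year (+ optional lag); open records stay alive."""
        if self.last_year_alive is None:
            return True
        return year <= self.last_year_alive + presumed_alive_lag


@dataclass(frozen=True)
class YearlyPopulationRecord:
    """Calves observed and (model-estimated) adult females alive in one year."""

    year: int
    calves_observed: int
    adult_females_alive: float

    def __post_init__(self) -> None:
        if self.calves_observed < 0:
            raise ValueError(f"{self.year}: negative calf count")
        if self.adult_females_alive < 1:
            raise ValueError(f"{self.year}: adult_females_alive must be >= 1")


@dataclass
class FecundityResult:
    id: str
    yearly_contributions: dict[int, float]
    mean_fecundity: float
    n_years_used: int
    included: bool


def adult_onset_year(history: IndividualHistory) -> int:
    """First year the female counts as adult.

    Birth year known: age nine.  Unknown: eight years after first sighting.
    Either way, a first calf before that threshold makes her adult in the
    calving year.
    """
    if history.birth_year is not None:
        threshold = history.birth_year + 9
    elif history.first_sighting_year is not None:
        threshold = history.first_sighting_year + 8
    else:  # pragma: no cover - blocked by __post_init__
        raise ValueError(f"{history.id}: no birth or sighting year")
    if history.calving_years:
        return min(threshold, min(history.calving_years))
    return threshold


def population_fecundity(record: YearlyPopulationRecord) -> float:
    """Calves observed divided by adult females alive."""
    if record.adult_females_alive < 1:
        raise ValueError(f"{record.year}: zero/invalid adult-female abundance")
    return record.calves_observed / record.adult_females_alive


def reproduced_in_window(history: IndividualHistory, year: int, window: int = DEFAULT_WINDOW) -> int:
    """1 if the female calved within ``window`` years of ``year``, else 0.

    Calving events outside the analysis range still count toward windows
    overlapping the boundary.
    """
    return int(any(year - window <= cy <= year + window for cy in history.calving_years))


def individual_contribution(
    history: IndividualHistory,
    record: YearlyPopulationRecord,
    window: int = DEFAULT_WINDOW,
) -> float:
    """De-lifing fecundity contribution of one female in one year."""
    if record.adult_females_alive <= 1:
        raise ValueError(
            f"{record.year}: de-lifing undefined with a single adult female"
        )
    indicator = reproduced_in_window(history, record.year, window)
    return (indicator - population_fecundity(record)) / (record.adult_females_alive - 1)


def _records_by_year(
    records: Iterable[YearlyPopulationRecord] | Mapping[int, YearlyPopulationRecord],
) -> dict[int, YearlyPopulationRecord]:
    if isinstance(records, Mapping):
        return dict(records)
    return {r.year: r for r in records}


def mean_individual_fecundity(
    history: IndividualHistory,
    records: Iterable[YearlyPopulationRecord] | Mapping[int, YearlyPopulationRecord],
    year_range: tuple[int, int] = DEFAULT_RANGE,
    window: int = DEFAULT_WINDOW,
    min_years: int = DEFAULT_MIN_YEARS,
    presumed_alive_lag: int = 0,
) -> FecundityResult:
    """Mean yearly de-lifing contribution over the female's adult-alive years."""
    by_year = _records_by_year(records)
    start, end = year_range
    onset = adult_onset_year(history)
    contributions: dict[int, float] = {}
    for year in range(max(start, onset), end + 1):
        if not history.alive_in(year, presumed_alive_lag):
            break
        if year not in by_year:
            raise ValueError(
                f"{history.id}: no population record for required year {year}"
            )
        contributions[year] = individual_contribution(history, by_year[year], window)
    n = len(contributions)
    mean = sum(contributions.values()) / n if n else math.nan
    return FecundityResult(
        id=history.id,
        yearly_contributions=contributions,
        mean_fecundity=mean,
        n_years_used=n,
        included=n >= min_years,
    )


def compute_fecundity(
    histories: Iterable[IndividualHistory],
    records: Iterable[YearlyPopulationRecord] | Mapping[int, YearlyPopulationRecord],
    year_range: tuple[int, int] = DEFAULT_RANGE,
    window: int = DEFAULT_WINDOW,
    min_years: int = DEFAULT_MIN_YEARS,
    presumed_alive_lag: int = 0,
) -> list[FecundityResult]:
    by_year = _records_by_year(records)
    return [
        mean_individual_fecundity(
            h, by_year, year_range=year_range, window=window,
            min_years=min_years, presumed_alive_lag=presumed_alive_lag,
        )
        for h in histories
    ]


def results_to_frame(results: Iterable[FecundityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": r.id,
            "mean_fecundity": r.mean_fecundity,
            "n_years_used": r.n_years_used,
            "included": r.included,
        }
        for r in results
    )


# ---------------------------------------------------------------------------
# CSV I/O.  Histories: id,birth_year,first_sighting_year,calving_years,
# last_year_alive with calving years ';'-separated; blanks mean unknown/open.
# ---------------------------------------------------------------------------

def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return int(value)


def read_histories(path) -> list[IndividualHistory]:
    df = pd.read_csv(path, dtype={"calving_years": str})
    out = []
    for row in df.itertuples(index=False):
        raw = getattr(row, "calving_years", None)
        calves = frozenset(
            int(tok) for tok in str(raw).split(";") if tok and tok.lower() != "nan"
        ) if raw is not None else frozenset()
        out.append(
            IndividualHistory(
                id=str(row.id),
                birth_year=_opt_int(row.birth_year),
                first_sighting_year=_opt_int(row.first_sighting_year),
                calving_years=calves,
                last_year_alive=_opt_int(row.last_year_alive),
            )
        )
    return out


def write_histories(histories: Iterable[IndividualHistory], path) -> None:
    pd.DataFrame(
        {
            "id": h.id,
            "birth_year": h.birth_year,
            "first_sighting_year": h.first_sighting_year,
            "calving_years": ";".join(str(y) for y in sorted(h.calving_years)),
            "last_year_alive": h.last_year_alive,
        }
        for h in histories
    ).to_csv(path, index=False)


def read_population(path) -> list[YearlyPopulationRecord]:
    df = pd.read_csv(path)
    return [
        YearlyPopulationRecord(
            year=int(r.year),
            calves_observed=int(r.calves_observed),
            adult_females_alive=float(r.adult_females_alive),
        )
        for r in df.itertuples(index=False)
    ]


def write_population(records: Iterable[YearlyPopulationRecord], path) -> None:
    pd.DataFrame(
        {
            "year": r.year,
            "calves_observed": r.calves_observed,
            "adult_females_alive": r.adult_females_alive,
        }
        for r in records
    ).to_csv(path, index=False)
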