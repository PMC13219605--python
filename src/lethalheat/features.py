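"""Heatwave event extraction and predictor construction.

A heatwave here is a maximal run of consecutive days whose daily maximum
temperature exceeds the city's historical 90th percentile. For each event
this module derives the 15 model inputs: the absolute conditions of the
event (maximum temperature, mean relative humidity, mean windspeed), the
thermo-temporal differentials ``ΔT_n`` / ``ΔH_n`` against the n days
preceding the event (n ∈ {30, 90, 180}), multi-year "adaptive" temperature
and humidity means that proxy long-run acclimatisation, and compressions of
country-level sociodemographic tables (mean BMI, mean age, the age gradient
of the population pyramid, and the Socio-Demographic Index).

Wet-bulb temperature is computed with Stull's empirical fit, which is valid
for roughly −20…50 °C and relative humidity ≥ 5%.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_NAMES",
    "CitySeries",
    "HeatwaveEvent",
    "PopulationPyramid",
    "CountryDemographics",
    "FeatureVector",
    "InsufficientHistoryError",
    "stull_wbt",
    "stull_validity_mask",
    "extract_events",
    "temp_differential",
    "humid_differential",
    "adaptive_temperature",
    "adaptive_humidity",
    "mean_age",
    "age_gradient",
    "build_feature_vector",
    "build_feature_table",
    "nearest_demographics",
]

#: Canonical ordering of the 15 model inputs.
FEATURE_NAMES: tuple[str, ...] = (
    "max_temp",
    "mean_humid",
    "mean_wind",
    "mean_bmi",
    "mean_age",
    "age_gradient",
    "mean_sdi",
    "dT30",
    "dT90",
    "dT180",
    "adaptive_temp",
    "dH30",
    "dH90",
    "dH180",
    "adaptive_humid",
)

DIFFERENTIAL_WINDOWS: tuple[int, ...] = (30, 90, 180)


class InsufficientHistoryError(ValueError):
    """Raised when a series does not cover the antecedent window an
    operation needs; the message names the required window."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CitySeries:
    """Contiguous daily weather record for one city.

    ``dates`` must be strictly increasing daily timestamps without gaps;
    ``tmax`` (°C), ``rh`` (%) and ``wind`` (m/s) are aligned arrays.
    """

    city_id: str
    country_id: str
    dates: pd.DatetimeIndex
    tmax: np.ndarray
    rh: np.ndarray
    wind: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmax = np.asarray(self.tmax, dtype=float)
        self.rh = np.asarray(self.rh, dtype=float)
        self.wind = np.asarray(self.wind, dtype=float)
        n = len(self.dates)
        if not (len(self.tmax) == len(self.rh) == len(self.wind) == n):
            raise ValueError("series arrays must align with dates")
        if n > 1:
            deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                raise ValueError("dates must be contiguous daily and strictly increasing")
        if np.any(self.rh < 0) or np.any(self.rh > 100):
            raise ValueError("relative humidity must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.dates)

    def index_of(self, date: pd.Timestamp) -> int:
        """Positional index of a calendar day, exploiting contiguity."""
        pos = (pd.Timestamp(date) - self.dates[0]).days
        if pos < 0 or pos >= len(self.dates):
            raise KeyError(f"{date!r} outside series for city {self.city_id}")
        return pos

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "city_id": self.city_id,
                "date": self.dates.strftime("%Y-%m-%d"),
                "tmax_c": self.tmax,
                "rh_pct": self.rh,
                "wind_ms": self.wind,
            }
        )


@dataclass
class HeatwaveEvent:
    """An above-percentile episode with its meteorological summaries.

    ``tmax`` is the maximum of daily maximum temperature over the event
    window (inclusive of both endpoints); ``rh_mean`` and ``wind_mean`` are
    means over the same window. ``lethal`` is the binary impact label, and
    ``mechanism`` (synthetic corpora only) records which generating process
    produced a lethal label: ``"shock"``, ``"threshold"`` or ``"none"``.
    """

    event_id: str
    city_id: str
    country_id: str
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    tmax: float
    rh_mean: float
    wind_mean: float
    lethal: int | None = None
    mechanism: str | None = None

    def __post_init__(self) -> None:
        self.start_date = pd.Timestamp(self.start_date)
        self.end_date = pd.Timestamp(self.end_date)
        if self.start_date > self.end_date:
            raise ValueError("event start_date must not exceed end_date")

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


@dataclass
class PopulationPyramid:
    """Age structure discretised over 5-year brackets.

    ``bracket_lower_bounds`` are the lower edges in years (0, 5, 10, …);
    ``proportions`` are population fractions summing to one. The bracket
    midpoint convention is lower bound + 2.5 years, including the
    open-ended top bracket.
    """

    bracket_lower_bounds: np.ndarray
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.bracket_lower_bounds = np.asarray(self.bracket_lower_bounds, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if len(self.bracket_lower_bounds) != len(self.proportions):
            raise ValueError("bracket bounds and proportions must align")
        if len(self.proportions) < 3:
            raise ValueError("pyramid needs at least 3 brackets")
        if np.any(self.proportions < 0):
            raise ValueError("pyramid proportions must be non-negative")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"pyramid proportions must sum to 1 (got {self.proportions.sum():.12f})"
            )

    @property
    def midpoints(self) -> np.ndarray:
        return self.bracket_lower_bounds + 2.5


@dataclass
class CountryDemographics:
    """Country-year sociodemographic record: mean BMI (kg/m²), the
    population pyramid, and the Socio-Demographic Index in [0, 1]."""

    country_id: str
    year: int
    mean_bmi: float
    pyramid: PopulationPyramid
    sdi: float

    def __post_init__(self) -> None:
        if self.mean_bmi <= 0:
            raise ValueError("mean_bmi must be positive")
        if not 0.0 <= self.sdi <= 1.0:
            raise ValueError("sdi must lie in [0, 1]")


@dataclass
class FeatureVector:
    """The 15 model inputs for one event, in canonical order."""

    max_temp: float
    mean_humid: float
    mean_wind: float
    mean_bmi: float
    mean_age: float
    age_gradient: float
    mean_sdi: float
    dT30: float
    dT90: float
    dT180: float
    adaptive_temp: float
    dH30: float
    dH90: float
    dH180: float
    adaptive_humid: float

    def as_array(self) -> np.ndarray:
        arr = np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature vector contains non-finite values")
        return arr

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FEATURE_NAMES}


# ---------------------------------------------------------------------------
# Wet-bulb temperature
# ---------------------------------------------------------------------------


def stull_wbt(t, rh):
    """Wet-bulb temperature (°C) from dry-bulb ``t`` (°C) and relative
    humidity ``rh`` (%), via Stull's empirical one-equation fit.

    Accepts scalars or arrays. ``rh`` must be strictly positive. Values
    outside the fit's stated validity range are still computed; use
    :func:`stull_validity_mask` to flag them.
    """
    t_arr = np.asarray(t, dtype=float)
    rh_arr = np.asarray(rh, dtype=float)
    if np.any(rh_arr <= 0):
        raise ValueError("relative humidity must be strictly positive for wet-bulb")
    tw = (
        t_arr * np.arctan(0.151977 * np.sqrt(rh_arr + 8.313659))
        + np.arctan(t_arr + rh_arr)
        - np.arctan(rh_arr - 1.676331)
        + 0.00391838 * rh_arr**1.5 * np.arctan(0.023101 * rh_arr)
        - 4.686035
    )
    if np.isscalar(t) and np.isscalar(rh):
        return float(tw)
    return tw


def stull_validity_mask(t, rh) -> np.ndarray:
    """True where (t, rh) lies inside the fit's stated validity range
    (approximately −20…50 °C dry-bulb and rh ≥ 5%)."""
    t_arr = np.asarray(t, dtype=float)
    rh_arr = np.asarray(rh, dtype=float)
    return (t_arr >= -20.0) & (t_arr <= 50.0) & (rh_arr >= 5.0) & (rh_arr <= 100.0)


# ---------------------------------------------------------------------------
# Event extraction
# ---------------------------------------------------------------------------


def extract_events(
    series: CitySeries,
    percentile: float = 0.90,
    min_duration: int = 2,
) -> list[HeatwaveEvent]:
    """Maximal runs of at least ``min_duration`` consecutive days strictly
    above the city's historical ``percentile`` of daily maximum temperature.

    The percentile basis is the full available record of the series. A
    constant series yields no events (no day strictly exceeds its own
    percentile).
    """
    if len(series) < 365:
        raise ValueError("series must cover at least one year to define a climatology")
    if min_duration < 1:
        raise ValueError("min_duration must be >= 1")
    threshold = float(np.quantile(series.tmax, percentile))
    above = series.tmax > threshold
    if not above.any():
        return []
    # run boundaries from sign changes of the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    starts, ends = edges[::2], edges[1::2]  # ends exclusive
    events: list[HeatwaveEvent] = []
    for s, e in zip(starts, ends):
        if e - s < min_duration:
            continue
        events.append(
            HeatwaveEvent(
                event_id=f"{series.city_id}:{series.dates[s].strftime('%Y%m%d')}",
                city_id=series.city_id,
                country_id=series.country_id,
                start_date=series.dates[s],
                end_date=series.dates[e - 1],
                tmax=float(series.tmax[s:e].max()),
                rh_mean=float(series.rh[s:e].mean()),
                wind_mean=float(series.wind[s:e].mean()),
            )
        )
    return events


# ---------------------------------------------------------------------------
# Antecedent differentials and adaptive variables
# ---------------------------------------------------------------------------


def _antecedent_window(series: CitySeries, anchor: pd.Timestamp, n: int) -> slice:
    """Positions of the n calendar days strictly before ``anchor``."""
    end = (pd.Timestamp(anchor) - series.dates[0]).days
    start = end - n
    if start < 0 or end > len(series):
        raise InsufficientHistoryError(
            f"series for city {series.city_id} does not cover the {n} days "
            f"before {pd.Timestamp(anchor).date()}"
        )
    return slice(start, end)


def _shift_years_back(day: "datetime.date", j: int) -> "datetime.date":
    """Same calendar day j years earlier; Feb 29 rolls to Feb 28."""
    try:
        return day.replace(year=day.year - j)
    except ValueError:
        return day.replace(year=day.year - j, day=28)


def temp_differential(series: CitySeries, event: HeatwaveEvent, n: int) -> float:
    """ΔT_n: event maximum temperature minus the mean daily maximum over
    the n days strictly before the event start."""
    win = _antecedent_window(series, event.start_date, n)
    return float(event.tmax - series.tmax[win].mean())


def humid_differential(series: CitySeries, event: HeatwaveEvent, n: int) -> float:
    """ΔH_n: event mean humidity minus the mean humidity over the n days
    strictly before the event start."""
    win = _antecedent_window(series, event.start_date, n)
    return float(event.rh_mean - series.rh[win].mean())


def _adaptive_mean(
    values: np.ndarray, series: CitySeries, event: HeatwaveEvent, n: int, m: int
) -> float:
    """Mean over the same n-day pre-event calendar window in each of the m
    years ending with the event year; truncated to all available complete
    years when fewer than m exist, erroring below 3."""
    if m < 1:
        raise ValueError("m must be >= 1")
    # plain-date arithmetic: hot path for large corpora
    start0 = series.dates[0].date()
    ev_day = event.start_date.date()
    n_days = len(values)
    total = 0.0
    count = 0
    used = 0
    for j in range(m):
        end = (_shift_years_back(ev_day, j) - start0).days
        start = end - n
        if start < 0 or end > n_days:
            break
        total += float(values[start:end].sum())
        count += n
        used += 1
    if used < 3:
        raise InsufficientHistoryError(
            f"adaptive variable needs >= 3 years of the {n}-day pre-event window "
            f"before {event.start_date.date()} for city {series.city_id} "
            f"(found {used})"
        )
    return total / count


def adaptive_temperature(
    series: CitySeries, event: HeatwaveEvent, n: int = 30, m: int = 10
) -> float:
    """Long-run acclimatisation proxy: mean of daily maximum temperature
    over the n-day pre-event window in the event year and the m−1 years
    before it (e.g. a late-January event averages that January and the
    previous nine Januaries)."""
    return _adaptive_mean(series.tmax, series, event, n, m)


def adaptive_humidity(
    series: CitySeries, event: HeatwaveEvent, n: int = 30, m: int = 10
) -> float:
    """Humidity analogue of :func:`adaptive_temperature`."""
    return _adaptive_mean(series.rh, series, event, n, m)


# ---------------------------------------------------------------------------
# Demographic compressions
# ---------------------------------------------------------------------------


def mean_age(pyramid: PopulationPyramid) -> float:
    """Population-weighted mean age in years (bracket midpoints)."""
    return float(np.dot(pyramid.midpoints, pyramid.proportions))


def age_gradient(pyramid: PopulationPyramid) -> float:
    """Regression slope compressing the pyramid's shape into one number.

    The regression assigns y = bracket age (midpoint) and x = proportion of
    the population in the bracket, so the slope is cov(x, y) / var(x):
    m = (x̄·ȳ − mean(x·y)) / (x̄·x̄ − mean(x·x)).
    A pyramid with all brackets equal has zero variance in x and no defined
    slope.
    """
    x = pyramid.proportions
    y = pyramid.midpoints
    denom = np.mean(x) ** 2 - np.mean(x * x)
    if denom == 0.0:
        raise ValueError("age gradient undefined: all pyramid proportions are equal")
    numer = np.mean(x) * np.mean(y) - np.mean(x * y)
    return float(numer / denom)


def nearest_demographics(
    records: Sequence[CountryDemographics], year: int
) -> CountryDemographics:
    """Record whose year is nearest to ``year``; ties resolve to the
    earlier year (annual tables vs daily events)."""
    if not records:
        raise KeyError("no demographic records supplied")
    return min(records, key=lambda r: (abs(r.year - year), r.year))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def build_feature_vector(
    event: HeatwaveEvent,
    series: CitySeries,
    demographics: Mapping[str, Sequence[CountryDemographics]],
    adaptive_n: int = 30,
    m: int = 10,
) -> FeatureVector:
    """Populate all 15 inputs for one event.

    ``demographics`` maps country_id to that country's year records; the
    record nearest the event year is used. Errors from component
    operations are re-raised with the event id for context.
    """
    if event.city_id != series.city_id:
        raise ValueError(
            f"event {event.event_id} belongs to city {event.city_id}, "
            f"series is for {series.city_id}"
        )
    try:
        demo = nearest_demographics(
            demographics[event.country_id], event.start_date.year
        )
        return FeatureVector(
            max_temp=event.tmax,
            mean_humid=event.rh_mean,
            mean_wind=event.wind_mean,
            mean_bmi=demo.mean_bmi,
            mean_age=mean_age(demo.pyramid),
            age_gradient=age_gradient(demo.pyramid),
            mean_sdi=demo.sdi,
            dT30=temp_differential(series, event, 30),
            dT90=temp_differential(series, event, 90),
            dT180=temp_differential(series, event, 180),
            adaptive_temp=adaptive_temperature(series, event, adaptive_n, m),
            dH30=humid_differential(series, event, 30),
            dH90=humid_differential(series, event, 90),
            dH180=humid_differential(series, event, 180),
            adaptive_humid=adaptive_humidity(series, event, adaptive_n, m),
        )
    except (KeyError, ValueError) as exc:
        raise type(exc)(f"event {event.event_id}: {exc}") from exc


def build_feature_table(
    events: Iterable[HeatwaveEvent],
    series_map: Mapping[str, CitySeries],
    demographics: Mapping[str, Sequence[CountryDemographics]],
    adaptive_n: int = 30,
    m: int = 10,
) -> pd.DataFrame:
    """Feature matrix for a collection of events, indexed by event_id,
    columns in canonical order plus the lethal label when present."""
    rows = []
    index = []
    labels = []
    have_labels = True
    for ev in events:
        vec = build_feature_vector(
            ev, series_map[ev.city_id], demographics, adaptive_n=adaptive_n, m=m
        )
        rows.append(vec.as_array())
        index.append(ev.event_id)
        if ev.lethal is None:
            have_labels = False
        else:
            labels.append(int(ev.lethal))
    df = pd.DataFrame(rows, index=pd.Index(index, name="event_id"), columns=FEATURE_NAMES)
    if have_labels and labels:
        df["lethal"] = labels
    return df
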