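"""Seeded synthetic weather, demographics and labelled heatwave corpora.

The generator emulates the statistical shape of the real inputs every
downstream stage needs, without any downloads: multi-city daily maximum
temperature as sinusoidal seasonality plus AR(1) Gaussian noise, relative
humidity anti-coupled to the temperature anomaly, plausible country-year
sociodemographic tables, and a two-mechanism lethality label model. Lethal
labels arise either from a hard wet-bulb cutoff ("threshold" mechanism) or
from a logistic latent risk on thermo-temporal and demographic drivers
("shock" mechanism), with the logistic intercept tuned by bisection so the
realised lethal prevalence matches a target (default 0.78%).

All randomness flows from one root seed through named substreams, so a
corpus is byte-identical given the same configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .features import (
    CitySeries,
    CountryDemographics,
    HeatwaveEvent,
    PopulationPyramid,
    build_feature_table,
    extract_events,
    stull_wbt,
)

__all__ = [
    "WeatherGenParams",
    "LethalityMechanism",
    "SyntheticCorpus",
    "generate_city_series",
    "generate_demographics",
    "plant_lethality",
    "generate_corpus",
]

DAYS_PER_YEAR = 365.25
PYRAMID_LOWER_BOUNDS = np.arange(0, 95, 5)  # 19 brackets, 0–4 … 90+

#: Shock-mechanism driver columns, in the order shock_weights applies to.
SHOCK_DRIVERS = ("dT180", "dT30", "mean_bmi", "age_gradient", "mean_sdi")


def _substream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Independent, reproducible generator for a named substream."""
    digest = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
    return np.random.default_rng([int(seed), digest, *map(int, extra)])


@dataclass
class WeatherGenParams:
    """Configuration of the multi-city weather process.

    ``mean_tmax_range`` gives the bounds from which each city's annual-mean
    daily maximum temperature (°C) is drawn. Temperature follows
    mean + amplitude·sin(2π(t − phase)/365.25) + AR(1) noise; humidity is a
    counter-phased seasonal mean plus ``rh_temp_coupling`` times the
    temperature anomaly (negative coupling makes hot days drier), clipped
    to [1, 100].

    Each city's seasonal amplitude is ``seasonal_amplitude`` scaled by a
    uniform draw from ``amplitude_jitter`` (continental cities swing
    harder than maritime ones; set the jitter to (1, 1) for identical
    cities). Without this between-city variation the thermo-temporal
    differentials at different horizons collapse into near-duplicates of
    one another, which real multi-city records do not show.
    """

    n_cities: int = 8
    years: int = 15
    mean_tmax_range: tuple[float, float] = (8.0, 24.0)
    seasonal_amplitude: float = 10.0
    amplitude_jitter: tuple[float, float] = (0.5, 1.4)
    seasonal_phase: float = 110.0
    ar1_coefficient: float = 0.7
    noise_sd: float = 2.5
    rh_mean: float = 60.0
    rh_amplitude: float = 10.0
    rh_temp_coupling: float = -2.0
    rh_noise_sd: float = 5.0
    wind_mean: float = 3.5
    wind_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years < 2:
            raise ValueError("years must be >= 2: adaptive variables need history")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if self.n_cities < 1:
            raise ValueError("n_cities must be >= 1")


@dataclass
class LethalityMechanism:
    """Two-mechanism label model.

    An event is lethal outright when its wet-bulb temperature (from event
    max temperature and mean humidity) exceeds ``threshold_wbt`` — the
    conventional heat-dissipation limit. Otherwise lethality is Bernoulli
    with logistic probability σ(intercept + w·z), where z are the
    standardized shock drivers (ΔT_180, ΔT_30, mean BMI, age gradient,
    SDI) and w = ``shock_weights``. The intercept is tuned so the expected
    prevalence matches ``target_prevalence``.
    """

    shock_weights: tuple[float, float, float, float, float] = (10.0, 0.8, 16.0, 0.8, -0.8)
    shock_intercept: float | None = None
    threshold_wbt: float = 35.0
    target_prevalence: float = 0.0078
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_prevalence < 0.5:
            raise ValueError("target_prevalence must lie in (0, 0.5)")
        if self.threshold_wbt <= 25.0:
            raise ValueError("threshold_wbt must exceed 25 °C")
        if len(self.shock_weights) != len(SHOCK_DRIVERS):
            raise ValueError(f"shock_weights must have {len(SHOCK_DRIVERS)} entries")


@dataclass
class SyntheticCorpus:
    """A complete synthetic study: weather series, demographic tables,
    labelled events with their feature matrix, and generation provenance."""

    series: dict[str, CitySeries]
    demographics: dict[str, list[CountryDemographics]]
    events: list[HeatwaveEvent]
    features: pd.DataFrame
    provenance: dict

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_id": [e.event_id for e in self.events],
                "city_id": [e.city_id for e in self.events],
                "country_id": [e.country_id for e in self.events],
                "start_date": [e.start_date.strftime("%Y-%m-%d") for e in self.events],
                "end_date": [e.end_date.strftime("%Y-%m-%d") for e in self.events],
                "tmax_c": [e.tmax for e in self.events],
                "rh_mean_pct": [e.rh_mean for e in self.events],
                "wind_mean_ms": [e.wind_mean for e in self.events],
                "lethal": [e.lethal for e in self.events],
                "mechanism": [e.mechanism for e in self.events],
            }
        )

    def content_hash(self) -> str:
        """Deterministic digest of series, events and labels."""
        h = hashlib.sha256()
        for cid in sorted(self.series):
            s = self.series[cid]
            h.update(cid.encode())
            h.update(np.ascontiguousarray(s.tmax).tobytes())
            h.update(np.ascontiguousarray(s.rh).tobytes())
        h.update(self.events_frame().to_csv(index=False).encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------


def generate_city_series(
    params: WeatherGenParams,
    city_index: int,
    start_year: int = 1980,
    country_id: str | None = None,
) -> CitySeries:
    """Daily weather for one city, deterministic given (seed, city_index).

    The deseasonalised temperature is an AR(1) process with the configured
    lag-one coefficient; humidity is counter-phased seasonally and coupled
    to the temperature anomaly.
    """
    rng = _substream(params.seed, "weather", city_index)
    n_days = int(round(params.years * DAYS_PER_YEAR))
    dates = pd.date_range(f"{start_year}-01-01", periods=n_days, freq="D")
    t = np.arange(n_days, dtype=float)

    lo, hi = params.mean_tmax_range
    city_mean = float(rng.uniform(lo, hi))
    j_lo, j_hi = params.amplitude_jitter
    season_factor = float(rng.uniform(j_lo, j_hi))
    amplitude = params.seasonal_amplitude * season_factor
    season = amplitude * np.sin(
        2.0 * np.pi * (t - params.seasonal_phase) / DAYS_PER_YEAR
    )
    innovations = rng.normal(0.0, params.noise_sd, n_days)
    if params.ar1_coefficient > 0.0:
        anomaly = _signal.lfilter([1.0], [1.0, -params.ar1_coefficient], innovations)
    else:
        anomaly = innovations
    tmax = city_mean + season + anomaly

    # humidity seasonality scales with the same per-city factor
    rh_season = -params.rh_amplitude * season_factor * np.sin(
        2.0 * np.pi * (t - params.seasonal_phase) / DAYS_PER_YEAR
    )
    rh = (
        params.rh_mean
        + rh_season
        + params.rh_temp_coupling * anomaly
        + rng.normal(0.0, params.rh_noise_sd, n_days)
    )
    rh = np.clip(rh, 1.0, 100.0)

    wind = np.clip(rng.normal(params.wind_mean, params.wind_sd, n_days), 0.0, None)

    return CitySeries(
        city_id=f"city{city_index:03d}",
        country_id=country_id or f"country{city_index:03d}",
        dates=dates,
        tmax=tmax,
        rh=rh,
        wind=wind,
    )


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------


def generate_demographics(
    n_countries: int,
    seed: int,
    years: Sequence[int] = tuple(range(1980, 2015)),
) -> dict[str, list[CountryDemographics]]:
    """Country-year tables with plausible structure.

    Pyramids follow a per-country exponential shape across 5-year brackets
    (decay rates straddle zero, so both young, bottom-heavy pyramids with
    negative age gradients and ageing, top-heavier ones with positive
    gradients occur), with a slow ageing drift across years. Mean BMI lies
    in [20, 35] with a mild secular increase; SDI is drawn in [0, 1].
    """
    if n_countries < 1:
        raise ValueError("n_countries must be >= 1")
    rng = _substream(seed, "demographics")
    midpoints = PYRAMID_LOWER_BOUNDS + 2.5
    out: dict[str, list[CountryDemographics]] = {}
    for c in range(n_countries):
        country_id = f"country{c:03d}"
        decay = rng.uniform(-0.012, 0.035)
        # clipped normal: country mean BMIs cluster in the mid-20s with a
        # long upper tail, unlike a bounded uniform whose extremes are
        # draw-dependent
        bmi0 = float(np.clip(rng.normal(26.5, 3.0), 20.5, 34.0))
        sdi0 = rng.uniform(0.3, 0.95)
        bracket_noise = rng.normal(0.0, 0.04, len(midpoints))
        records = []
        for i, year in enumerate(years):
            lam = decay - 0.0003 * i  # slow population ageing
            shape = np.exp(-lam * midpoints) * np.exp(bracket_noise)
            props = shape / shape.sum()
            pyramid = PopulationPyramid(PYRAMID_LOWER_BOUNDS.copy(), props)
            bmi = float(np.clip(bmi0 + 0.03 * i + rng.normal(0.0, 0.05), 20.0, 35.0))
            sdi = float(np.clip(sdi0 + 0.002 * i + rng.normal(0.0, 0.003), 0.0, 1.0))
            records.append(
                CountryDemographics(
                    country_id=country_id,
                    year=int(year),
                    mean_bmi=bmi,
                    pyramid=pyramid,
                    sdi=sdi,
                )
            )
        out[country_id] = records
    return out


def demographics_frame(
    demographics: Mapping[str, Sequence[CountryDemographics]]
) -> pd.DataFrame:
    """Flatten demographic records to the `demographics.csv` schema."""
    rows = []
    for country_id in sorted(demographics):
        for rec in demographics[country_id]:
            row = {
                "country_id": rec.country_id,
                "year": rec.year,
                "mean_bmi": rec.mean_bmi,
                "sdi": rec.sdi,
            }
            for lb, p in zip(
                rec.pyramid.bracket_lower_bounds.astype(int), rec.pyramid.proportions
            ):
                key = f"p_{lb:02d}_{lb + 4:02d}" if lb < 90 else "p_90_plus"
                row[key] = p
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lethality planting
# ---------------------------------------------------------------------------


def _expected_prevalence(intercept: float, latent: np.ndarray, n_threshold: int) -> float:
    p = 1.0 / (1.0 + np.exp(-(intercept + latent)))
    return (n_threshold + p.sum()) / (len(latent) + n_threshold)


def _tune_intercept(
    latent: np.ndarray,
    n_threshold: int,
    target: float,
    rel_tol: float = 0.10,
    max_iter: int = 60,
) -> float:
    """Bisection on the logistic intercept so the expected lethal fraction
    hits the target within ±10% relative. The bracket must extend below
    minus the largest latent risk, or the achievable prevalence is
    floored above the target."""
    lo, hi = -(np.abs(latent).max() + 20.0), 10.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        prev = _expected_prevalence(mid, latent, n_threshold)
        if abs(prev - target) <= rel_tol * target:
            return mid
        if prev < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def plant_lethality(
    events: Sequence[HeatwaveEvent],
    features: pd.DataFrame,
    mech: LethalityMechanism,
) -> list[HeatwaveEvent]:
    """Assign lethal labels in place via the two-mechanism model.

    Events whose Stull wet-bulb temperature exceeds ``mech.threshold_wbt``
    are lethal with mechanism "threshold". All others draw a Bernoulli
    label from the shock logistic risk; lethal draws get mechanism
    "shock", the rest "none". Returns the same event objects, labelled.
    """
    if len(events) != len(features):
        raise ValueError(
            f"events ({len(events)}) and features ({len(features)}) must align 1:1"
        )
    missing = [c for c in SHOCK_DRIVERS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks shock driver columns: {missing}")
    ids = [e.event_id for e in events]
    if list(features.index) != ids:
        if set(features.index) != set(ids):
            raise ValueError("events and features cannot be aligned by event_id")
        features = features.loc[ids]

    wbt = stull_wbt(
        np.array([e.tmax for e in events]), np.array([e.rh_mean for e in events])
    )
    is_threshold = np.asarray(wbt) > mech.threshold_wbt

    drivers = features.loc[~is_threshold, list(SHOCK_DRIVERS)].to_numpy(dtype=float)
    sd = drivers.std(axis=0, ddof=0)
    sd[sd == 0.0] = 1.0
    z = (drivers - drivers.mean(axis=0)) / sd
    latent = z @ np.asarray(mech.shock_weights, dtype=float)

    n_threshold = int(is_threshold.sum())
    intercept = mech.shock_intercept
    if intercept is None:
        intercept = _tune_intercept(latent, n_threshold, mech.target_prevalence)
    p_shock = 1.0 / (1.0 + np.exp(-(intercept + latent)))

    rng = _substream(mech.seed, "labels")
    draws = rng.random(len(latent)) < p_shock

    shock_iter = iter(draws)
    for ev, thr in zip(events, is_threshold):
        if thr:
            ev.lethal, ev.mechanism = 1, "threshold"
        else:
            lethal = bool(next(shock_iter))
            ev.lethal = int(lethal)
            ev.mechanism = "shock" if lethal else "none"
    return list(events)


# ---------------------------------------------------------------------------
# Full corpus
# ---------------------------------------------------------------------------


def generate_corpus(
    weather: WeatherGenParams,
    mech: LethalityMechanism,
    percentile: float = 0.90,
    min_duration: int = 2,
    adaptive_n: int = 30,
    m: int = 10,
    min_history_years: int = 10,
    cities_per_country: int = 4,
    start_year: int = 1980,
) -> SyntheticCorpus:
    """Run the full chain series → event extraction → features → labels.

    Events beginning within the first ``min_history_years`` years of a
    city's record are dropped so every kept event is fully featurizable
    (the adaptive variables look back up to m years).
    """
    n_countries = max(1, -(-weather.n_cities // cities_per_country))
    years = range(start_year, start_year + weather.years)
    demographics = generate_demographics(n_countries, weather.seed, years=tuple(years))

    series: dict[str, CitySeries] = {}
    events: list[HeatwaveEvent] = []
    for i in range(weather.n_cities):
        country_id = f"country{i // cities_per_country:03d}"
        s = generate_city_series(weather, i, start_year=start_year, country_id=country_id)
        series[s.city_id] = s
        cutoff = s.dates[0] + pd.DateOffset(years=min_history_years)
        for ev in extract_events(s, percentile=percentile, min_duration=min_duration):
            if ev.start_date >= cutoff and ev.start_date - pd.Timedelta(days=180) >= s.dates[0]:
                events.append(ev)

    if not events:
        raise ValueError(
            f"no heatwave events extracted (percentile={percentile}, "
            f"min_duration={min_duration}, min_history_years={min_history_years}); "
            "lengthen the series or relax the extraction settings"
        )

    feats = build_feature_table(events, series, demographics, adaptive_n=adaptive_n, m=m)
    plant_lethality(events, feats, mech)
    feats["lethal"] = [e.lethal for e in events]

    provenance = {
        "weather": asdict(weather),
        "mechanism": asdict(mech),
        "extraction": {
            "percentile": percentile,
            "min_duration": min_duration,
            "adaptive_n": adaptive_n,
            "m": m,
            "min_history_years": min_history_years,
            "cities_per_country": cities_per_country,
            "start_year": start_year,
        },
    }
    corpus = SyntheticCorpus(
        series=series,
        demographics=demographics,
        events=events,
        features=feats,
        provenance=json.loads(json.dumps(provenance)),
    )
    realised = float(np.mean([e.lethal for e in events]))
    target = mech.target_prevalence
    if len(events) >= 5000 and not (0.5 * target <= realised <= 1.5 * target):
        raise RuntimeError(
            f"realised lethal prevalence {realised:.5f} outside ±50% of target {target}"
        )
    return corpus
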