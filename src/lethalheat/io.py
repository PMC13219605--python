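"""CSV round-tripping for the pipeline's tabular artifacts.

Schemas:
  series.csv        city_id, date (ISO-8601), tmax_c, rh_pct, wind_ms
                    (+ country_id, carried for convenience)
  demographics.csv  country_id, year, mean_bmi, sdi, p_00_04 … p_90_plus
  events.csv        event_id, city_id, country_id, start_date, end_date,
                    tmax_c, rh_mean_pct, wind_mean_ms, lethal, mechanism
  features.csv      event_id + 15 feature columns + lethal
"""

from __future__ import annotations

import re
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import (
    CitySeries,
    CountryDemographics,
    HeatwaveEvent,
    PopulationPyramid,
)

__all__ = [
    "write_series_csv",
    "read_series_csv",
    "write_demographics_csv",
    "read_demographics_csv",
    "write_events_csv",
    "read_events_csv",
    "events_to_frame",
    "series_from_grid",
]

_PYRAMID_COL = re.compile(r"^p_(\d{2})_(?:\d{2}|plus)$")


def write_series_csv(series: Mapping[str, CitySeries], path) -> None:
    frames = [series[cid].to_frame().assign(country_id=series[cid].country_id)
              for cid in sorted(series)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_series_csv(path) -> dict[str, CitySeries]:
    df = pd.read_csv(path, parse_dates=["date"])
    out: dict[str, CitySeries] = {}
    for cid, grp in df.groupby("city_id", sort=True):
        grp = grp.sort_values("date")
        out[str(cid)] = CitySeries(
            city_id=str(cid),
            country_id=str(grp["country_id"].iloc[0]) if "country_id" in grp else str(cid),
            dates=pd.DatetimeIndex(grp["date"]),
            tmax=grp["tmax_c"].to_numpy(float),
            rh=grp["rh_pct"].to_numpy(float),
            wind=grp["wind_ms"].to_numpy(float),
        )
    return out


def write_demographics_csv(
    demographics: Mapping[str, Sequence[CountryDemographics]], path
) -> None:
    from .synthetic_data import demographics_frame

    demographics_frame(demographics).to_csv(path, index=False)


def read_demographics_csv(path) -> dict[str, list[CountryDemographics]]:
    df = pd.read_csv(path)
    pcols = [c for c in df.columns if _PYRAMID_COL.match(c)]
    pcols.sort(key=lambda c: int(c.split("_")[1]))
    lower_bounds = np.array([int(c.split("_")[1]) for c in pcols], dtype=float)
    out: dict[str, list[CountryDemographics]] = {}
    for _, row in df.iterrows():
        props = row[pcols].to_numpy(dtype=float)
        props = props / props.sum()  # absorb CSV rounding
        rec = CountryDemographics(
            country_id=str(row["country_id"]),
            year=int(row["year"]),
            mean_bmi=float(row["mean_bmi"]),
            pyramid=PopulationPyramid(lower_bounds.copy(), props),
            sdi=float(row["sdi"]),
        )
        out.setdefault(rec.country_id, []).append(rec)
    for recs in out.values():
        recs.sort(key=lambda r: r.year)
    return out


def events_to_frame(events: Sequence[HeatwaveEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "city_id": [e.city_id for e in events],
            "country_id": [e.country_id for e in events],
            "start_date": [e.start_date.strftime("%Y-%m-%d") for e in events],
            "end_date": [e.end_date.strftime("%Y-%m-%d") for e in events],
            "tmax_c": [e.tmax for e in events],
            "rh_mean_pct": [e.rh_mean for e in events],
            "wind_mean_ms": [e.wind_mean for e in events],
            "lethal": [e.lethal for e in events],
            "mechanism": [e.mechanism for e in events],
        }
    )


def write_events_csv(events: Sequence[HeatwaveEvent], path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def series_from_grid(
    dataset,
    cities: pd.DataFrame,
    var_map: Mapping[str, str] | None = None,
) -> dict[str, CitySeries]:
    """Map a gridded weather cube to per-city daily series.

    ``dataset`` is an xarray Dataset with dims (time, lat, lon) and daily
    time steps; ``cities`` has columns city_id, country_id, lat, lon.
    Each city takes the nearest grid point. ``var_map`` renames dataset
    variables to the expected {"tmax", "rh", "wind"} (identity default).
    """
    var_map = dict(var_map or {})
    names = {k: var_map.get(k, k) for k in ("tmax", "rh", "wind")}
    missing = [v for v in names.values() if v not in dataset.data_vars]
    if missing:
        raise KeyError(f"gridded dataset lacks variable(s): {missing}")
    out: dict[str, CitySeries] = {}
    for _, row in cities.iterrows():
        point = dataset.sel(lat=row["lat"], lon=row["lon"], method="nearest")
        dates = pd.DatetimeIndex(point["time"].values)
        out[str(row["city_id"])] = CitySeries(
            city_id=str(row["city_id"]),
            country_id=str(row["country_id"]),
            dates=dates,
            tmax=np.asarray(point[names["tmax"]].values, dtype=float),
            rh=np.asarray(point[names["rh"]].values, dtype=float),
            wind=np.asarray(point[names["wind"]].values, dtype=float),
        )
    return out


def read_events_csv(path) -> list[HeatwaveEvent]:
    df = pd.read_csv(path)
    events = []
    for _, row in df.iterrows():
        lethal = row.get("lethal")
        mech = row.get("mechanism")
        events.append(
            HeatwaveEvent(
                event_id=str(row["event_id"]),
                city_id=str(row["city_id"]),
                country_id=str(row["country_id"]),
                start_date=pd.Timestamp(row["start_date"]),
                end_date=pd.Timestamp(row["end_date"]),
                tmax=float(row["tmax_c"]),
                rh_mean=float(row["rh_mean_pct"]),
                wind_mean=float(row["wind_mean_ms"]),
                lethal=None if pd.isna(lethal) else int(lethal),
                mechanism=None if (mech is None or pd.isna(mech)) else str(mech),
            )
        )
    return events
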