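"""Schema-validated readers and writers for the pipeline's file formats.

All tabular formats are CSV with ISO-8601 dates; rasters are NetCDF-style
regular grids (via xarray's scipy backend); grid-cell polygons are GeoJSON.
Write → read round trips are identity up to float formatting, and schema
violations report the offending column and row.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import pandas as pd
import xarray as xr

from .environment import EnvironmentFields
from .geolocation import PathEstimate
from .synthetic import TagRecordSet

__all__ = [
    "write_tag_records",
    "read_tag_records",
    "write_effort",
    "read_effort",
    "write_isotope_samples",
    "read_isotope_samples",
    "write_paths",
    "read_paths",
    "write_overlap_table",
    "read_overlap_table",
    "write_environment",
    "read_environment",
    "cells_to_geojson",
    "SchemaError",
]


class SchemaError(ValueError):
    """A file violates its documented schema (column and row reported)."""


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def _parse_dates(series: pd.Series, what: str, column: str) -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce", format="ISO8601")
    bad = parsed.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax())
        raise SchemaError(
            f"{what}: malformed date {series[row]!r} in column {column}, row {row}"
        )
    return parsed


TAG_RECORD_COLUMNS = [
    "id", "date", "sunrise_utc", "sunset_utc", "min_sst_c", "max_depth_m", "wet_fraction",
]


def write_tag_records(records: list[TagRecordSet], path: str | Path) -> Path:
    frames = []
    for rec in records:
        df = rec.data.copy()
        df.insert(0, "id", rec.individual_id)
        df.insert(1, "sex", rec.sex)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False)
    return Path(path)


def read_tag_records(path: str | Path) -> list[TagRecordSet]:
    df = pd.read_csv(path)
    _check_columns(df, TAG_RECORD_COLUMNS, "tag records")
    df["date"] = _parse_dates(df["date"], "tag records", "date").dt.date
    for col in ("sunrise_utc", "sunset_utc"):
        df[col] = _parse_dates(df[col], "tag records", col)
    if (df["wet_fraction"] < 0).any() or (df["wet_fraction"] > 1).any():
        row = int(((df["wet_fraction"] < 0) | (df["wet_fraction"] > 1)).idxmax())
        raise SchemaError(f"tag records: wet_fraction outside [0,1] at row {row}")
    out = []
    for tag, sub in df.groupby("id", sort=False):
        sex = str(sub["sex"].iloc[0]) if "sex" in sub else ""
        out.append(
            TagRecordSet(str(tag), sex, sub.drop(columns=["id", "sex"], errors="ignore").reset_index(drop=True))
        )
    return out


EFFORT_COLUMNS = ["fishery", "month", "lat_min", "lon_min", "hours"]


def write_effort(effort: pd.DataFrame, path: str | Path) -> Path:
    effort[EFFORT_COLUMNS].to_csv(path, index=False)
    return Path(path)


def read_effort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, EFFORT_COLUMNS, "effort")
    if (df["hours"] < 0).any():
        row = int((df["hours"] < 0).idxmax())
        raise SchemaError(f"effort: negative hours at row {row}")
    return df


ISOTOPE_COLUMNS = ["id", "sex", "d13C", "d15N", "C_N", "year"]


def write_isotope_samples(samples: pd.DataFrame, path: str | Path) -> Path:
    samples[ISOTOPE_COLUMNS].to_csv(path, index=False)
    return Path(path)


def read_isotope_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ISOTOPE_COLUMNS, "isotope samples")
    for col in ("d13C", "d15N"):
        bad = ~pd.to_numeric(df[col], errors="coerce").notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(f"isotope samples: non-numeric {col} at row {row}")
    return df


PATH_COLUMNS = ["id", "date", "lat", "lon", "dispersion_km"]


def write_paths(paths: list[tuple[str, PathEstimate]] | list[PathEstimate], path: str | Path) -> Path:
    frames = []
    for item in paths:
        sex, pe = item if isinstance(item, tuple) else ("", item)
        df = pe.data.copy()
        df.insert(0, "id", pe.individual_id)
        if sex:
            df.insert(1, "sex", sex)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def read_paths(path: str | Path) -> list[tuple[str, PathEstimate]]:
    df = pd.read_csv(path)
    _check_columns(df, [c for c in PATH_COLUMNS if c != "dispersion_km"], "paths")
    df["date"] = _parse_dates(df["date"], "paths", "date").dt.date
    out = []
    for tag, sub in df.groupby("id", sort=False):
        sex = str(sub["sex"].iloc[0]) if "sex" in sub.columns else ""
        cols = [c for c in ("date", "lat", "lon", "dispersion_km") if c in sub.columns]
        out.append((sex, PathEstimate(str(tag), sub[cols].reset_index(drop=True))))
    return out


def write_overlap_table(table: pd.DataFrame, path: str | Path) -> Path:
    table.to_csv(path, index=False)
    return Path(path)


def read_overlap_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["fishery", "sex", "month", "density", "score", "overlap", "interaction"], "overlap table")
    return df


def write_environment(env: EnvironmentFields, path: str | Path) -> Path:
    env.dataset.to_netcdf(path, engine="scipy")
    return Path(path)


def read_environment(path: str | Path) -> EnvironmentFields:
    with xr.open_dataset(path, engine="scipy") as ds:
        return EnvironmentFields(ds.load())


def cells_to_geojson(
    table: pd.DataFrame, path: str | Path, cell_size: float = 2.0
) -> Path:
    """Write each grid cell row as a GeoJSON polygon feature."""
    features = []
    for row in table.itertuples(index=False):
        lat0, lon0 = float(row.lat_min), float(row.lon_min)
        ring = [
            [lon0, lat0],
            [lon0 + cell_size, lat0],
            [lon0 + cell_size, lat0 + cell_size],
            [lon0, lat0 + cell_size],
            [lon0, lat0],
        ]
        props = {
            k: (v.item() if hasattr(v, "item") else v)
            for k, v in row._asdict().items()
        }
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload))
    return Path(path)
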