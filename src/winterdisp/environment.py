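"""Synthetic environmental rasters for the Patagonian Shelf.

Provides a monthly sea-surface-temperature climatology and a boolean land
mask on regular lat-lon grids (0.25°, emulating the resolution of optimally
interpolated satellite SST products), packaged for fast vectorized
nearest-cell sampling by the particle filter.

The land mask uses a deliberately coarse synthetic coastline polyline for the
Atlantic coast of Patagonia: land lies west of the polyline between 54.8°S
and 38°S, and everything south of 54.8°S (Beagle Channel / Drake Passage) is
sea.  It is a stand-in for a real coastline product, adequate because the
same mask is used to simulate and to estimate tracks.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import xarray as xr

__all__ = ["EnvironmentFields", "make_environment"]

# synthetic coastline polyline: (lat, easternmost land longitude)
_COAST_LAT = np.array(
    [-54.8, -54.0, -52.0, -50.0, -48.0, -46.0, -44.0, -42.0, -40.0, -38.0]
)
_COAST_LON = np.array(
    [-66.0, -65.3, -68.4, -68.3, -66.9, -67.3, -65.2, -63.5, -62.2, -58.0]
)


def _coast_lon_at(lat: np.ndarray) -> np.ndarray:
    return np.interp(lat, _COAST_LAT, _COAST_LON)


@dataclass
class EnvironmentFields:
    """Regular-grid SST and land rasters with nearest-cell samplers.

    ``dataset`` holds ``sst(month, lat, lon)`` in °C and ``land(lat, lon)``
    as 0/1; coordinates are cell centres of a regular grid.
    """

    dataset: xr.Dataset

    def __post_init__(self) -> None:
        lat = self.dataset["lat"].values
        lon = self.dataset["lon"].values
        self._lat0, self._dlat = float(lat[0]), float(lat[1] - lat[0])
        self._lon0, self._dlon = float(lon[0]), float(lon[1] - lon[0])
        self._nlat, self._nlon = lat.size, lon.size
        self._months = self.dataset["month"].values
        self._sst = self.dataset["sst"].values
        self._land = self.dataset["land"].values.astype(bool)

    def _indices(self, lats, lons):
        i = np.clip(
            np.rint((np.asarray(lats) - self._lat0) / self._dlat).astype(int),
            0,
            self._nlat - 1,
        )
        j = np.clip(
            np.rint((np.asarray(lons) - self._lon0) / self._dlon).astype(int),
            0,
            self._nlon - 1,
        )
        return i, j

    def is_land(self, lats, lons):
        """Boolean land flag for positions (nearest cell; outside grid → sea edge)."""
        i, j = self._indices(lats, lons)
        return self._land[i, j]

    def sample_sst(self, date: dt.date, lats, lons):
        """SST (°C) at positions for the month containing ``date``."""
        k = int(np.argmin(np.abs(self._months - date.month)))
        i, j = self._indices(lats, lons)
        return self._sst[k, i, j]

    def covers(self, lats, lons) -> bool:
        lats, lons = np.asarray(lats), np.asarray(lons)
        lat_hi = self._lat0 + self._dlat * (self._nlat - 1)
        lon_hi = self._lon0 + self._dlon * (self._nlon - 1)
        return bool(
            (lats >= self._lat0 - self._dlat).all()
            and (lats <= lat_hi + self._dlat).all()
            and (lons >= self._lon0 - self._dlon).all()
            and (lons <= lon_hi + self._dlon).all()
        )


def make_environment(
    lat_min: float = -60.0,
    lat_max: float = -38.0,
    lon_min: float = -75.0,
    lon_max: float = -45.0,
    resolution: float = 0.25,
    months: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9, 10),
) -> EnvironmentFields:
    """Build the synthetic SST climatology and land mask.

    SST is a smooth field with a strong meridional gradient (~0.55 °C per
    degree of latitude), a weak zonal term, and a seasonal cycle peaking in
    austral summer — enough structure for SST matching to constrain latitude
    without pretending to be a real ocean product.
    """
    lat = np.arange(lat_min, lat_max + resolution / 2, resolution)
    lon = np.arange(lon_min, lon_max + resolution / 2, resolution)
    month = np.asarray(months)

    glat, glon = np.meshgrid(lat, lon, indexing="ij")
    land = (
        (glat > -54.8) & (glat < -38.0 + 1e-9) & (glon < _coast_lon_at(glat))
    ).astype(np.int8)

    seasonal = 3.0 * np.cos(2 * np.pi * (month - 2) / 12.0)  # peak ~February
    base = 4.0 + 0.55 * (glat - lat_min) + 0.05 * (glon - lon_min)
    sst = seasonal[:, None, None] + base[None, :, :]

    ds = xr.Dataset(
        {
            "sst": (("month", "lat", "lon"), sst),
            "land": (("lat", "lon"), land),
        },
        coords={"month": month, "lat": lat, "lon": lon},
        attrs={"crs": "WGS-84 degrees", "note": "synthetic climatology"},
    )
    return EnvironmentFields(ds)
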