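"""Low-precision solar geometry for light-level geolocation.

Implements the NOAA general solar position equations (Spencer-style Fourier
series for declination and the equation of time), forward prediction of
sunrise/sunset times at an arbitrary solar elevation (calibration) angle, and
the inversion used by light-level geolocation: longitude from the timing of
local solar noon, latitude from day length.

All angles are decimal degrees, times UTC.  Solar parameters for a calendar
date are evaluated once at 12:00 UTC of that date; forward and inverse
computations share this convention so that a noise-free round trip is exact.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

__all__ = [
    "solar_declination",
    "equation_of_time",
    "day_length_hours",
    "twilight_times",
    "TwilightPair",
    "twilight_to_coords",
    "TwilightInversion",
    "NoSolutionError",
]

#: Default threshold on |d(day length)/d(latitude)| below which the latitude
#: solution is declared degenerate (minutes of day length per degree).
MIN_LATITUDE_SENSITIVITY = 2.0


class NoSolutionError(ValueError):
    """The observed day length is inconsistent with any latitude."""


def _solar_coords(date: dt.date) -> tuple[float, float]:
    """(declination deg, equation of time min) at 12:00 UTC of ``date``.

    Low-precision solar ephemeris: mean longitude and mean anomaly advanced
    from J2000, ecliptic longitude with the two leading equation-of-centre
    terms, declination through the obliquity.  Accurate to a few hundredths
    of a degree / a few seconds of time — well inside geolocator error
    scales.
    """
    n = (dt.datetime(date.year, date.month, date.day, 12) - _J2000).days
    l_mean = (280.460 + 0.9856474 * n) % 360.0
    g = np.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = np.radians(l_mean + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g))
    eps = np.radians(23.439 - 0.0000004 * n)
    decl = np.degrees(np.arcsin(np.sin(eps) * np.sin(lam)))
    alpha = np.degrees(np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))) % 360.0
    eqtime = 4.0 * ((l_mean - alpha + 180.0) % 360.0 - 180.0)
    return float(decl), float(eqtime)


_J2000 = dt.datetime(2000, 1, 1, 12)


def solar_declination(date: dt.date) -> float:
    """Solar declination (degrees) for a calendar date."""
    return _solar_coords(date)[0]


def equation_of_time(date: dt.date) -> float:
    """Equation of time (minutes; positive when the sun is ahead of clock)."""
    return _solar_coords(date)[1]


def _hour_angle_deg(lat: float, decl: float, elevation: float) -> float:
    """Half the day length, as an hour angle in degrees.

    Raises :class:`NoSolutionError` when the sun never reaches (polar night)
    or never drops below (polar day) the elevation threshold.
    """
    phi, delta, a = np.radians([lat, decl, elevation])
    cos_h = (np.sin(a) - np.sin(phi) * np.sin(delta)) / (np.cos(phi) * np.cos(delta))
    if cos_h > 1.0:
        raise NoSolutionError(f"sun never rises above {elevation}° at lat {lat}")
    if cos_h < -1.0:
        raise NoSolutionError(f"sun never sets below {elevation}° at lat {lat}")
    return float(np.degrees(np.arccos(cos_h)))


def day_length_hours(lat: float, date: dt.date, elevation: float) -> float:
    """Day length (hours) between crossings of the given solar elevation."""
    return 2.0 * _hour_angle_deg(lat, solar_declination(date), elevation) / 15.0


def twilight_times(
    lat: float, lon: float, date: dt.date, elevation: float
) -> tuple[dt.datetime, dt.datetime]:
    """Predicted UTC sunrise and sunset at the given solar elevation angle.

    ``lon`` is east-positive.  Returns timezone-naive UTC datetimes; the
    sunset may fall on the next calendar day at far-eastern longitudes.
    """
    ha = _hour_angle_deg(lat, solar_declination(date), elevation)
    eqt = equation_of_time(date)
    sunrise_min = 720.0 - 4.0 * (lon + ha) - eqt
    sunset_min = 720.0 - 4.0 * (lon - ha) - eqt
    base = dt.datetime(date.year, date.month, date.day)
    return (
        base + dt.timedelta(minutes=sunrise_min),
        base + dt.timedelta(minutes=sunset_min),
    )


@dataclass(frozen=True)
class TwilightPair:
    """One day's observed sunrise/sunset times from a geolocator."""

    date: dt.date
    sunrise_utc: dt.datetime
    sunset_utc: dt.datetime

    def __post_init__(self) -> None:
        if self.sunset_utc <= self.sunrise_utc:
            raise ValueError(
                f"{self.date}: sunset {self.sunset_utc} not after sunrise "
                f"{self.sunrise_utc}"
            )

    @property
    def day_length_hours(self) -> float:
        return (self.sunset_utc - self.sunrise_utc).total_seconds() / 3600.0

    @property
    def midpoint_utc(self) -> dt.datetime:
        return self.sunrise_utc + (self.sunset_utc - self.sunrise_utc) / 2


@dataclass(frozen=True)
class TwilightInversion:
    """Position recovered from one twilight pair.

    ``degenerate_latitude`` marks near-equinox days where day length barely
    depends on latitude; the longitude remains valid and ``lat`` holds the
    (unreliable) nominal solution.
    """

    lat: float
    lon: float
    degenerate_latitude: bool


def _wrap_lon(lon: float) -> float:
    """Wrap a longitude into (-180, 180]."""
    wrapped = -((-lon + 180.0) % 360.0 - 180.0)
    return 180.0 if wrapped == -180.0 else wrapped


def twilight_to_coords(
    pair: TwilightPair,
    solar_angle: float,
    *,
    hint_lat: float | None = None,
    min_sensitivity: float = MIN_LATITUDE_SENSITIVITY,
) -> TwilightInversion:
    """Invert a twilight pair to (lat, lon) at a given solar elevation angle.

    Longitude comes from the twilight midpoint (local solar noon): 15°/hour
    offset of solar noon from 12:00 UTC after removing the equation of time.
    Latitude solves the sunrise hour-angle equation
    ``cos H = (sin a - sin φ sin δ) / (cos φ cos δ)`` for φ given the observed
    day length ``2H`` and that date's solar declination δ.

    Parameters
    ----------
    pair : observed sunrise/sunset times (UTC).
    solar_angle : sun elevation defining twilight, degrees (|a| < 18).
    hint_lat : disambiguates when two latitudes solve the equation
        (choose the nearer); without a hint the southern solution is used.
    min_sensitivity : day-length sensitivity (minutes/degree) below which
        latitude is flagged degenerate.
    """
    if abs(solar_angle) >= 18.0:
        raise ValueError("solar angle must satisfy |a| < 18°")

    eqt = equation_of_time(pair.date)
    base = dt.datetime(pair.date.year, pair.date.month, pair.date.day)
    t_mid_min = (pair.midpoint_utc - base).total_seconds() / 60.0
    lon = _wrap_lon((720.0 - eqt - t_mid_min) / 4.0)

    decl = solar_declination(pair.date)
    h_deg = pair.day_length_hours * 15.0 / 2.0
    delta, a = np.radians([decl, solar_angle])
    h = np.radians(h_deg)

    # sin δ sin φ + (cos δ cos H) cos φ = sin a  →  k cos(φ − ψ) = sin a
    coef_cos = np.cos(delta) * np.cos(h)
    coef_sin = np.sin(delta)
    k = float(np.hypot(coef_cos, coef_sin))
    if abs(np.sin(a)) > k:
        raise NoSolutionError(
            f"{pair.date}: day length {pair.day_length_hours:.2f} h has no "
            f"latitude solution at solar angle {solar_angle}°"
        )
    psi = np.arctan2(coef_sin, coef_cos)
    offset = np.arccos(np.clip(np.sin(a) / k, -1.0, 1.0))
    candidates = [float(np.degrees(psi + offset)), float(np.degrees(psi - offset))]
    valid = [c for c in candidates if -89.9 <= c <= 89.9]
    if not valid:
        raise NoSolutionError(
            f"{pair.date}: latitude solution outside ±89.9° for day length "
            f"{pair.day_length_hours:.2f} h"
        )
    if hint_lat is not None:
        lat = min(valid, key=lambda c: abs(c - hint_lat))
    else:
        lat = min(valid)

    degenerate = _daylength_sensitivity(lat, decl, solar_angle) < min_sensitivity
    return TwilightInversion(lat=lat, lon=lon, degenerate_latitude=degenerate)


def _daylength_sensitivity(lat: float, decl: float, elevation: float) -> float:
    """|d(day length)/d(latitude)| in minutes per degree, by central difference."""
    dphi = 0.5
    try:
        phi, delta, a = np.radians([lat, decl, elevation])

        def daylen_min(p: float) -> float:
            cos_h = (np.sin(a) - np.sin(p) * np.sin(delta)) / (
                np.cos(p) * np.cos(delta)
            )
            return float(np.degrees(np.arccos(np.clip(cos_h, -1, 1)))) * 8.0

        lo = daylen_min(phi - np.radians(dphi))
        hi = daylen_min(phi + np.radians(dphi))
    except FloatingPointError:  # pragma: no cover
        return 0.0
    return abs(hi - lo) / (2.0 * dphi)
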