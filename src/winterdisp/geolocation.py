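"""Probabilistic light-level geolocation by iterative particle selection.

Reconstructs a daily most-probable path from twilight times.  For each day a
cloud of candidate positions is proposed by inverting the twilight pair over
a range of solar elevation angles; candidates are weighted by travel-speed
plausibility from the previous position (gamma density with a hard cap),
agreement between the tag's daily minimum SST and a satellite SST field
(Gaussian kernel), and land avoidance.  One candidate per day is kept per
forward pass; the passes are repeated ``n_iterations`` times and the final
path is the per-day geographic median of the retained points, with the median
great-circle distance to that point reported as dispersion.

Within a configurable window around the equinoxes, when day length carries no
latitude information, latitude proposals fall back to the speed-reachable
band around the previous position while longitude remains twilight-derived.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import solar
from .environment import EnvironmentFields
from .solar import NoSolutionError, TwilightPair, solar_declination, twilight_to_coords
from .sphere import geographic_median, haversine_km
from .synthetic import TagRecordSet

__all__ = [
    "GeolocationParams",
    "ParticleCloud",
    "PathEstimate",
    "TwilightPair",
    "twilight_to_coords",
    "solar_declination",
    "propose_particles",
    "weight_particles",
    "estimate_path",
    "detect_trip_window",
    "geographic_median",
    "AllParticlesOnLandError",
    "InconsistentEnvironmentError",
]


class AllParticlesOnLandError(RuntimeError):
    """Every proposal fell on land after the retry budget."""


class InconsistentEnvironmentError(RuntimeError):
    """All particle weights vanished (environment contradicts the track)."""


@dataclass(frozen=True)
class GeolocationParams:
    """Tuning parameters of the path estimator.

    ``solar_angle_range`` spans the plausible tag calibration angles (the
    true angle is unknown and may drift); ``speed_*`` parametrize the gamma
    travel-speed plausibility with a hard cap; ``sst_sd`` is the width of the
    SST agreement kernel; ``equinox_window_days`` disables day-length
    latitude within that many days of 20 March / 22 September.
    """

    n_particles: int = 2000
    n_iterations: int = 200
    solar_angle_range: tuple[float, float] = (-7.0, 0.0)
    speed_mean: float = 2.0  # km/h
    speed_sd: float = 1.0
    speed_max: float = 8.0
    sst_sd: float = 1.0  # °C
    equinox_window_days: int = 12
    lat_jitter_sd: float = 0.5  # degrees
    lon_jitter_sd: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_iterations < 1:
            raise ValueError("n_particles and n_iterations must be ≥ 1")
        if self.solar_angle_range[0] >= self.solar_angle_range[1]:
            raise ValueError("solar_angle_range must be (low, high) with low < high")
        if self.sst_sd <= 0:
            raise ValueError("sst_sd must be positive")


@dataclass
class ParticleCloud:
    """One day's candidate positions, optionally weighted (weights sum to 1)."""

    date: dt.date
    lats: np.ndarray
    lons: np.ndarray
    weights: np.ndarray | None = None

    def __len__(self) -> int:
        return self.lats.size

    @property
    def effective_sample_size(self) -> float:
        if self.weights is None:
            return float(len(self))
        return float(1.0 / np.sum(self.weights**2))


@dataclass
class PathEstimate:
    """Most-probable daily path with per-day dispersion diagnostics."""

    individual_id: str
    data: pd.DataFrame  # columns: date, lat, lon, dispersion_km
    iteration_paths: np.ndarray | None = None  # (n_iterations, n_days, 2)


_EQUINOXES = ((3, 20), (9, 22))


def _near_equinox(date: dt.date, window_days: int) -> bool:
    for month, day in _EQUINOXES:
        eq = dt.date(date.year, month, day)
        if abs((date - eq).days) <= window_days:
            return True
    return False


def _day_solar_terms(pair: TwilightPair) -> tuple[float, float, float]:
    """(declination deg, observed hour angle deg, twilight-midpoint longitude)."""
    decl = solar_declination(pair.date)
    h_deg = pair.day_length_hours * 15.0 / 2.0
    eqt = solar.equation_of_time(pair.date)
    base = dt.datetime(pair.date.year, pair.date.month, pair.date.day)
    t_mid_min = (pair.midpoint_utc - base).total_seconds() / 60.0
    lon = solar._wrap_lon((720.0 - eqt - t_mid_min) / 4.0)
    return decl, h_deg, lon


def _invert_latitudes(
    decl: float, h_deg: float, angles: np.ndarray, hint_lat: float
) -> np.ndarray:
    """Vectorized latitude solutions of the hour-angle equation.

    Angles with no solution yield NaN.  Where two latitudes solve the
    equation, the one nearer ``hint_lat`` is taken.
    """
    delta = np.radians(decl)
    h = np.radians(h_deg)
    a = np.radians(angles)
    coef_cos = np.cos(delta) * np.cos(h)
    coef_sin = np.sin(delta)
    k = np.hypot(coef_cos, coef_sin)
    ratio = np.sin(a) / k
    psi = np.arctan2(coef_sin, coef_cos)
    with np.errstate(invalid="ignore"):
        offset = np.arccos(np.clip(ratio, -1.0, 1.0))
        c1 = np.degrees(psi + offset)
        c2 = np.degrees(psi - offset)
    bad = np.abs(ratio) > 1.0
    in1 = (c1 >= -89.9) & (c1 <= 89.9) & ~bad
    in2 = (c2 >= -89.9) & (c2 <= 89.9) & ~bad
    pick1 = in1 & (~in2 | (np.abs(c1 - hint_lat) <= np.abs(c2 - hint_lat)))
    lat = np.where(pick1, c1, np.where(in2, c2, np.nan))
    return lat


def propose_particles(
    prev_cloud: ParticleCloud | None,
    pair: TwilightPair,
    params: GeolocationParams,
    rng: np.random.Generator,
    land_mask: EnvironmentFields | None = None,
    *,
    max_retries: int = 5,
) -> ParticleCloud:
    """Propose an unweighted candidate cloud for one day.

    Each candidate samples a solar angle uniformly from the configured range,
    inverts the twilight pair, and adds lat/lon jitter.  Within the equinox
    window (or when the inversion is degenerate) latitude is drawn uniformly
    from the band reachable from the previous position at the speed cap.
    """
    n = params.n_particles
    decl, h_deg, lon_mid = _day_solar_terms(pair)
    if prev_cloud is not None and len(prev_cloud) > 0:
        if prev_cloud.weights is not None and len(prev_cloud) > 1:
            idx = rng.choice(len(prev_cloud), size=n, p=prev_cloud.weights)
        else:
            idx = rng.integers(0, len(prev_cloud), size=n)
        ref_lats = prev_cloud.lats[idx]
    else:
        ref_lats = None

    sens = solar._daylength_sensitivity(
        ref_lats.mean() if ref_lats is not None else -50.0, decl, np.mean(params.solar_angle_range)
    )
    degenerate = (
        _near_equinox(pair.date, params.equinox_window_days)
        or sens < solar.MIN_LATITUDE_SENSITIVITY
    )

    for attempt in range(max_retries):
        widen = 1.0 + attempt  # spread further if everything landed ashore
        angles = rng.uniform(*params.solar_angle_range, size=n)
        hint = float(ref_lats.mean()) if ref_lats is not None else -50.0
        if degenerate:
            reach_deg = params.speed_max * 24.0 / 111.32
            base = ref_lats if ref_lats is not None else np.full(n, hint)
            lats = base + rng.uniform(-reach_deg, reach_deg, size=n)
        else:
            lats = _invert_latitudes(decl, h_deg, angles, hint)
            fallback = np.isnan(lats)
            if fallback.any():
                base = ref_lats if ref_lats is not None else np.full(n, hint)
                reach_deg = params.speed_max * 24.0 / 111.32
                lats = np.where(
                    fallback, base + rng.uniform(-reach_deg, reach_deg, size=n), lats
                )
        if attempt == 0:
            lat_jit, lon_jit = params.lat_jitter_sd, params.lon_jitter_sd
        else:  # spread wider once everything landed ashore
            lat_jit = widen * max(params.lat_jitter_sd, 0.2)
            lon_jit = widen * max(params.lon_jitter_sd, 0.2)
        lats = lats + rng.normal(0.0, lat_jit, size=n)
        lons = lon_mid + rng.normal(0.0, lon_jit, size=n)
        lats = np.clip(lats, -89.5, 89.5)

        if land_mask is None or not land_mask.is_land(lats, lons).all():
            return ParticleCloud(pair.date, lats, lons)
    raise AllParticlesOnLandError(
        f"{pair.date}: all {n} proposals on land after {max_retries} retries"
    )


def weight_particles(
    cloud: ParticleCloud,
    prev_location: tuple[float, float] | None,
    tag_min_sst: float,
    env: EnvironmentFields,
    params: GeolocationParams,
) -> ParticleCloud:
    """Weight a cloud by speed plausibility × SST agreement × land avoidance.

    Speed plausibility is a gamma density (moment-matched to the configured
    mean/sd) of the travel speed implied from ``prev_location`` over one day,
    zero beyond the hard cap; SST agreement is a Gaussian kernel of the
    tag−satellite temperature difference; particles on land get exactly zero.
    Weights are renormalized to sum to one.
    """
    if len(cloud) == 0:
        raise ValueError("cannot weight an empty cloud")
    w = np.ones(len(cloud))
    if prev_location is not None:
        dist = haversine_km(prev_location[0], prev_location[1], cloud.lats, cloud.lons)
        speed = dist / 24.0
        shape = (params.speed_mean / params.speed_sd) ** 2
        scale = params.speed_sd**2 / params.speed_mean
        w *= stats.gamma.pdf(speed, a=shape, scale=scale)
        w *= (speed <= params.speed_max).astype(float)
    if np.isfinite(tag_min_sst):
        sat = env.sample_sst(cloud.date, cloud.lats, cloud.lons)
        w *= np.exp(-0.5 * ((tag_min_sst - sat) / params.sst_sd) ** 2)
    w *= ~env.is_land(cloud.lats, cloud.lons)
    total = w.sum()
    if total <= 0.0:
        raise InconsistentEnvironmentError(
            f"{cloud.date}: all particle weights are zero"
        )
    return ParticleCloud(cloud.date, cloud.lats, cloud.lons, w / total)


def _twilight_pairs(records: TagRecordSet) -> list[TwilightPair | None]:
    pairs: list[TwilightPair | None] = []
    for row in records.data.itertuples():
        if pd.isna(row.sunrise_utc) or pd.isna(row.sunset_utc):
            pairs.append(None)
            continue
        date = row.date if isinstance(row.date, dt.date) else row.date.date()
        pairs.append(
            TwilightPair(date, row.sunrise_utc.to_pydatetime(), row.sunset_utc.to_pydatetime())
        )
    return pairs


def estimate_path(
    records: TagRecordSet,
    env: EnvironmentFields,
    params: GeolocationParams,
    *,
    keep_iteration_paths: bool = True,
) -> PathEstimate:
    """Estimate the most-probable daily path for one tag.

    Runs ``params.n_iterations`` seeded forward passes; each pass proposes
    ``params.n_particles`` candidates per day, weights them against the
    previous day's selected position and the environment (``env`` supplies
    both the SST field and the land mask), and keeps one weighted-sampled
    candidate.  The returned per-day location is the geographic median of the
    retained points and the dispersion the median great-circle distance from
    it.  Should the median itself fall in a land cell (possible near coasts),
    the nearest retained off-land point is reported instead.
    """
    pairs = _twilight_pairs(records)
    usable = [(i, p) for i, p in enumerate(pairs) if p is not None]
    if len(usable) < 2:
        raise ValueError("estimate_path requires at least 2 days with twilights")
    sst = records.data["min_sst_c"].to_numpy(dtype=float)

    n_days = len(usable)
    selected = np.empty((params.n_iterations, n_days, 2))
    root = np.random.SeedSequence(params.rng_seed)
    for it, seq in enumerate(root.spawn(params.n_iterations)):
        rng = np.random.default_rng(seq)
        prev: tuple[float, float] | None = None
        prev_cloud: ParticleCloud | None = None
        for d, (row_idx, pair) in enumerate(usable):
            cloud = None
            for _ in range(4):  # fresh proposals if every weight vanishes
                try:
                    cand = propose_particles(prev_cloud, pair, params, rng, env)
                    cloud = weight_particles(cand, prev, sst[row_idx], env, params)
                    break
                except InconsistentEnvironmentError:
                    continue
            if cloud is None:
                # tolerate a locally inconsistent day by widening the kernels,
                # then by dropping the speed constraint altogether
                relaxed = GeolocationParams(
                    **{
                        **params.__dict__,
                        "speed_max": params.speed_max * 2.0,
                        "sst_sd": params.sst_sd * 3.0,
                    }
                )
                cand = propose_particles(prev_cloud, pair, relaxed, rng, env)
                try:
                    cloud = weight_particles(cand, prev, sst[row_idx], env, relaxed)
                except InconsistentEnvironmentError:
                    cloud = weight_particles(cand, None, sst[row_idx], env, relaxed)
            j = rng.choice(len(cloud), p=cloud.weights)
            prev = (float(cloud.lats[j]), float(cloud.lons[j]))
            prev_cloud = ParticleCloud(
                pair.date, np.array([prev[0]]), np.array([prev[1]])
            )
            selected[it, d] = prev

    rows = []
    for d, (row_idx, pair) in enumerate(usable):
        pts = selected[:, d, :]
        med_lat, med_lon = geographic_median(pts[:, 0], pts[:, 1])
        if env.is_land(med_lat, med_lon):
            dist_all = haversine_km(med_lat, med_lon, pts[:, 0], pts[:, 1])
            k = int(np.argmin(dist_all))
            med_lat, med_lon = float(pts[k, 0]), float(pts[k, 1])
        disp = float(np.median(haversine_km(med_lat, med_lon, pts[:, 0], pts[:, 1])))
        rows.append((pair.date, med_lat, med_lon, disp))

    data = pd.DataFrame(rows, columns=["date", "lat", "lon", "dispersion_km"])
    return PathEstimate(
        records.individual_id,
        data,
        iteration_paths=selected if keep_iteration_paths else None,
    )


def detect_trip_window(
    records: TagRecordSet,
    *,
    wet_threshold: float = 0.5,
    dry_threshold: float = 0.5,
    sustained_days: int = 2,
) -> tuple[dt.date, dt.date]:
    """Departure/arrival dates from the wet/dry record.

    Departure is the first date whose wet fraction stays ≥ ``wet_threshold``
    for ``sustained_days`` consecutive days (the tag is continuously
    submerged once at sea); arrival is the first later date whose dry
    fraction stays ≥ ``dry_threshold`` equally long.
    """
    df = records.data
    wet = df["wet_fraction"].to_numpy(dtype=float)
    dates = [d if isinstance(d, dt.date) else d.date() for d in df["date"]]
    k = sustained_days

    def first_sustained(mask: np.ndarray, start: int) -> int | None:
        for i in range(start, len(mask) - k + 1):
            if mask[i : i + k].all():
                return i
        return None

    dep = first_sustained(wet >= wet_threshold, 0)
    if dep is None:
        raise ValueError("no departure found: wet threshold never sustained")
    arr = first_sustained((1.0 - wet) >= dry_threshold, dep + 1)
    if arr is None:
        raise ValueError("no arrival found: dry threshold never sustained after departure")
    return dates[dep], dates[arr]
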