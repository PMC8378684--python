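"""Ground-truthed synthetic data for every pipeline stage.

Emulates a winter-dispersal geolocator study on the Patagonian Shelf:
sex-structured movement tracks (biased random walks toward monthly latitude
bands), daily tag records derived from the true tracks (twilight times, daily
minimum SST, maximum dive depth, wet/dry fraction), clustered monthly fishing
effort fields at 0.5°, and blood isotope values drawn from a two-baseline
mixing model with known trophic positions.

Everything is driven by a single :class:`SimulationConfig`; identical config
plus seed yields bit-identical outputs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference, solar
from .environment import EnvironmentFields, _coast_lon_at, make_environment
from .reference import TDF, Baseline
from .sphere import destination_point, haversine_km

__all__ = [
    "SimulationConfig",
    "IsotopeTruth",
    "FisherySpec",
    "TrueTrack",
    "TagRecordSet",
    "simulate_tracks",
    "simulate_tag_records",
    "simulate_fishing_effort",
    "simulate_blood_isotopes",
    "simulate_dataset",
    "DEFAULT_LATITUDE_CENTERS",
    "DEFAULT_FISHERIES",
]

KM_PER_DEG_LAT = 111.32

#: Monthly target latitudes by sex, tracing the observed seasonal bands:
#: females push furthest north in June, males stay ~4° south of them in
#: mid-winter, both converge south again before returning to the colony.
DEFAULT_LATITUDE_CENTERS: dict[str, dict[int, float]] = {
    "female": {4: -54.0, 5: -49.0, 6: -43.0, 7: -45.0, 8: -45.0, 9: -51.0},
    "male": {4: -54.0, 5: -53.0, 6: -47.0, 7: -47.0, 8: -47.0, 9: -49.0},
}


@dataclass(frozen=True)
class IsotopeTruth:
    """Known mixing-model truths for the blood-isotope generator."""

    tp_female: float = 4.8
    alpha_female: float = 0.5
    tp_male: float = 5.4
    alpha_male: float = 1.0
    d15n_resid_sd: float = 0.4
    d13c_resid_sd: float = 0.4

    def for_sex(self, sex: str) -> tuple[float, float]:
        if sex == "female":
            return self.tp_female, self.alpha_female
        return self.tp_male, self.alpha_male


@dataclass(frozen=True)
class FisherySpec:
    """A fishery's spatial footprint for the effort generator.

    ``hotspots`` are (lat_min, lat_max, lon_min, lon_max, mean_hours) boxes;
    within each box the mean is further amplified toward the box centre so a
    few core cells reach the top effort bin.  Cells outside ``lat_extent`` /
    ``lon_extent`` carry exactly zero hours.
    """

    name: str
    lat_extent: tuple[float, float]
    lon_extent: tuple[float, float]
    hotspots: tuple[tuple[float, float, float, float, float], ...]
    background_mean_hours: float = 25.0


DEFAULT_FISHERIES: tuple[FisherySpec, ...] = (
    FisherySpec(
        name="trawl",
        lat_extent=(-56.0, -38.0),
        lon_extent=(-69.0, -55.0),
        hotspots=(
            (-45.0, -40.0, -65.0, -58.0, 1800.0),
            (-52.0, -50.0, -69.0, -64.0, 900.0),
            (-50.0, -45.0, -68.0, -60.0, 700.0),
        ),
    ),
    FisherySpec(
        name="shrimp",
        lat_extent=(-50.0, -43.0),
        lon_extent=(-67.0, -60.0),
        hotspots=((-50.0, -45.0, -67.0, -61.0, 1500.0),),
    ),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic winter-dispersal dataset.

    Defaults reproduce the scale of the 2017 Martillo Island season: 5 female
    and 4 male recovered track datasets (13 + 11 blood samples), an
    April–September dispersal over the shelf, travel speed of a swimming
    penguin (km/h), and tag noise at the scale of light-level geolocators.
    """

    n_females: int = 5
    n_males: int = 4
    n_blood_females: int = 13
    n_blood_males: int = 11
    start_date: dt.date = dt.date(2017, 4, 1)
    end_date: dt.date = dt.date(2017, 9, 25)
    colony_lat: float = reference.COLONY_LAT
    colony_lon: float = reference.COLONY_LON
    speed_mean: float = 2.0  # km/h sustained
    speed_sd: float = 0.7
    speed_max: float = 8.0
    heading_noise_sd: float = 25.0  # degrees
    offshore_offset_deg: float = 3.5  # corridor distance east of the coastline
    sex_monthly_latitude_centers: dict[str, dict[int, float]] = field(
        default_factory=lambda: DEFAULT_LATITUDE_CENTERS
    )
    solar_angle: float = -3.44  # tag twilight calibration elevation, degrees
    twilight_noise_sd: float = 3.0  # minutes
    sst_noise_sd: float = 0.3  # °C
    depth_median_female: float = 44.3  # m
    depth_median_male: float = 57.1  # m
    depth_log_sd: float = 0.35
    isotope_truth: IsotopeTruth = field(default_factory=IsotopeTruth)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_females < 0 or self.n_males < 0:
            raise ValueError("individual counts must be non-negative")
        if self.start_date >= self.end_date:
            raise ValueError("start_date must precede end_date")
        if self.speed_mean <= 0 or self.speed_sd < 0 or self.speed_max <= 0:
            raise ValueError("speed parameters must be positive (sd may be zero)")
        if self.twilight_noise_sd < 0 or self.sst_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    def rng(self, *spawn_key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.rng_seed, spawn_key=spawn_key)
        )


@dataclass(frozen=True)
class TrueTrack:
    """Ground-truth daily positions for one individual."""

    individual_id: str
    sex: str
    positions: pd.DataFrame  # columns: date, lat, lon (one row per day)
    departure_date: dt.date
    arrival_date: dt.date


@dataclass(frozen=True)
class TagRecordSet:
    """One tag's daily records.

    ``data`` columns: date, sunrise_utc, sunset_utc, min_sst_c, max_depth_m,
    wet_fraction; twilight columns are NaT on days the tag could not resolve
    twilight.
    """

    individual_id: str
    sex: str
    data: pd.DataFrame


def _present_day(baseline: Baseline, year: int) -> Baseline:
    """Baseline with its δ13C shifted by the Suess decline to ``year``."""
    shifted = baseline.d13c_mean - 0.022 * (year - baseline.sampling_year)
    return Baseline(
        baseline.name, baseline.d15n_mean, baseline.d15n_sd,
        shifted, baseline.d13c_sd, year,
    )


class InfeasibleCentersError(ValueError):
    """Monthly latitude targets unreachable at the configured speed cap."""


def _check_reachability(config: SimulationConfig) -> None:
    max_month_km = config.speed_max * 24.0 * 28.0
    for sex, centers in config.sex_monthly_latitude_centers.items():
        months = sorted(centers)
        for m0, m1 in zip(months, months[1:]):
            gap_km = abs(centers[m1] - centers[m0]) * KM_PER_DEG_LAT
            if gap_km > max_month_km:
                raise InfeasibleCentersError(
                    f"{sex}: month {m1} center {centers[m1]}° is {gap_km:.0f} km "
                    f"from month {m0} center, beyond the {max_month_km:.0f} km "
                    "reachable in a month at the speed cap"
                )


def _bearing_deg(lat1, lon1, lat2, lon2) -> float:
    p1, l1, p2, l2 = np.radians([lat1, lon1, lat2, lon2])
    y = np.sin(l2 - l1) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(l2 - l1)
    return float(np.degrees(np.arctan2(y, x)))


def _target_for(config: SimulationConfig, sex: str, month: int) -> tuple[float, float]:
    centers = config.sex_monthly_latitude_centers[sex]
    month_key = min(centers, key=lambda m: abs(m - month))
    lat = centers[month_key]
    lon = float(_coast_lon_at(np.asarray(lat))) + config.offshore_offset_deg
    return lat, lon


def _simulate_one_track(
    config: SimulationConfig,
    env: EnvironmentFields,
    individual_id: str,
    sex: str,
    rng: np.random.Generator,
) -> TrueTrack:
    departure = config.start_date + dt.timedelta(days=int(rng.integers(0, 7)))
    # arrive ≥ 2 days before recording ends: devices are recovered a few
    # days after the bird returns, so the tail of the record is dry
    arrival = config.end_date - dt.timedelta(days=int(rng.integers(2, 8)))
    n_days = (arrival - departure).days + 1
    mean_day_km = config.speed_mean * 24.0
    max_day_km = config.speed_max * 24.0

    lat, lon = config.colony_lat, config.colony_lon
    rows = [(departure, lat, lon)]
    for k in range(1, n_days):
        date = departure + dt.timedelta(days=k)
        days_left = (arrival - date).days
        dist_home = float(haversine_km(lat, lon, config.colony_lat, config.colony_lon))

        homing = dist_home >= max(days_left - 1, 0) * mean_day_km * 0.8
        if days_left == 0:
            # last day: arrive exactly (guaranteed reachable by the homing leg)
            rows.append((date, config.colony_lat, config.colony_lon))
            lat, lon = config.colony_lat, config.colony_lon
            continue
        if homing:
            t_lat, t_lon = config.colony_lat, config.colony_lon
            pace = min(max_day_km * 0.95, max(dist_home / max(days_left, 1), 1.0) * 1.3)
            step = float(np.clip(rng.normal(pace, config.speed_sd * 24.0), 0.0, max_day_km))
        else:
            t_lat, t_lon = _target_for(config, sex, date.month)
            step = float(
                np.clip(
                    rng.normal(mean_day_km, config.speed_sd * 24.0), 0.0, max_day_km
                )
            )
        dist_target = float(haversine_km(lat, lon, t_lat, t_lon))
        step = min(step, max(dist_target, 5.0))
        base_bearing = _bearing_deg(lat, lon, t_lat, t_lon)

        placed = False
        for _ in range(60):
            bearing = base_bearing + rng.normal(0.0, config.heading_noise_sd)
            cand_lat, cand_lon = destination_point(lat, lon, bearing, step)
            if (
                not env.is_land(cand_lat, cand_lon)
                and -59.5 < cand_lat < -38.5
                and -74.0 < cand_lon < -46.0
            ):
                lat, lon = float(cand_lat), float(cand_lon)
                placed = True
                break
        if not placed:  # back off due east into open water
            cand_lat, cand_lon = destination_point(lat, lon, 90.0, step)
            lat, lon = float(cand_lat), float(cand_lon)
        rows.append((date, lat, lon))

    positions = pd.DataFrame(rows, columns=["date", "lat", "lon"])
    return TrueTrack(individual_id, sex, positions, departure, arrival)


def simulate_tracks(
    config: SimulationConfig, env: EnvironmentFields | None = None
) -> list[TrueTrack]:
    """Simulate one ground-truth track per configured individual."""
    _check_reachability(config)
    if env is None:
        env = make_environment()
    tracks: list[TrueTrack] = []
    idx = 0
    for sex, n in (("female", config.n_females), ("male", config.n_males)):
        for i in range(n):
            tag = f"{'F' if sex == 'female' else 'M'}{i + 1:02d}"
            tracks.append(
                _simulate_one_track(config, env, tag, sex, config.rng(1, idx))
            )
            idx += 1
    return tracks


def simulate_tag_records(
    track: TrueTrack,
    env: EnvironmentFields,
    config: SimulationConfig,
    *,
    recording_start: dt.date | None = None,
    recording_end: dt.date | None = None,
) -> TagRecordSet:
    """Derive one tag's daily records from its true track.

    Twilight times are computed from the true position by solar geometry at
    the configured calibration angle plus Gaussian timing noise; min SST is
    the satellite field at the true position plus noise; wet fraction is 1
    while at sea and near 0 at the colony; daily maximum dive depth is drawn
    from the sex-specific lognormal.  Days with undefined twilight (polar
    light regimes) are flagged missing, never fabricated.
    """
    rng = config.rng(2, int(track.individual_id[1:]) + (0 if track.sex == "female" else 100))
    start = recording_start or config.start_date
    end = recording_end or config.end_date
    if not env.covers(track.positions["lat"].values, track.positions["lon"].values):
        raise ValueError("SST field does not cover the track's bounding box")

    pos = track.positions.set_index("date")
    median_depth = (
        config.depth_median_female if track.sex == "female" else config.depth_median_male
    )
    rows = []
    for k in range((end - start).days + 1):
        date = start + dt.timedelta(days=k)
        at_sea = track.departure_date <= date < track.arrival_date
        if date in pos.index:
            lat, lon = float(pos.loc[date, "lat"]), float(pos.loc[date, "lon"])
        else:
            lat, lon = config.colony_lat, config.colony_lon
        try:
            sunrise, sunset = solar.twilight_times(lat, lon, date, config.solar_angle)
            noise = rng.normal(0.0, config.twilight_noise_sd, size=2)
            sunrise += dt.timedelta(minutes=float(noise[0]))
            sunset += dt.timedelta(minutes=float(noise[1]))
        except solar.NoSolutionError:
            sunrise = sunset = pd.NaT
            rng.normal(0.0, 1.0, size=2)  # keep the stream aligned
        sst = float(env.sample_sst(date, lat, lon)) + rng.normal(0.0, config.sst_noise_sd)
        depth = float(rng.lognormal(np.log(median_depth), config.depth_log_sd))
        wet = 1.0 if at_sea else float(np.clip(rng.normal(0.06, 0.02), 0.0, 0.2))
        rows.append((date, sunrise, sunset, sst, depth if at_sea else 0.0, wet))

    data = pd.DataFrame(
        rows,
        columns=["date", "sunrise_utc", "sunset_utc", "min_sst_c", "max_depth_m", "wet_fraction"],
    )
    return TagRecordSet(track.individual_id, track.sex, data)


def simulate_fishing_effort(
    config: SimulationConfig,
    fisheries: tuple[FisherySpec, ...] = DEFAULT_FISHERIES,
    *,
    months: tuple[int, ...] = (4, 5, 6, 7, 8, 9),
    cell_size: float = 0.5,
    lat_range: tuple[float, float] = (-60.0, -38.0),
    lon_range: tuple[float, float] = (-75.0, -55.0),
) -> pd.DataFrame:
    """Monthly gridded fishing hours at 0.5° for each configured fishery.

    Returns a long-format frame (fishery, month, lat_min, lon_min, hours);
    only cells inside the fishery's extent may carry nonzero hours.
    """
    if any(m < min(4, config.start_date.month) or m > 12 for m in months):
        raise ValueError("months must be calendar months within the season")
    rng = config.rng(3)
    lat_edges = np.arange(lat_range[0], lat_range[1], cell_size)
    lon_edges = np.arange(lon_range[0], lon_range[1], cell_size)
    glat, glon = np.meshgrid(lat_edges, lon_edges, indexing="ij")
    clat, clon = glat + cell_size / 2, glon + cell_size / 2

    frames = []
    for spec in fisheries:
        inside = (
            (clat >= spec.lat_extent[0])
            & (clat <= spec.lat_extent[1])
            & (clon >= spec.lon_extent[0])
            & (clon <= spec.lon_extent[1])
        )
        for month in months:
            mean = np.where(inside, spec.background_mean_hours, 0.0)
            for la0, la1, lo0, lo1, hot_mean in spec.hotspots:
                in_box = (clat >= la0) & (clat <= la1) & (clon >= lo0) & (clon <= lo1)
                c_lat, c_lon = (la0 + la1) / 2, (lo0 + lo1) / 2
                bump = np.exp(
                    -(((clat - c_lat) / max(la1 - la0, 1e-9)) ** 2)
                    - ((clon - c_lon) / max(lo1 - lo0, 1e-9)) ** 2
                )
                mean = np.where(in_box & inside, hot_mean * (1.0 + 4.0 * bump), mean)
            shape = 1.5
            hours = np.where(
                mean > 0, rng.gamma(shape, np.maximum(mean, 1e-12) / shape), 0.0
            )
            frames.append(
                pd.DataFrame(
                    {
                        "fishery": spec.name,
                        "month": month,
                        "lat_min": glat.ravel(),
                        "lon_min": glon.ravel(),
                        "hours": hours.ravel(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def simulate_blood_isotopes(
    config: SimulationConfig,
    baselines_by_sex: dict[str, tuple[Baseline, Baseline]] | None = None,
    tdf: TDF = reference.DEFAULT_TDF,
    sampling_year: int = 2017,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blood δ13C/δ15N samples from the two-baseline mixing model.

    Expected consumer values: ``δ15N = α·b1 + (1−α)·b2 + ΔN·(TP−2)`` and the
    analogous δ13C relation, plus per-sex residual noise.  The true mixing
    endpoints are the baselines' present-day values (their δ13C means
    Suess-shifted from the baseline sampling year to ``sampling_year``),
    since the blood reflects the contemporary food web.  By default females
    mix the Southern Patagonia and Bahía Franklin baselines while males (α=1)
    sit on the Northern Patagonia baseline, matching the sexes' last-month
    foraging areas.  Returns ``(samples, truth)`` frames; ``truth`` records
    each individual's TP and α.
    """
    if baselines_by_sex is None:
        baselines_by_sex = {
            "female": (reference.SOUTHERN_PATAGONIA, reference.BAHIA_FRANKLIN),
            "male": (reference.NORTHERN_PATAGONIA, reference.NORTHERN_PATAGONIA),
        }
    truth = config.isotope_truth
    for sex in ("female", "male"):
        _, alpha = truth.for_sex(sex)
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha for {sex} must lie in [0, 1], got {alpha}")
    rng = config.rng(4)
    rows, truth_rows = [], []
    for sex, n in (("female", config.n_blood_females), ("male", config.n_blood_males)):
        tp, alpha = truth.for_sex(sex)
        raw_1, raw_2 = baselines_by_sex[sex]
        baseline_1 = _present_day(raw_1, sampling_year)
        baseline_2 = _present_day(raw_2, sampling_year)
        for i in range(n):
            exp_n = (
                alpha * baseline_1.d15n_mean
                + (1 - alpha) * baseline_2.d15n_mean
                + tdf.d15n_mean * (tp - 2.0)
            )
            exp_c = (
                alpha * baseline_1.d13c_mean
                + (1 - alpha) * baseline_2.d13c_mean
                + tdf.d13c_mean * (tp - 2.0)
            )
            d15n = exp_n + rng.normal(0.0, truth.d15n_resid_sd)
            d13c = exp_c + rng.normal(0.0, truth.d13c_resid_sd)
            tag = f"B{'F' if sex == 'female' else 'M'}{i + 1:02d}"
            rows.append((tag, sex, d13c, d15n, 3.25, sampling_year))
            truth_rows.append((tag, sex, tp, alpha, exp_c, exp_n))
    samples = pd.DataFrame(
        rows, columns=["id", "sex", "d13C", "d15N", "C_N", "year"]
    )
    truth_df = pd.DataFrame(
        truth_rows, columns=["id", "sex", "tp", "alpha", "expected_d13C", "expected_d15N"]
    )
    return samples, truth_df


def simulate_dataset(config: SimulationConfig) -> dict:
    """Run every generator; returns env, tracks, tag records, effort, isotopes."""
    env = make_environment()
    tracks = simulate_tracks(config, env)
    records = [simulate_tag_records(t, env, config) for t in tracks]
    effort = simulate_fishing_effort(config)
    samples, truth = simulate_blood_isotopes(config)
    return {
        "environment": env,
        "tracks": tracks,
        "tag_records": records,
        "effort": effort,
        "isotope_samples": samples,
        "isotope_truth": truth,
    }


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: the same study conditions under a different seed."""
    return replace(config, rng_seed=seed)
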