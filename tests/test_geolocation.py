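"""Particle-filter geolocation: proposals, weighting, path estimation."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from winterdisp import solar
from winterdisp.geolocation import (
    GeolocationParams,
    ParticleCloud,
    detect_trip_window,
    estimate_path,
    propose_particles,
    weight_particles,
)
from winterdisp.sphere import haversine_km
from winterdisp.synthetic import SimulationConfig, TagRecordSet, simulate_tag_records, simulate_tracks

EQUINOXES = (dt.date(2017, 3, 20), dt.date(2017, 9, 22))


def days_off_equinox(dates, window=12):
    return np.array(
        [all(abs((d - eq).days) > window for eq in EQUINOXES) for d in dates]
    )


def make_pair(lat, lon, date, angle):
    sr, ss = solar.twilight_times(lat, lon, date, angle)
    return solar.TwilightPair(date, sr, ss)


class TestProposals:
    def test_count_matches_params(self, env):
        pair = make_pair(-50.0, -63.0, dt.date(2017, 6, 15), -3.44)
        params = GeolocationParams(n_particles=257, rng_seed=0)
        cloud = propose_particles(None, pair, params, np.random.default_rng(0), env)
        assert len(cloud) == 257

    def test_collapses_to_twilight_inversion(self, env):
        """One particle, no jitter, pinned solar angle → the inversion point."""
        date, angle = dt.date(2017, 6, 15), -3.44
        pair = make_pair(-50.0, -63.0, date, angle)
        params = GeolocationParams(
            n_particles=1,
            solar_angle_range=(angle - 1e-9, angle + 1e-9),
            lat_jitter_sd=0.0,
            lon_jitter_sd=0.0,
        )
        prev = ParticleCloud(date, np.array([-50.5]), np.array([-63.0]))
        cloud = propose_particles(prev, pair, params, np.random.default_rng(1), env)
        inv = solar.twilight_to_coords(pair, angle, hint_lat=-50.5)
        assert cloud.lats[0] == pytest.approx(inv.lat, abs=1e-5)
        assert cloud.lons[0] == pytest.approx(inv.lon, abs=1e-5)

    def test_equinox_proposals_stay_within_reach(self, env):
        date = dt.date(2017, 9, 22)
        pair = make_pair(-50.0, -63.0, date, -3.44)
        params = GeolocationParams(n_particles=500, lat_jitter_sd=0.0, rng_seed=0)
        prev = ParticleCloud(date, np.array([-50.0]), np.array([-63.0]))
        cloud = propose_particles(prev, pair, params, np.random.default_rng(2), env)
        reach_deg = params.speed_max * 24.0 / 111.32
        assert np.abs(cloud.lats - -50.0).max() <= reach_deg + 1e-9


class TestWeighting:
    def test_land_particles_get_zero_weight(self, env):
        date = dt.date(2017, 6, 15)
        cloud = ParticleCloud(
            date,
            lats=np.array([-50.0, -50.0]),
            lons=np.array([-70.0, -63.0]),  # first is inland Patagonia
        )
        assert env.is_land(-50.0, -70.0)
        sst = float(env.sample_sst(date, -50.0, -63.0))
        params = GeolocationParams()
        weighted = weight_particles(cloud, None, sst, env, params)
        assert weighted.weights[0] == 0.0
        assert weighted.weights[1] == pytest.approx(1.0)

    def test_symmetric_particles_equal_weights(self, env):
        date = dt.date(2017, 6, 15)
        prev = (-50.0, -63.0)
        cloud = ParticleCloud(
            date, lats=np.array([-49.5, -50.5]), lons=np.array([-63.0, -63.0])
        )
        sst_vals = env.sample_sst(date, cloud.lats, cloud.lons)
        tag_sst = float(sst_vals.mean())  # equidistant in SST space too
        weighted = weight_particles(cloud, prev, tag_sst, env, GeolocationParams())
        assert weighted.weights[0] == pytest.approx(weighted.weights[1], rel=1e-6)

    def test_weights_match_hand_computed_product(self, env):
        """Five-particle weights equal speed-gamma × SST-kernel × sea factor."""
        date = dt.date(2017, 7, 1)
        prev = (-50.0, -63.0)
        params = GeolocationParams(speed_mean=2.0, speed_sd=1.0, sst_sd=1.0)
        lats = np.array([-49.6, -50.2, -50.9, -50.0, -48.5])
        lons = np.array([-63.1, -62.7, -63.4, -70.0, -63.0])
        cloud = ParticleCloud(date, lats, lons)
        tag_sst = float(env.sample_sst(date, -50.0, -63.0))
        weighted = weight_particles(cloud, prev, tag_sst, env, params)

        speeds = haversine_km(prev[0], prev[1], lats, lons) / 24.0
        shape, scale = (2.0 / 1.0) ** 2, 1.0**2 / 2.0
        expected = stats.gamma.pdf(speeds, a=shape, scale=scale)
        expected *= (speeds <= params.speed_max).astype(float)
        expected *= np.exp(
            -0.5 * ((tag_sst - env.sample_sst(date, lats, lons)) / 1.0) ** 2
        )
        expected *= ~env.is_land(lats, lons)
        expected /= expected.sum()
        np.testing.assert_allclose(weighted.weights, expected, rtol=1e-12)

    def test_weights_always_normalized(self, env):
        rng = np.random.default_rng(5)
        date = dt.date(2017, 8, 10)
        for _ in range(5):
            cloud = ParticleCloud(
                date,
                lats=rng.uniform(-54, -44, 100),
                lons=rng.uniform(-64, -58, 100),
            )
            weighted = weight_particles(
                cloud, (-50.0, -62.0), 8.0, env, GeolocationParams()
            )
            assert weighted.weights.sum() == pytest.approx(1.0, abs=1e-9)
            assert (weighted.weights >= 0).all()


SMALL = dict(n_particles=300, n_iterations=15)


class TestEstimatePath:
    def test_zero_noise_recovery(self, env, noise_free_track_and_records):
        """With noise-free tags and the true calibration angle bracketed,
        the path is recovered to a fraction of a degree off-equinox."""
        cfg, track, records = noise_free_track_and_records
        params = GeolocationParams(
            **SMALL, solar_angle_range=(-3.6, -3.3), lat_jitter_sd=0.2, rng_seed=3
        )
        pe = estimate_path(records, env, params, keep_iteration_paths=False)
        m = pe.data.merge(track.positions, on="date", suffixes=("_e", "_t"))
        off = days_off_equinox(list(m["date"]))
        lat_err_deg = np.abs(m["lat_e"] - m["lat_t"])[off]
        lon_err_deg = np.abs(m["lon_e"] - m["lon_t"])[off]
        assert np.median(lat_err_deg) < 0.5
        assert np.median(lon_err_deg) < 0.2

    def test_no_path_point_on_land(self, env, track_and_records):
        _, records = track_and_records
        params = GeolocationParams(**SMALL, rng_seed=4)
        pe = estimate_path(records, env, params)
        assert not env.is_land(pe.data["lat"].values, pe.data["lon"].values).any()
        n_it, n_days, _ = pe.iteration_paths.shape
        flat = pe.iteration_paths.reshape(-1, 2)
        assert not env.is_land(flat[:, 0], flat[:, 1]).any()

    def test_seeded_determinism(self, env, track_and_records):
        _, records = track_and_records
        params = GeolocationParams(n_particles=100, n_iterations=5, rng_seed=9)
        a = estimate_path(records, env, params)
        b = estimate_path(records, env, params)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_accuracy_monotone_in_twilight_noise(self, env):
        """Median latitude error does not decrease as twilight noise grows."""
        errs = []
        params = GeolocationParams(
            **SMALL, solar_angle_range=(-3.7, -3.2), lat_jitter_sd=0.2, rng_seed=3
        )
        for noise in (0.0, 3.0, 8.0):
            cfg = SimulationConfig(twilight_noise_sd=noise)
            track = simulate_tracks(cfg, env)[0]
            records = simulate_tag_records(track, env, cfg)
            pe = estimate_path(records, env, params, keep_iteration_paths=False)
            m = pe.data.merge(track.positions, on="date", suffixes=("_e", "_t"))
            off = days_off_equinox(list(m["date"]))
            errs.append(
                float(
                    np.median(
                        haversine_km(m["lat_e"], m["lon_e"], m["lat_t"], m["lon_e"])[off]
                    )
                )
            )
        assert errs[0] <= errs[1] <= errs[2]

    def test_equinox_dispersion_exceeds_off_equinox(self, env):
        cfg = SimulationConfig(twilight_noise_sd=2.0)
        track = simulate_tracks(cfg, env)[0]
        records = simulate_tag_records(track, env, cfg)
        params = GeolocationParams(
            **SMALL, solar_angle_range=(-3.7, -3.2), lat_jitter_sd=0.2, rng_seed=3
        )
        pe = estimate_path(records, env, params, keep_iteration_paths=False)
        off = days_off_equinox(list(pe.data["date"]))
        disp = pe.data["dispersion_km"].values
        assert np.median(disp[~off]) > np.median(disp[off])

    def test_requires_two_usable_days(self, env, track_and_records):
        _, records = track_and_records
        one_day = TagRecordSet(
            records.individual_id, records.sex, records.data.iloc[:1].copy()
        )
        with pytest.raises(ValueError, match="2 days"):
            estimate_path(one_day, env, GeolocationParams())


class TestTripWindow:
    @staticmethod
    def _records(wet):
        start = dt.date(2017, 4, 1)
        dates = [start + dt.timedelta(days=i) for i in range(len(wet))]
        df = pd.DataFrame(
            {
                "date": dates,
                "sunrise_utc": pd.NaT,
                "sunset_utc": pd.NaT,
                "min_sst_c": 8.0,
                "max_depth_m": 0.0,
                "wet_fraction": wet,
            }
        )
        return TagRecordSet("X", "female", df)

    def test_step_function(self):
        wet = [1.0] * 100 + [0.0] * 20
        rec = self._records(wet)
        dep, arr = detect_trip_window(rec)
        assert dep == dt.date(2017, 4, 1)
        assert arr == dt.date(2017, 4, 1) + dt.timedelta(days=100)

    def test_all_dry_errors(self):
        with pytest.raises(ValueError, match="departure"):
            detect_trip_window(self._records([0.0] * 50))

    def test_ground_truth_recovery(self, track_and_records):
        track, records = track_and_records
        dep, arr = detect_trip_window(records)
        assert dep == track.departure_date
        assert arr == track.arrival_date
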