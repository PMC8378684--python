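"""Density grids, effort scoring, overlap/interaction tables and sex GLMs."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from winterdisp.geolocation import PathEstimate
from winterdisp.overlap import (
    GridSpec,
    build_overlap_table,
    effort_score,
    grid_counts,
    last_month_subset,
    normalize_density,
    regrid_effort,
    sex_interaction_test,
    sex_overlap_test,
)


def path_from(lats, lons, start=dt.date(2017, 5, 1), tag="P1"):
    dates = [start + dt.timedelta(days=i) for i in range(len(lats))]
    return PathEstimate(tag, pd.DataFrame({"date": dates, "lat": lats, "lon": lons}))


class TestGridCounts:
    def test_single_fix_single_cell(self):
        counts = grid_counts([("female", path_from([-49.0], [-64.0]))])
        assert len(counts) == 1
        row = counts.iloc[0]
        assert (row["lat_min"], row["lon_min"]) == (-50.0, -64.0)
        assert row["count"] == 1

    def test_edge_fix_goes_to_lower_edge_cell(self):
        counts = grid_counts([("female", path_from([-50.0], [-64.0]))])
        assert counts.iloc[0]["lat_min"] == -50.0

    def test_total_conservation(self):
        rng = np.random.default_rng(0)
        n = 500
        paths = [
            ("female", path_from(rng.uniform(-59, -39, n), rng.uniform(-74, -56, n))),
            ("male", path_from(rng.uniform(-59, -39, n), rng.uniform(-74, -56, n))),
        ]
        counts = grid_counts(paths)
        assert counts["count"].sum() == 2 * n


class TestNormalize:
    def test_proportional_scaling(self):
        counts = pd.DataFrame(
            {
                "sex": "female", "month": 5,
                "lat_min": [-50.0, -48.0, -46.0], "lon_min": -64.0,
                "count": [4, 2, 0],
            }
        )
        out = normalize_density(counts)
        assert list(out["density"]) == [1.0, 0.5, 0.0]

    def test_every_nonzero_layer_peaks_at_one(self):
        rng = np.random.default_rng(1)
        frames = []
        for sex in ("female", "male"):
            for month in (5, 6, 7):
                frames.append(
                    pd.DataFrame(
                        {
                            "sex": sex, "month": month,
                            "lat_min": np.arange(-56, -40, 2.0), "lon_min": -64.0,
                            "count": rng.integers(0, 30, 8),
                        }
                    )
                )
        out = normalize_density(pd.concat(frames, ignore_index=True))
        peaks = out.groupby(["sex", "month"])["density"].max()
        assert (peaks == 1.0).all()
        assert out["density"].between(0, 1).all()


class TestRegrid:
    @staticmethod
    def fine_grid(hours_fn):
        rows = []
        for la in np.arange(-52.0, -50.0, 0.5):
            for lo in np.arange(-64.0, -62.0, 0.5):
                rows.append(("trawl", 5, la, lo, hours_fn(la, lo)))
        return pd.DataFrame(rows, columns=["fishery", "month", "lat_min", "lon_min", "hours"])

    def test_sixteen_nested_cells_sum(self):
        eff = self.fine_grid(lambda la, lo: 10.0)
        coarse = regrid_effort(eff)
        assert len(coarse) == 1
        assert coarse.iloc[0]["hours"] == pytest.approx(160.0)

    def test_all_zero_stays_zero(self):
        coarse = regrid_effort(self.fine_grid(lambda la, lo: 0.0))
        assert (coarse["hours"] == 0).all()
        assert (coarse["score"] == 0).all()

    def test_conservation_of_random_grid(self):
        rng = np.random.default_rng(2)
        eff = self.fine_grid(lambda la, lo: float(rng.gamma(1.0, 50.0)))
        coarse = regrid_effort(eff)
        assert coarse["hours"].sum() == pytest.approx(eff["hours"].sum())

    def test_misaligned_grid_rejected(self):
        eff = self.fine_grid(lambda la, lo: 5.0)
        eff["lat_min"] += 0.2
        with pytest.raises(ValueError, match="misaligned"):
            regrid_effort(eff)

    def test_negative_hours_rejected(self):
        eff = self.fine_grid(lambda la, lo: 5.0)
        eff.loc[0, "hours"] = -1.0
        with pytest.raises(ValueError):
            regrid_effort(eff)


class TestEffortScore:
    @pytest.mark.parametrize(
        "hours,score",
        [
            (0.0, 0), (0.5, 1), (60.0, 1), (100.0, 2), (200.0, 2),
            (201.0, 3), (800.0, 3), (801.0, 4), (6000.0, 4), (7000.0, 5),
            (60000.0, 5),
        ],
    )
    def test_bins(self, hours, score):
        assert effort_score(hours) == score

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            effort_score(-3.0)


def make_overlap_table(densities, scores, sexes=None, fishery="trawl"):
    n = len(densities)
    return pd.DataFrame(
        {
            "fishery": fishery,
            "sex": sexes or ["female"] * n,
            "month": 6,
            "lat_min": np.arange(n) * 2.0 - 56.0,
            "lon_min": -64.0,
            "count": 1,
            "density": densities,
            "hours": np.asarray(scores) * 100.0,
            "score": scores,
            "overlap": (np.asarray(scores) > 0).astype(int),
            "interaction": np.asarray(densities) * np.asarray(scores),
        }
    )


class TestOverlapTable:
    def test_formula_and_flags(self):
        density = pd.DataFrame(
            {
                "sex": ["female", "female", "female"], "month": 6,
                "lat_min": [-50.0, -48.0, -46.0], "lon_min": -64.0,
                "count": [2, 4, 4], "density": [0.5, 1.0, 1.0],
            }
        )
        effort = pd.DataFrame(
            {
                "fishery": "trawl", "month": 6,
                "lat_min": [-50.0, -48.0, -46.0], "lon_min": -64.0,
                "hours": [900.0, 0.0, 6500.0], "score": [4, 0, 5],
            }
        )
        table = build_overlap_table(density, effort)
        by_cell = table.set_index("lat_min")
        assert by_cell.loc[-50.0, "interaction"] == pytest.approx(2.0)
        assert by_cell.loc[-50.0, "overlap"] == 1
        assert by_cell.loc[-48.0, "interaction"] == 0.0
        assert by_cell.loc[-48.0, "overlap"] == 0
        assert by_cell.loc[-46.0, "interaction"] == pytest.approx(5.0)

    def test_interaction_bounded_and_fisheries_separate(self):
        rng = np.random.default_rng(3)
        density = pd.DataFrame(
            {
                "sex": rng.choice(["female", "male"], 40),
                "month": rng.choice([5, 6, 7], 40),
                "lat_min": rng.choice(np.arange(-56, -40, 2.0), 40),
                "lon_min": rng.choice(np.arange(-70, -58, 2.0), 40),
                "count": 1,
                "density": rng.uniform(0.01, 1.0, 40),
            }
        ).drop_duplicates(["sex", "month", "lat_min", "lon_min"])
        effort = pd.DataFrame(
            {
                "fishery": rng.choice(["trawl", "shrimp"], 60),
                "month": rng.choice([5, 6, 7], 60),
                "lat_min": rng.choice(np.arange(-56, -40, 2.0), 60),
                "lon_min": rng.choice(np.arange(-70, -58, 2.0), 60),
                "hours": rng.gamma(1.0, 900.0, 60),
            }
        ).drop_duplicates(["fishery", "month", "lat_min", "lon_min"])
        effort["score"] = effort_score(effort["hours"].values)
        table = build_overlap_table(density, effort)
        assert table["interaction"].between(0, 5).all()
        assert (table["overlap"] == (table["score"] > 0).astype(int)).all()
        assert set(table.groupby("fishery").groups) <= {"trawl", "shrimp"}
        # a fishery's rows never mix with the other's effort hours
        for fishery, sub in table.groupby("fishery"):
            eff = effort[effort["fishery"] == fishery]
            merged = sub.merge(eff, on=["month", "lat_min", "lon_min"], how="left")
            assert (
                merged["hours_y"].fillna(0.0).to_numpy()
                == pytest.approx(merged["hours_x"].to_numpy())
            )


class TestSexTests:
    def test_equal_overlap_proportions_null(self):
        table = make_overlap_table(
            [0.5] * 8, [1, 1, 0, 0, 1, 1, 0, 0],
            sexes=["female"] * 4 + ["male"] * 4,
        )
        res = sex_overlap_test(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_complete_separation_flagged(self):
        table = make_overlap_table(
            [0.5] * 20, [1] * 10 + [0] * 10,
            sexes=["female"] * 10 + ["male"] * 10,
        )
        res = sex_overlap_test(table)
        assert res.separation
        assert res.p_value < 1e-6

    @pytest.mark.parametrize("seed", range(4))
    def test_deviance_matches_g_statistic(self, seed):
        """Binomial GLM deviance reduction equals the closed-form 2×2 G."""
        rng = np.random.default_rng(seed)
        n = 60
        sexes = ["female"] * (n // 2) + ["male"] * (n // 2)
        flags = rng.random(n) < np.where(np.array(sexes) == "female", 0.7, 0.4)
        table = make_overlap_table([0.5] * n, flags.astype(int), sexes=sexes)
        res = sex_overlap_test(table)
        obs = pd.crosstab(pd.Series(sexes), pd.Series(flags)).to_numpy().astype(float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
        g = 2.0 * terms.sum()
        assert res.statistic == pytest.approx(g, rel=1e-6)
        assert res.df_resid == n - 2

    def test_identical_interactions_null(self):
        table = make_overlap_table([0.5] * 8, [2] * 8, sexes=["female"] * 4 + ["male"] * 4)
        res = sex_interaction_test(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_interaction_separation(self):
        rng = np.random.default_rng(1)
        dens = np.r_[0.2 + rng.normal(0, 0.002, 6), 0.8 + rng.normal(0, 0.002, 6)]
        table = make_overlap_table(dens, [5] * 12, sexes=["female"] * 6 + ["male"] * 6)
        res = sex_interaction_test(table)
        assert res.p_value < 1e-6

    @pytest.mark.parametrize("seed", range(4))
    def test_f_equals_pooled_t_squared(self, seed):
        rng = np.random.default_rng(seed)
        dens = rng.uniform(0.05, 1.0, 30)
        sexes = list(rng.choice(["female", "male"], 27)) + ["female", "male", "male"]
        table = make_overlap_table(dens, [3] * 30, sexes=sexes)
        res = sex_interaction_test(table)
        a = table.loc[table["sex"] == "female", "interaction"]
        b = table.loc[table["sex"] == "male", "interaction"]
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t**2, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)


class TestLastMonth:
    def test_inclusive_31_day_window(self):
        path = path_from(
            [-50.0] * 180, [-64.0] * 180, start=dt.date(2017, 4, 1)
        )
        blood = dt.date(2017, 4, 1) + dt.timedelta(days=179)
        sub = last_month_subset(path, blood)
        assert len(sub.data) == 31

    def test_blood_before_path_rejected(self):
        path = path_from([-50.0] * 10, [-64.0] * 10, start=dt.date(2017, 5, 1))
        with pytest.raises(ValueError):
            last_month_subset(path, dt.date(2017, 4, 1))

    def test_matches_brute_force_filter(self):
        path = path_from(
            list(np.linspace(-54, -44, 120)), [-63.0] * 120, start=dt.date(2017, 4, 10)
        )
        blood = dt.date(2017, 8, 1)
        sub = last_month_subset(path, blood)
        expected = [
            d for d in path.data["date"]
            if blood - dt.timedelta(days=30) <= d <= blood
        ]
        assert list(sub.data["date"]) == expected
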