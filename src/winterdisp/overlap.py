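"""Gridded penguin-density × fishing-effort overlap and interaction scoring.

Daily location fixes are counted on a 2° × 2° grid (cell edges anchored at
even integer degrees, half-open cells) and normalized per sex and month to
the layer maximum.  Fishing effort at 0.5° is re-gridded by exact nesting
into the same 2° lattice and binned into scores 0–5.  For every cell where
penguins are present the overlap flag (score > 0) and the interaction score
(density × score, range 0–5) are tabulated, and sexes are compared with a
binomial GLM on the overlap flag and a Gaussian linear model on the
interaction score, separately per fishery.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .geolocation import PathEstimate

__all__ = [
    "GridSpec",
    "grid_counts",
    "normalize_density",
    "regrid_effort",
    "effort_score",
    "build_overlap_table",
    "sex_overlap_test",
    "sex_interaction_test",
    "last_month_subset",
    "SCORE_BIN_EDGES",
]

#: Upper edges of the effort-hour bins for scores 1..5 (left-open intervals;
#: zero hours is score 0, anything above the last edge is score 5).
SCORE_BIN_EDGES = (0.0, 60.0, 200.0, 800.0, 6000.0)


@dataclass(frozen=True)
class GridSpec:
    """Regular lat-lon analysis grid with half-open cells [edge, edge+size)."""

    cell_size: float = 2.0
    lat_min: float = -60.0
    lat_max: float = -38.0
    lon_min: float = -75.0
    lon_max: float = -55.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        if self.lat_min >= self.lat_max or self.lon_min >= self.lon_max:
            raise ValueError("bounding box is empty")

    def cell_edges(self, lat, lon):
        """Lower edges of the cells containing the given positions."""
        lat_e = np.floor(np.asarray(lat) / self.cell_size) * self.cell_size
        lon_e = np.floor(np.asarray(lon) / self.cell_size) * self.cell_size
        return lat_e, lon_e

    def in_box(self, lat, lon):
        return (
            (np.asarray(lat) >= self.lat_min)
            & (np.asarray(lat) < self.lat_max)
            & (np.asarray(lon) >= self.lon_min)
            & (np.asarray(lon) < self.lon_max)
        )


def grid_counts(
    paths: dict[str, tuple[str, PathEstimate]] | list[tuple[str, PathEstimate]],
    spec: GridSpec = GridSpec(),
) -> pd.DataFrame:
    """Count daily fixes per (cell, sex, month).

    ``paths`` is a list of (sex, PathEstimate).  Each daily fix increments
    exactly one half-open cell; fixes outside the bounding box are counted in
    an overflow row (lat_min/lon_min = NaN) so totals are conserved.
    Returns columns: sex, month, lat_min, lon_min, count.
    """
    if isinstance(paths, dict):
        paths = list(paths.values())
    frames = []
    for sex, pe in paths:
        df = pe.data
        months = np.array(
            [d.month if isinstance(d, dt.date) else d.month for d in df["date"]]
        )
        lat_e, lon_e = spec.cell_edges(df["lat"].to_numpy(), df["lon"].to_numpy())
        inside = spec.in_box(df["lat"].to_numpy(), df["lon"].to_numpy())
        frames.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "month": months,
                    "lat_min": np.where(inside, lat_e, np.nan),
                    "lon_min": np.where(inside, lon_e, np.nan),
                }
            )
        )
    fixes = pd.concat(frames, ignore_index=True)
    counts = (
        fixes.groupby(["sex", "month", "lat_min", "lon_min"], dropna=False)
        .size()
        .rename("count")
        .reset_index()
    )
    return counts


def normalize_density(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalize cell counts to the maximum count within each sex × month.

    Adds a ``density`` column in [0, 1]; a layer that is all zeros stays all
    zeros.  Overflow rows (NaN cell) are dropped from density layers.
    """
    out = counts.dropna(subset=["lat_min", "lon_min"]).copy()
    layer_max = out.groupby(["sex", "month"])["count"].transform("max")
    out["density"] = np.where(layer_max > 0, out["count"] / layer_max, 0.0)
    return out


def regrid_effort(effort: pd.DataFrame, spec: GridSpec = GridSpec()) -> pd.DataFrame:
    """Aggregate 0.5° effort cells into the coarse analysis grid.

    Requires exact nesting: every fine-cell edge must sit on a multiple of
    the fine cell size that subdivides the coarse cells evenly.  Coarse hours
    are the sum of the nested fine-cell hours (conserved); adds the score
    column.  Input columns: fishery, month, lat_min, lon_min, hours.
    """
    if (effort["hours"] < 0).any():
        raise ValueError("negative effort hours")
    fine_lat = np.sort(effort["lat_min"].unique())
    if len(fine_lat) > 1:
        fine_size = float(np.min(np.diff(fine_lat)))
        ratio = spec.cell_size / fine_size
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"fine grid ({fine_size}°) does not nest in {spec.cell_size}° cells"
            )
        for col in ("lat_min", "lon_min"):
            rem = np.abs(effort[col].to_numpy() / fine_size % 1.0)
            if not (np.isclose(rem, 0.0) | np.isclose(rem, 1.0)).all():
                raise ValueError(f"{col}: fine-cell edges misaligned with the grid")
    lat_e, lon_e = spec.cell_edges(
        effort["lat_min"].to_numpy(), effort["lon_min"].to_numpy()
    )
    coarse = (
        effort.assign(lat_min=lat_e, lon_min=lon_e)
        .groupby(["fishery", "month", "lat_min", "lon_min"], as_index=False)["hours"]
        .sum()
    )
    coarse["score"] = effort_score(coarse["hours"].to_numpy())
    return coarse


def effort_score(hours):
    """Bin fishing hours into scores 0–5.

    0 for exactly zero effort; then 1: (0, 60], 2: (60, 200], 3: (200, 800],
    4: (800, 6000], 5: above 6000.
    """
    h = np.asarray(hours, dtype=float)
    if (h < 0).any():
        raise ValueError("negative hours")
    score = np.searchsorted(SCORE_BIN_EDGES, h, side="left")
    score = np.where(h == 0.0, 0, np.maximum(score, 1))
    return score if score.ndim else int(score)


def build_overlap_table(density: pd.DataFrame, effort: pd.DataFrame) -> pd.DataFrame:
    """Join penguin density with scored effort on the shared grid.

    One row per (cell, sex, month, fishery) with density > 0; cells without
    effort records carry score 0.  ``overlap`` = 1 iff score > 0;
    ``interaction`` = density × score ∈ [0, 5].
    """
    present = density[density["density"] > 0]
    rows = []
    for fishery, eff in effort.groupby("fishery"):
        merged = present.merge(
            eff[["month", "lat_min", "lon_min", "hours", "score"]],
            on=["month", "lat_min", "lon_min"],
            how="left",
        )
        merged["fishery"] = fishery
        merged[["hours", "score"]] = merged[["hours", "score"]].fillna(0)
        rows.append(merged)
    table = pd.concat(rows, ignore_index=True)
    table["score"] = table["score"].astype(int)
    table["overlap"] = (table["score"] > 0).astype(int)
    table["interaction"] = table["density"] * table["score"]
    cols = [
        "fishery", "sex", "month", "lat_min", "lon_min",
        "count", "density", "hours", "score", "overlap", "interaction",
    ]
    return table[cols]


@dataclass(frozen=True)
class GlmComparison:
    statistic: float
    df_resid: int
    p_value: float
    separation: bool = False


def sex_overlap_test(table: pd.DataFrame) -> GlmComparison:
    """Binomial GLM of the overlap flag on sex (likelihood-ratio test).

    With a single binary covariate the deviance reduction equals the 2×2
    G-statistic; the p-value is the 1-df chi-square tail and ``df_resid`` the
    residual degrees of freedom (rows − 2).
    """
    sexes = sorted(table["sex"].unique())
    if len(sexes) != 2:
        raise ValueError("both sexes required")
    y = table["overlap"].to_numpy(dtype=float)
    x = (table["sex"] == sexes[1]).to_numpy(dtype=float)
    props = table.groupby("sex")["overlap"].mean()
    separation = bool(((props == 0) | (props == 1)).any())
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation is reported via the flag
        null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit()
        full = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit(
            maxiter=200
        )
    lr = float(null.deviance - full.deviance)
    p = float(stats.chi2.sf(lr, df=1))
    return GlmComparison(lr, int(len(y) - 2), p, separation)


def sex_interaction_test(table: pd.DataFrame) -> GlmComparison:
    """Gaussian linear model of the interaction score on sex (F test).

    Applied to rows with effort present (score > 0), the interaction rows.
    """
    sub = table[table["score"] > 0]
    sexes = sorted(sub["sex"].unique())
    if len(sexes) != 2:
        raise ValueError("both sexes required among interaction rows")
    y = sub["interaction"].to_numpy(dtype=float)
    x = (sub["sex"] == sexes[1]).to_numpy(dtype=float)
    if np.ptp(y) == 0.0:  # constant response: no effect by construction
        return GlmComparison(0.0, int(len(y) - 2), 1.0)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    f = float(model.fvalue)
    p = float(model.f_pvalue)
    return GlmComparison(f, int(len(y) - 2), p)


def last_month_subset(path: PathEstimate, blood_date: dt.date) -> PathEstimate:
    """Positions within the 30 days before blood sampling (inclusive window).

    Blood isotope turnover is ~30 days, so the window [blood_date − 30 d,
    blood_date] is the period the sample integrates.
    """
    dates = np.array(
        [d if isinstance(d, dt.date) else d.date() for d in path.data["date"]]
    )
    if len(dates) == 0 or blood_date < dates.min():
        raise ValueError("blood date precedes the path")
    lo = blood_date - dt.timedelta(days=30)
    mask = (dates >= lo) & (dates <= blood_date)
    if not mask.any():
        raise ValueError("no positions within 30 days of blood sampling")
    return PathEstimate(path.individual_id, path.data.loc[mask].reset_index(drop=True))
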