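"""End-to-end orchestration of the winter-dispersal analysis.

Stages run in dependency order — simulate (or ingest) → geolocate → metrics →
overlap → isotopes — each reading the previous stage's files, so any stage
can be re-run in isolation.  A run manifest records stage statuses, output
paths with SHA-256 checksums, and the per-stage seeds fanned out from the
global seed; identical config + seed reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as wio
from . import isotopes as iso
from . import overlap as ov
from . import reference, synthetic, track_metrics
from .environment import make_environment
from .geolocation import GeolocationParams, detect_trip_window, estimate_path

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("winterdisp")

_STAGES = ("simulate", "geolocate", "metrics", "overlap", "isotopes")


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run.

    When ``simulate`` is enabled the synthetic generators produce every
    input; otherwise the ``*_path`` fields must point at existing files for
    each enabled stage.
    """

    out_dir: str | Path = "winterdisp_run"
    stages: tuple[str, ...] = _STAGES
    seed: int = 0
    log_level: str = "INFO"
    simulation: synthetic.SimulationConfig | None = None
    geolocation: GeolocationParams | None = None
    grid: ov.GridSpec = field(default_factory=ov.GridSpec)
    records_path: str | None = None
    effort_path: str | None = None
    isotopes_path: str | None = None
    environment_path: str | None = None
    paths_path: str | None = None

    def resolve(self, name: str, default: str) -> Path:
        explicit = getattr(self, f"{name}_path")
        return Path(explicit) if explicit else Path(self.out_dir) / default


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from a YAML key-value file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "simulation" in raw and raw["simulation"] is not None:
        sim = dict(raw["simulation"])
        for key in ("start_date", "end_date"):
            if key in sim and isinstance(sim[key], str):
                sim[key] = dt.date.fromisoformat(sim[key])
        raw["simulation"] = synthetic.SimulationConfig(**sim)
    if "geolocation" in raw and raw["geolocation"] is not None:
        geo = dict(raw["geolocation"])
        if "solar_angle_range" in geo:
            geo["solar_angle_range"] = tuple(geo["solar_angle_range"])
        raw["geolocation"] = GeolocationParams(**geo)
    if "grid" in raw and raw["grid"] is not None:
        raw["grid"] = ov.GridSpec(**raw["grid"])
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(config: PipelineConfig, stage_index: int) -> int:
    seq = np.random.SeedSequence(config.seed, spawn_key=(stage_index,))
    return int(seq.generate_state(1)[0] % (2**31))


def _validate(config: PipelineConfig) -> None:
    enabled = set(config.stages)
    unknown = enabled - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if "simulate" in enabled:
        return  # everything downstream is generated
    requirements = {
        "geolocate": ["records"],
        "metrics": ["records", "paths"],
        "overlap": ["paths", "effort"],
        "isotopes": ["isotopes"],
    }
    for stage in enabled:
        for inp in requirements.get(stage, []):
            path = config.resolve(inp, f"{inp}.csv")
            candidates = [path]
            if inp == "records":
                candidates.append(config.resolve("records", "tag_records.csv"))
            if not any(p.exists() for p in candidates):
                raise FileNotFoundError(
                    f"stage '{stage}' requires input '{inp}' but {path} is missing"
                )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns the manifest (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    _validate(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, status: str, outputs: list[Path], seed: int | None = None):
        manifest["stages"][stage] = {
            "status": status,
            "seed": seed,
            "outputs": {str(p): _sha256(p) for p in outputs if p.exists()},
        }

    enabled = set(config.stages)
    ctx: dict = {}
    for idx, stage in enumerate(_STAGES):
        if stage not in enabled:
            manifest["stages"][stage] = {"status": "skipped", "outputs": {}}
            continue
        seed = _stage_seed(config, idx)
        try:
            outputs = _RUNNERS[stage](config, ctx, seed, out_dir)
        except Exception as exc:
            log.error("stage %s failed: %s", stage, exc)
            record(stage, f"failed: {exc}", [], seed)
            for later in _STAGES[idx + 1 :]:
                manifest["stages"][later] = {"status": "halted", "outputs": {}}
            break
        record(stage, "ok", outputs, seed)
        log.info("stage %s ok (%d outputs)", stage, len(outputs))

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_simulate(config: PipelineConfig, ctx: dict, seed: int, out: Path) -> list[Path]:
    sim = config.simulation or synthetic.SimulationConfig(rng_seed=seed)
    data = synthetic.simulate_dataset(sim)
    ctx.update(data, sim_config=sim)
    truth_rows = []
    for t in data["tracks"]:
        for row in t.positions.itertuples(index=False):
            truth_rows.append((t.individual_id, t.sex, row.date, row.lat, row.lon))
    import pandas as pd

    truth = pd.DataFrame(truth_rows, columns=["id", "sex", "date", "lat", "lon"])
    outputs = [
        wio.write_tag_records(data["tag_records"], out / "tag_records.csv"),
        wio.write_effort(data["effort"], out / "effort.csv"),
        wio.write_isotope_samples(data["isotope_samples"], out / "isotopes.csv"),
        wio.write_environment(data["environment"], out / "environment.nc"),
    ]
    truth_path = out / "true_tracks.csv"
    truth.to_csv(truth_path, index=False)
    data["isotope_truth"].to_csv(out / "isotope_truth.csv", index=False)
    return outputs + [truth_path, out / "isotope_truth.csv"]


def _run_geolocate(config: PipelineConfig, ctx: dict, seed: int, out: Path) -> list[Path]:
    records = ctx.get("tag_records") or wio.read_tag_records(
        config.resolve("records", "tag_records.csv")
    )
    env = ctx.get("environment")
    if env is None:
        env_path = config.resolve("environment", "environment.nc")
        env = wio.read_environment(env_path) if env_path.exists() else make_environment()
    params = config.geolocation or GeolocationParams(rng_seed=seed)
    paths = []
    for rec in records:
        pe = estimate_path(rec, env, params, keep_iteration_paths=False)
        paths.append((rec.sex, pe))
        log.info("geolocated %s (%d days)", rec.individual_id, len(pe.data))
    ctx["paths"] = paths
    ctx["environment"] = env
    return [wio.write_paths(paths, out / "paths.csv")]


def _run_metrics(config: PipelineConfig, ctx: dict, seed: int, out: Path) -> list[Path]:
    import pandas as pd

    records = ctx.get("tag_records") or wio.read_tag_records(
        config.resolve("records", "tag_records.csv")
    )
    paths = ctx.get("paths") or wio.read_paths(config.resolve("paths", "paths.csv"))
    by_id = {pe.individual_id: (sex, pe) for sex, pe in paths}
    summaries = []
    for rec in records:
        if rec.individual_id not in by_id:
            continue
        sex, pe = by_id[rec.individual_id]
        dep, arr = detect_trip_window(rec)
        summaries.append(track_metrics.trip_summary(pe, sex or rec.sex, dep, arr))
    summary_df = pd.DataFrame(
        [
            {
                "id": s.individual_id,
                "sex": s.sex,
                "departure": s.departure_date,
                "arrival": s.arrival_date,
                "trip_duration_days": s.trip_duration_days,
                "latitudinal_range_km": s.latitudinal_range_km,
            }
            for s in summaries
        ]
    )
    stats_report: dict = {}
    if summary_df["sex"].nunique() == 2:
        for var in ("latitudinal_range_km", "trip_duration_days"):
            gc = track_metrics.heteroscedastic_group_test(
                summary_df[var], summary_df["sex"]
            )
            stats_report[var] = dataclasses.asdict(gc)
        depth_rows = []
        for rec in records:
            sub = rec.data[rec.data["max_depth_m"] > 0]
            for depth in sub["max_depth_m"]:
                depth_rows.append((rec.individual_id, rec.sex, float(depth)))
        ddf = pd.DataFrame(depth_rows, columns=["id", "sex", "depth"])
        fit = track_metrics.random_intercept_depth_model(ddf["depth"], ddf["id"], ddf["sex"])
        stats_report["daily_max_depth"] = dataclasses.asdict(fit)
    summary_path = out / "trip_summaries.csv"
    summary_df.to_csv(summary_path, index=False)
    stats_path = out / "track_stats.json"
    stats_path.write_text(json.dumps(stats_report, indent=2, default=str))
    ctx["trip_summaries"] = summary_df
    return [summary_path, stats_path]


def _run_overlap(config: PipelineConfig, ctx: dict, seed: int, out: Path) -> list[Path]:
    paths = ctx.get("paths") or wio.read_paths(config.resolve("paths", "paths.csv"))
    effort = ctx.get("effort")
    if effort is None:
        effort = wio.read_effort(config.resolve("effort", "effort.csv"))
    counts = ov.grid_counts(paths, config.grid)
    density = ov.normalize_density(counts)
    coarse = ov.regrid_effort(effort, config.grid)
    table = ov.build_overlap_table(density, coarse)
    report = {}
    for fishery, sub in table.groupby("fishery"):
        entry = {"overlap": dataclasses.asdict(ov.sex_overlap_test(sub))}
        if (sub["score"] > 0).any():
            entry["interaction"] = dataclasses.asdict(ov.sex_interaction_test(sub))
        report[str(fishery)] = entry
    outputs = [
        wio.write_overlap_table(table, out / "overlap.csv"),
        wio.cells_to_geojson(table, out / "overlap_cells.geojson", config.grid.cell_size),
    ]
    density.to_csv(out / "density.csv", index=False)
    (out / "overlap_stats.json").write_text(json.dumps(report, indent=2))
    ctx["overlap_table"] = table
    return outputs + [out / "density.csv", out / "overlap_stats.json"]


def _run_isotopes(config: PipelineConfig, ctx: dict, seed: int, out: Path) -> list[Path]:
    import pandas as pd

    samples = ctx.get("isotope_samples")
    if samples is None:
        samples = wio.read_isotope_samples(config.resolve("isotopes", "isotopes.csv"))
    year = int(samples["year"].iloc[0])
    females = samples[samples["sex"] == "female"]
    males = samples[samples["sex"] == "male"]

    fits = {}
    posts = {}
    for sex, sub in (("female", females), ("male", males)):
        fits[sex] = iso.sea_from_samples(sub["d13C"], sub["d15N"], label=sex)
        posts[sex] = iso.sea_bayesian(sub["d13C"], sub["d15N"], seed=seed, label=sex)
    overlap_pct = iso.ellipse_overlap(fits["female"], fits["male"])

    northern = iso.corrected_baseline(reference.NORTHERN_PATAGONIA, year)
    southern = iso.corrected_baseline(reference.SOUTHERN_PATAGONIA, year)
    franklin = iso.corrected_baseline(reference.BAHIA_FRANKLIN, year)
    tp_female = iso.tp_two_baseline(
        females["d13C"], females["d15N"], southern, franklin, reference.DEFAULT_TDF,
        seed=seed,
    )
    tp_male = iso.tp_one_baseline(
        males["d15N"], northern, reference.DEFAULT_TDF, seed=seed + 1
    )
    p_male_higher = iso.compare_posteriors(tp_male.tp_draws, tp_female.tp_draws, seed=seed)

    ellipse_df = pd.DataFrame(
        [
            {
                "sex": sex,
                "n": fits[sex].n,
                "sea": fits[sex].sea,
                "sea_c": fits[sex].sea_c,
                "sea_b_mean": posts[sex].mean,
                "sea_b_ci_low": posts[sex].credible_interval()[0],
                "sea_b_ci_high": posts[sex].credible_interval()[1],
            }
            for sex in ("female", "male")
        ]
    )
    draws_df = pd.DataFrame(
        {
            "tp_female": tp_female.tp_draws[: min(5000, tp_female.tp_draws.size)],
            "alpha_female": tp_female.alpha_draws[: min(5000, tp_female.tp_draws.size)],
            "tp_male": np.resize(tp_male.tp_draws, min(5000, tp_female.tp_draws.size)),
        }
    )
    report = {
        "sea_overlap": dataclasses.asdict(overlap_pct),
        "p_smaller_sea_male": iso.prob_smaller_sea(posts["male"], posts["female"]),
        "tp_female": tp_female.summary(),
        "tp_male": tp_male.summary(),
        "p_tp_male_gt_female": p_male_higher,
        "converged": {"female": tp_female.converged, "male": tp_male.converged},
    }
    ellipse_path = out / "ellipses.csv"
    ellipse_df.to_csv(ellipse_path, index=False)
    draws_path = out / "tp_draws.csv"
    draws_df.to_csv(draws_path, index=False)
    report_path = out / "isotope_report.json"
    report_path.write_text(json.dumps(report, indent=2))
    ctx["isotope_report"] = report
    return [ellipse_path, draws_path, report_path]


_RUNNERS = {
    "simulate": _run_simulate,
    "geolocate": _run_geolocate,
    "metrics": _run_metrics,
    "overlap": _run_overlap,
    "isotopes": _run_isotopes,
}
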