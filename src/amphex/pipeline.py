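"""End-to-end orchestration of the exposure pipeline on on-disk artifacts.

Stages communicate only through files in a working directory, so each stage
can be run, inspected, and rerun independently (and the CLI maps onto them
one-to-one):

    simulate -> detect-events -> build-layers -> exposure -> aggregate
                                                          -> fit-status-model

Each stage records provenance (config snapshot, seed, input digests, timings)
in the directory's ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .aggregation import exposed_grid, multi_exposure, taxon_summary
from .climate import (
    AnalysisConfig,
    compute_percentile_threshold,
    drought_event_mask,
    monthly_event_counts,
)
from .exposure import exposure_table, region_mask_from_ranges
from .hazard import build_hazard_layer, decadal_count, difference_field
from .status import fit_multinomial
from .synthetic import (
    SyntheticScenario,
    exposures_wide,
    gen_ranges,
    gen_spei_cube,
    gen_status_changes,
    gen_temperature_cube,
)

EVENT_CLASSES = ("heat_wave", "cold_spell", "drought")


def load_config(path: str | Path | None) -> dict:
    """Read the plain-text (YAML) config file; returns {} when absent."""
    if path is None:
        return {}
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data


def analysis_config(file_cfg: dict, **cli_overrides) -> AnalysisConfig:
    """AnalysisConfig with precedence: CLI flag > config file > default."""
    values = dict(file_cfg.get("analysis", {}))
    values.update({k: v for k, v in cli_overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown analysis config keys: {sorted(unknown)}")
    for key in ("baseline_decade", "recent_decade"):
        if key in values:
            values[key] = tuple(values[key])
    return AnalysisConfig(**values)


def scenario_config(file_cfg: dict, seed: int | None = None) -> SyntheticScenario:
    values = dict(file_cfg.get("scenario", {}))
    if seed is not None:
        values["seed"] = seed
    known = {f.name for f in dataclasses.fields(SyntheticScenario)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown scenario config keys: {sorted(unknown)}")
    for key in ("baseline_decade", "recent_decade"):
        if key in values:
            values[key] = tuple(values[key])
    return SyntheticScenario(**values)


def _manifest(config: AnalysisConfig, seed: int | None = None) -> io.RunManifest:
    return io.RunManifest(config=dataclasses.asdict(config), seed=seed)


def stage_simulate(
    scenario: SyntheticScenario, out_dir: str | Path, config: AnalysisConfig
) -> None:
    """Generate and write all synthetic inputs for both analysis decades."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest(config, scenario.seed)
    with manifest.time_stage("simulate"):
        for tag, decade in (
            ("baseline", scenario.baseline_decade),
            ("recent", scenario.recent_decade),
        ):
            io.write_temperature_cube(
                gen_temperature_cube(scenario, decade), out / f"temperature_{tag}.nc"
            )
            io.write_spei_cube(
                gen_spei_cube(scenario, decade), out / f"spei_{tag}.nc"
            )
        ranges, taxonomy = gen_ranges(scenario)
        io.write_ranges(ranges, out / "ranges.geojson")
        io.write_table(taxonomy, out / "taxonomy.csv")
    manifest.write(out)


def stage_detect_events(
    in_dir: str | Path, out_dir: str | Path, config: AnalysisConfig
) -> None:
    """Detect heat/cold/drought events and write monthly counts per decade."""
    ind, out = Path(in_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest(config)
    with manifest.time_stage("detect_events"):
        baseline = io.read_temperature_cube(ind / "temperature_baseline.nc")
        recent = io.read_temperature_cube(ind / "temperature_recent.nc")
        manifest.add_inputs(
            ind / "temperature_baseline.nc", ind / "temperature_recent.nc"
        )
        b0, b1 = config.baseline_decade
        window = (f"{b0}-01-01", f"{b1}-12-31")
        for q, direction, cls in (
            (config.heat_q, "above", "heat_wave"),
            (config.cold_q, "below", "cold_spell"),
        ):
            thr = compute_percentile_threshold(baseline, q, window)
            for tag, cube in (("baseline", baseline), ("recent", recent)):
                counts = monthly_event_counts(cube, thr, direction, config)
                io.write_monthly_counts(counts, out / f"counts_{cls}_{tag}.nc")
        for tag in ("baseline", "recent"):
            spei = io.read_spei_cube(ind / f"spei_{tag}.nc")
            manifest.add_inputs(ind / f"spei_{tag}.nc")
            counts = drought_event_mask(spei, config.spei_cutoff)
            io.write_monthly_counts(counts, out / f"counts_drought_{tag}.nc")
    manifest.write(out)


def stage_build_layers(
    in_dir: str | Path,
    counts_dir: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig,
) -> None:
    """Decadal sums, difference fields, region mask, and binary hazard layers."""
    ind, cnt, out = Path(in_dir), Path(counts_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest(config)
    with manifest.time_stage("build_layers"):
        ranges = io.read_ranges(ind / "ranges.geojson")
        manifest.add_inputs(ind / "ranges.geojson")
        region = None
        for cls in EVENT_CLASSES:
            monthly_b = io.read_monthly_counts(cnt / f"counts_{cls}_baseline.nc")
            monthly_r = io.read_monthly_counts(cnt / f"counts_{cls}_recent.nc")
            diff = difference_field(
                decadal_count(monthly_r, config.recent_decade),
                decadal_count(monthly_b, config.baseline_decade),
            )
            if region is None:
                region = region_mask_from_ranges(ranges, diff.grid)
                io.write_region_mask(region, out / "region_mask.nc")
            rule = "increase_only" if cls == "cold_spell" else "ge_threshold"
            layer = build_hazard_layer(
                diff,
                region,
                layer_percentile=config.layer_percentile,
                rule=rule,
                include_zero=config.cold_include_zero,
            )
            io.write_difference_field(diff, out / f"difference_{cls}.nc")
            io.write_hazard_layer(layer, out / f"layer_{cls}.nc")
    manifest.write(out)


def stage_exposure(
    in_dir: str | Path,
    layers_dir: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Per-species overlap, exposure classification, excess-event statistics."""
    ind, lay, out = Path(in_dir), Path(layers_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest(config)
    with manifest.time_stage("exposure"):
        ranges = io.read_ranges(ind / "ranges.geojson")
        layers = {
            cls: io.read_hazard_layer(lay / f"layer_{cls}.nc")
            for cls in EVENT_CLASSES
        }
        diffs = {
            cls: io.read_difference_field(lay / f"difference_{cls}.nc")
            for cls in EVENT_CLASSES
        }
        table = exposure_table(ranges, layers, diffs, cutoff=config.exposure_cutoff)
        io.write_table(table, out / "exposure.csv")
    manifest.write(out)
    return table


def stage_aggregate(
    in_dir: str | Path,
    exposure_dir: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig,
) -> None:
    """Gridded, taxonomic, and multi-exposure summaries."""
    ind, exp, out = Path(in_dir), Path(exposure_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest(config)
    with manifest.time_stage("aggregate"):
        ranges = io.read_ranges(ind / "ranges.geojson")
        taxonomy = io.read_table(ind / "taxonomy.csv")
        exposures = io.read_table(exp / "exposure.csv")
        summary = exposed_grid(ranges, exposures, config.aggregation_cell_degrees)
        io.write_field(
            summary.richness.astype(float), summary.grid, out / "richness.nc",
            "richness",
        )
        for cls, counts in summary.exposed_counts.items():
            io.write_field(
                counts.astype(float), summary.grid, out / f"exposed_count_{cls}.nc",
                "exposed_count", {"event_class": cls},
            )
            io.write_field(
                summary.exposed_proportion(cls), summary.grid,
                out / f"exposed_proportion_{cls}.nc", "exposed_proportion",
                {"event_class": cls},
            )
        for level in ("order", "family"):
            io.write_table(
                taxon_summary(exposures, taxonomy, level), out / f"taxon_{level}.csv"
            )
        io.write_table(multi_exposure(exposures), out / "multi_exposure.csv")
    manifest.write(out)


def stage_fit_status_model(
    records_path: str | Path, out_dir: str | Path, config: AnalysisConfig
) -> pd.DataFrame:
    """Fit the multinomial status-change model and write a Table-1-style CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest(config)
    with manifest.time_stage("fit_status_model"):
        records = io.read_table(records_path)
        manifest.add_inputs(records_path)
        frames = []
        for period, sub in records.groupby("period"):
            if sub["outcome"].nunique() < 2:
                warnings.warn(
                    f"period {period}: only one outcome level present; "
                    "model not identifiable, skipping",
                    stacklevel=2,
                )
                continue
            res = fit_multinomial(sub)
            sf = res.summary_frame()
            sf.insert(0, "period", period)
            frames.append(sf)
        columns = ["period", "outcome", "predictor", "odds_ratio",
                   "ci_low", "ci_high", "p"]
        table = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=columns)
        )
        io.write_table(table, out / "status_model.csv")
    manifest.write(out)
    return table


def run_all(
    scenario: SyntheticScenario, config: AnalysisConfig, out_dir: str | Path
) -> pd.DataFrame:
    """Full synthetic loop: simulate, detect, layer, expose, aggregate, fit.

    Status outcomes are drawn from the scenario's true model parameters using
    the *computed* exposure proportions, so the final fit closes the loop on
    the generator's ground truth.  Returns the fitted odds-ratio table.
    """
    out = Path(out_dir)
    stage_simulate(scenario, out / "inputs", config)
    stage_detect_events(out / "inputs", out / "events", config)
    stage_build_layers(out / "inputs", out / "events", out / "layers", config)
    exposures = stage_exposure(out / "inputs", out / "layers", out / "exposure", config)
    stage_aggregate(out / "inputs", out / "exposure", out / "aggregate", config)
    wide = exposures_wide(exposures)
    records = gen_status_changes(
        wide, scenario.status_params, rng=np.random.default_rng([scenario.seed, 917])
    )
    io.write_table(records, out / "exposure" / "status_changes.csv")
    return stage_fit_status_model(
        out / "exposure" / "status_changes.csv", out / "model", config
    )
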