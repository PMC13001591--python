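"""End-to-end orchestration: simulate/ingest -> cull -> aggregate -> metrics
-> linear and GAM trend analyses -> CSV report bundle with a JSON manifest.

Outputs are pure functions of the run configuration and seed: rerunning
with the same inputs produces byte-identical CSVs (the manifest records a
hash of every output).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .gam import GAMConfig, GAMError, fit_gam, predict_standardized, smooth_significance
from .ingest import GROUP_KEYS, aggregate, cull, read_trap_csv, write_aggregates_csv, write_trap_csv
from .linear import STUDY_PHASES, PhaseDefinition, phase_analysis, trend_table
from .metrics import COMMUNITY_METRICS, PredationWeights, series_by_group
from .species import HabitatMap, Origin, SpeciesRegistry
from .synthetic import (
    ScenarioConfig,
    generate_scenario,
    load_scenario_yaml,
    registry_from_profiles,
    study_default_scenario,
)

logger = logging.getLogger("coccitrend")


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: exactly one input source, plus analysis settings."""

    outdir: str | Path
    input_csv: str | Path | None = None
    scenario: str | None = None           # "default" or a scenario YAML path
    species_config: str | Path | None = None  # species/habitat YAML (CSV input)
    phases: tuple[PhaseDefinition, ...] | None = STUDY_PHASES
    gam: GAMConfig = field(default_factory=GAMConfig)
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self):
        if (self.input_csv is None) == (self.scenario is None):
            raise ValueError("provide exactly one of input_csv or scenario")


@dataclass
class DetectionSummary:
    """Zero-capture (below-detection) years per species over a window."""

    table: pd.DataFrame                 # species, origin, zero_years, n_zero_years
    window: tuple[int, int]
    native_any_undetected: int          # natives with >= 1 zero-capture year
    native_all_undetected: int          # natives undetected in every window year


def detection_summary(
    aggregates: pd.DataFrame,
    window: tuple[int, int],
    registry: SpeciesRegistry,
) -> DetectionSummary:
    """For each species, the window years with zero total captures across all
    treatments; species with no rows at all in a year count as undetected.
    Both readings of "not detected on an annual basis" are summarized: at
    least one undetected year, and undetected in all window years.
    """
    years = list(range(window[0], window[1] + 1))
    sp_rows = aggregates[~aggregates["taxon_key"].isin(GROUP_KEYS)]
    totals = (
        sp_rows[sp_rows["year"].isin(years)]
        .groupby(["taxon_key", "year"], observed=True)["captures"]
        .sum()
    )
    rows = []
    for name in registry.names:
        zero_years = [y for y in years if totals.get((name, y), 0) == 0]
        rows.append(
            {
                "species": name,
                "origin": registry.origin(name).value,
                "zero_years": ";".join(map(str, zero_years)),
                "n_zero_years": len(zero_years),
            }
        )
    table = pd.DataFrame(rows)
    native = table[table["origin"] == Origin.NATIVE.value]
    return DetectionSummary(
        table=table,
        window=window,
        native_any_undetected=int((native["n_zero_years"] >= 1).sum()),
        native_all_undetected=int((native["n_zero_years"] == len(years)).sum()),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle to ``outdir``.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    curves_dir = outdir / "curves"
    curves_dir.mkdir(exist_ok=True)
    timings: dict[str, float] = {}

    # -- input ------------------------------------------------------------
    t0 = _stage("input")
    if config.scenario is not None:
        if config.scenario == "default":
            scen, species = study_default_scenario()
        else:
            scen, species = load_scenario_yaml(config.scenario)
        scen = dataclasses.replace(scen, seed=config.seed)
        registry = registry_from_profiles(species)
        habitat_map = HabitatMap(dict(scen.treatments))
        records = generate_scenario(scen, species)
        write_trap_csv(records, outdir / "records.csv")
        source = {"scenario": config.scenario, "seed": config.seed}
    else:
        if config.species_config is None:
            raise ValueError("CSV input requires a species_config YAML")
        registry = SpeciesRegistry.from_yaml(config.species_config)
        habitat_map = HabitatMap.from_yaml(config.species_config)
        records = read_trap_csv(config.input_csv, registry)
        source = {"input_csv": str(config.input_csv)}
    timings["input"] = time.perf_counter() - t0

    # -- cull + aggregate -------------------------------------------------
    t0 = _stage("cull")
    n_raw = len(records)
    records = cull(records)
    logger.info("culling removed %d of %d records", n_raw - len(records), n_raw)
    timings["cull"] = time.perf_counter() - t0

    t0 = _stage("aggregate")
    aggregates = aggregate(records, registry)
    write_aggregates_csv(aggregates, outdir / "aggregates.csv")
    timings["aggregate"] = time.perf_counter() - t0

    weights = PredationWeights.from_registry(registry)
    year_range = (int(records["year"].min()), int(records["year"].max()))

    # -- trends per community metric --------------------------------------
    t0 = _stage("trends")
    linear_rows, gam_rows = [], []
    for group in COMMUNITY_METRICS:
        series = series_by_group(aggregates, habitat_map, group, weights=weights)
        phases = config.phases if config.phases is not None else ()
        fits = phase_analysis(series, phases=phases, alpha=config.alpha)
        linear_rows.append(trend_table(fits, group))

        pooled = fit_gam(series, config.gam, by_habitat=False)
        parted = fit_gam(series, config.gam, by_habitat=True)
        test = smooth_significance(pooled)
        gam_rows.append(
            {
                "group": group, "model": "pooled", "habitat": "",
                "edf": test.edf, "ref_df": test.ref_df, "F": test.F,
                "p_value": test.p_value, "significant": test.significant,
                "gcv": pooled.gcv, "dispersion": pooled.dispersion,
            }
        )
        for lv in parted.habitat_levels:
            t = smooth_significance(parted, f"s(year):{lv}")
            gam_rows.append(
                {
                    "group": group, "model": "by_habitat", "habitat": lv,
                    "edf": t.edf, "ref_df": t.ref_df, "F": t.F,
                    "p_value": t.p_value, "significant": t.significant,
                    "gcv": parted.gcv, "dispersion": parted.dispersion,
                }
            )
        years = list(range(year_range[0], year_range[1] + 1))
        predict_standardized(pooled, years).to_csv(
            curves_dir / f"{group}_pooled.csv", index=False
        )
        predict_standardized(parted, years).to_csv(
            curves_dir / f"{group}_by_habitat.csv", index=False
        )
    timings["trends"] = time.perf_counter() - t0

    # -- per-species curves ------------------------------------------------
    t0 = _stage("species_curves")
    skipped = []
    for name in registry.names:
        sub = aggregates[aggregates["taxon_key"] == name]
        if sub.empty or sub["captures"].sum() < 10:
            skipped.append(name)
            continue
        series = series_by_group(aggregates, habitat_map, name)
        try:
            fit = fit_gam(series, config.gam, by_habitat=False)
            yrs = sorted(series.loc[series["effort"] > 0, "year"].unique())
            predict_standardized(fit, yrs).to_csv(
                curves_dir / f"species_{name.replace(' ', '_')}.csv", index=False
            )
        except GAMError as exc:
            logger.warning("species %s: GAM skipped (%s)", name, exc)
            skipped.append(name)
    timings["species_curves"] = time.perf_counter() - t0

    linear_df = pd.concat(linear_rows, ignore_index=True)
    linear_df.to_csv(outdir / "linear_trends.csv", index=False)
    gam_df = pd.DataFrame(gam_rows)
    gam_df.to_csv(outdir / "gam_summary.csv", index=False)

    # -- detection summary -------------------------------------------------
    last5 = (year_range[1] - 4, year_range[1])
    det = detection_summary(aggregates, last5, registry)
    det.table.to_csv(outdir / "detection_summary.csv", index=False)

    # -- manifest ----------------------------------------------------------
    outputs = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*.csv")
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "source": source,
        "alpha": config.alpha,
        "gam": dataclasses.asdict(config.gam),
        "phases": [dataclasses.asdict(p) for p in (config.phases or ())],
        "records_culled_in": n_raw,
        "records_culled_out": len(records),
        "species_gam_skipped": skipped,
        "detection_window": list(last5),
        "native_any_undetected_last5": det.native_any_undetected,
        "native_all_undetected_last5": det.native_all_undetected,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {name: _sha256(outdir / name) for name in outputs},
    }
    config_hash = hashlib.sha256(
        json.dumps({k: v for k, v in manifest.items() if k not in ("timings_s",)},
                   sort_keys=True).encode()
    ).hexdigest()
    manifest["config_hash"] = config_hash
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
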