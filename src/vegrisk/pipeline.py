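"""End-to-end orchestration: one config in, a reproducible bundle out.

``run_pipeline`` builds the model (from a synthetic scenario or from real
input files), fits it, writes every table, the climate/anomaly grids, logs
and a manifest to the output directory.  The manifest records the config,
seed, package version and per-stage row counts — no timestamps — so a
re-run with the same config and seed reproduces every output byte for
byte.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, save_config
from .grids import median_anomaly, read_ascii_grid, write_ascii_grid
from .model import VegetationRiskModel, VegetationRiskResults
from .synthetic import generate_scenario

__all__ = ["run_pipeline", "build_model"]


def _load_real_inputs(config: RunConfig) -> VegetationRiskModel:
    occ = pd.read_csv(config.occurrences_path)
    current = {
        "MAT": read_ascii_grid(config.current_mat_path, "MAT", "current"),
        "MAP": read_ascii_grid(config.current_map_path, "MAP", "current"),
    }
    if len(config.future_mat_paths) != len(config.future_map_paths):
        raise ValueError("future MAT and MAP path lists must pair up per GCM")
    futures = [
        {
            "MAT": read_ascii_grid(pm, "MAT", f"future:gcm{i + 1:02d}"),
            "MAP": read_ascii_grid(pp, "MAP", f"future:gcm{i + 1:02d}"),
        }
        for i, (pm, pp) in enumerate(
            zip(config.future_mat_paths, config.future_map_paths)
        )
    ]
    veg = (read_ascii_grid(config.veg_map_path, "VEG")
           if config.veg_map_path else None)

    def _names(path):
        if path is None:
            return None
        s = pd.read_csv(path)
        return set(s.iloc[:, 0].astype(str).str.strip())

    return VegetationRiskModel(
        occurrences=occ, current=current, futures=futures,
        accepted_names=_names(config.accepted_names_path),
        exotic_names=_names(config.exotic_names_path),
        veg_map=veg, config=config,
    )


def build_model(config: RunConfig) -> VegetationRiskModel:
    """Construct the model for either input mode (validates the config)."""
    config.validate()
    if config.scenario is not None:
        scenario = generate_scenario(config.scenario)
        model = VegetationRiskModel.from_scenario(scenario, config=config)
        model._scenario = scenario  # kept for output of raw tables
        return model
    return _load_real_inputs(config)


def run_pipeline(config: RunConfig) -> VegetationRiskResults:
    """Run every stage in dependency order and write the output bundle."""
    model = build_model(config)
    results = model.fit()

    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir is None:
        return results
    outdir.mkdir(parents=True, exist_ok=True)

    written = results.to_csv(outdir)
    scenario = getattr(model, "_scenario", None)
    if scenario is not None:
        scenario.occurrences.to_csv(outdir / "occurrences_raw.csv", index=False)
        scenario.truth.to_csv(outdir / "true_niches.csv", index=False)
        scenario.injection_log.to_csv(outdir / "injection_log.csv", index=False)
        written["occurrences_raw"] = str(outdir / "occurrences_raw.csv")

    gdir = outdir / "grids"
    gdir.mkdir(exist_ok=True)
    write_ascii_grid(model.current["MAT"], gdir / "current_mat.asc")
    write_ascii_grid(model.current["MAP"], gdir / "current_map.asc")
    write_ascii_grid(
        median_anomaly(model.current["MAT"], [f["MAT"] for f in model.futures]),
        gdir / "anomaly_mat.asc",
    )
    write_ascii_grid(
        median_anomaly(model.current["MAP"], [f["MAP"] for f in model.futures]),
        gdir / "anomaly_map.asc",
    )
    if model.veg_map is not None:
        write_ascii_grid(model.veg_map, gdir / "veg_map.asc")

    # the saved config omits the output path: the bundle's location is
    # wherever it sits, and outputs stay byte-identical across re-runs
    saved = replace(config, output_dir=None)
    save_config(saved, outdir / "config.yaml")
    manifest = {
        "package": "vegrisk",
        "version": __version__,
        "seed": config.seed,
        "mode": "synthetic" if config.scenario is not None else "real",
        "row_counts": {
            "occurrences_raw": (len(scenario.occurrences)
                                 if scenario is not None else None),
            "occurrences_clean": len(results.clean_records),
            "species_niches": len(results.niches),
            "completeness": len(results.completeness),
            "risk_cells": len(results.cells),
            "null_results": len(results.null_results),
            "veg_summary": (len(results.veg_summary)
                             if results.veg_summary is not None else None),
        },
        "outputs": sorted(written),
        "log": results.log,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n"
    )
    return results
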