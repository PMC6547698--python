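"""Model/Results facade over the full analysis.

:class:`VegetationRiskModel` is built from data — an occurrence table,
current and future climate fields, optional lookups and a vegetation map —
and ``fit()`` runs the whole chain: QC, climate matching, limit
estimation, assemblage aggregation, completeness, safety margins,
exposure, risk, adaptive capacity, null-model z-scores, vegetation-class
summaries and the risk-capacity regressions.  The returned
:class:`VegetationRiskResults` carries every intermediate table, a
``summary()`` report, plotting helpers and CSV export.

    >>> scen = generate_scenario(ScenarioConfig(seed=1))
    >>> res = VegetationRiskModel.from_scenario(scen).fit()
    >>> print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import completeness as comp
from . import nullmodel, qc, risk as risk_mod, veg as veg_mod
from .config import RunConfig
from .grids import ClimateField, CoarseGrid, aggregate_to_coarse, median_anomaly, sample_climate
from .niche import estimate_limits
from .synthetic import Scenario

__all__ = ["VegetationRiskModel", "VegetationRiskResults"]


class VegetationRiskModel:
    """Climate-change risk model for gridded vegetation assemblages.

    Parameters
    ----------
    occurrences : DataFrame
        Raw occurrence table (Darwin-Core-aligned columns, see
        :data:`vegrisk.qc.REQUIRED_COLUMNS`).
    current : dict
        ``{"MAT": ClimateField, "MAP": ClimateField}`` long-term surfaces.
    futures : list of dict
        One ``{"MAT": ..., "MAP": ...}`` per GCM.
    accepted_names, exotic_names : set or None
        Name lookups for QC.
    veg_map : ClimateField or None
        Categorical vegetation raster on the fine grid.
    veg_class_names : dict or None
        Class code -> display name.
    config : RunConfig or None
        Method constants; defaults apply when omitted.
    """

    def __init__(
        self,
        occurrences: pd.DataFrame,
        current: dict[str, ClimateField],
        futures: list[dict[str, ClimateField]],
        accepted_names: set[str] | None = None,
        exotic_names: set[str] | None = None,
        veg_map: ClimateField | None = None,
        veg_class_names: dict[int, str] | None = None,
        config: RunConfig | None = None,
    ) -> None:
        self.occurrences = occurrences
        self.current = current
        self.futures = futures
        self.accepted_names = accepted_names
        self.exotic_names = exotic_names
        self.veg_map = veg_map
        self.veg_class_names = veg_class_names
        self.config = config or RunConfig(scenario=None, occurrences_path="<in-memory>")
        self.extent = current["MAT"].extent

    @classmethod
    def from_scenario(cls, scenario: Scenario, config: RunConfig | None = None
                      ) -> "VegetationRiskModel":
        cfg = config or RunConfig(scenario=scenario.config,
                                  seed=scenario.config.seed,
                                  coarse_edge=scenario.config.coarse_resolution)
        return cls(
            occurrences=scenario.occurrences,
            current=scenario.current,
            futures=scenario.futures,
            accepted_names=scenario.accepted_names,
            exotic_names=scenario.exotic_names,
            veg_map=scenario.veg_map,
            config=cfg,
        )

    # -- estimation ---------------------------------------------------------
    def fit(self) -> "VegetationRiskResults":
        cfg = self.config
        log: dict[str, int | float] = {}

        clean, report = qc.clean_occurrences(
            self.occurrences, self.accepted_names, self.exotic_names, self.extent
        )
        if len(clean) == 0:
            raise ValueError("no occurrence records survive quality control")

        x = clean["decimalLongitude"].to_numpy(float)
        y = clean["decimalLatitude"].to_numpy(float)
        mat_vals = sample_climate(self.current["MAT"], x, y)
        map_vals = sample_climate(self.current["MAP"], x, y)
        matched = pd.DataFrame(
            {"species": clean["species"].to_numpy(), "mat": mat_vals, "map": map_vals}
        )
        n_unmatched = int(matched[["mat", "map"]].isna().any(axis=1).sum())
        log["records_dropped_no_climate"] = n_unmatched

        niches = estimate_limits(
            matched, upper_pct=cfg.upper_pct, lower_pct=cfg.lower_pct,
            min_records=cfg.min_records,
        )

        grid = CoarseGrid.from_extent(self.extent, cfg.coarse_edge)
        cell_mat = aggregate_to_coarse(
            self.current["MAT"], grid, cfg.min_land_fraction
        ).set_index("cell_id")["value"]
        cell_map = aggregate_to_coarse(
            self.current["MAP"], grid, cfg.min_land_fraction
        ).set_index("cell_id")["value"]
        anom_mat_field = median_anomaly(self.current["MAT"],
                                        [f["MAT"] for f in self.futures])
        anom_map_field = median_anomaly(self.current["MAP"],
                                        [f["MAP"] for f in self.futures])
        anom_mat = aggregate_to_coarse(anom_mat_field, grid,
                                       cfg.min_land_fraction).set_index("cell_id")["value"]
        anom_map = aggregate_to_coarse(anom_map_field, grid,
                                       cfg.min_land_fraction).set_index("cell_id")["value"]

        assemblages = risk_mod.build_assemblages(clean, grid)
        cells = risk_mod.cell_risk_table(
            assemblages, niches, cell_mat, cell_map, anom_mat, anom_map
        )
        if len(cells) == 0:
            raise ValueError("no coarse cell carries both an assemblage and climate")

        completeness_tbl = comp.completeness_table(
            assemblages, threshold=cfg.completeness_threshold
        )
        passing, failing = comp.filter_cells(completeness_tbl,
                                             cfg.completeness_threshold)
        log["cells_completeness_passing"] = len(passing)
        log["cells_completeness_failing"] = len(failing)

        null_results = nullmodel.null_zscore_table(
            cells, niches, n_draws=cfg.n_draws, seed=cfg.seed,
            pool_constraint=cfg.pool_constraint,
        )
        joint = nullmodel.classify_cells(null_results, threshold=cfg.z_threshold)

        veg_summary = None
        if self.veg_map is not None:
            veg_summary = veg_mod.class_risk_summary(
                self.veg_map, grid, cells,
                excluded_codes=set(cfg.excluded_veg_codes),
                class_names=self.veg_class_names,
            )

        drying = {
            f: risk_mod.proportional_drying_fraction(cells, f)
            for f in cfg.proportional_fractions
        }

        reg_cells = cells[cells["cell_id"].isin(passing)]
        regressions = {}
        for var, (rc, ac) in {"MAT": ("risk_mat", "ac_mat"),
                              "MAP": ("risk_map", "ac_map")}.items():
            if len(reg_cells) >= 10:
                regressions[var] = risk_mod.risk_capacity_regression(
                    reg_cells, rc, ac, alpha=cfg.alpha
                )
            else:
                regressions[var] = None
                log.setdefault("regression_skipped_too_few_cells", len(reg_cells))

        return VegetationRiskResults(
            model=self,
            config=cfg,
            grid=grid,
            clean_records=clean,
            cleaning_report=report,
            niches=niches,
            completeness=completeness_tbl,
            completeness_passing=passing,
            cells=cells,
            null_results=null_results,
            joint_classification=joint,
            veg_summary=veg_summary,
            drying_fractions=drying,
            regressions=regressions,
            log=log,
        )


@dataclass
class VegetationRiskResults:
    """Fitted per-cell risk surfaces, species limits and diagnostics."""

    model: VegetationRiskModel
    config: RunConfig
    grid: CoarseGrid
    clean_records: pd.DataFrame
    cleaning_report: qc.CleaningReport
    niches: pd.DataFrame
    completeness: pd.DataFrame
    completeness_passing: list
    cells: pd.DataFrame
    null_results: pd.DataFrame
    joint_classification: pd.DataFrame
    veg_summary: pd.DataFrame | None
    drying_fractions: dict[float, float]
    regressions: dict[str, risk_mod.RegressionResult | None]
    log: dict = field(default_factory=dict)

    # -- headline shares (cell counts are areas on the equal-area grid) ----
    def share_at_risk(self, variable: str = "MAT") -> float:
        col = "at_risk_mat" if variable == "MAT" else "at_risk_map"
        return float(self.cells[col].mean()) if len(self.cells) else float("nan")

    def z_share(self, variable: str, side: str = "higher") -> float:
        sub = self.null_results[
            (self.null_results["variable"] == variable) & self.null_results["defined"]
        ]
        if len(sub) == 0:
            return float("nan")
        return float((sub["category"] == side).mean())

    def summary(self) -> str:
        c = self.cells
        lines = [
            "Vegetation climate-change risk analysis",
            "=" * 41,
            f"records in: {self.cleaning_report.n_input}; "
            f"cleaned: {self.cleaning_report.retained_after_dedup}",
            f"species with limits: {len(self.niches)}; "
            f"assemblage cells: {len(c)}",
            f"completeness >= {self.config.completeness_threshold}: "
            f"{len(self.completeness_passing)} cells",
            "",
            f"share of cells at risk (MAT): {100 * self.share_at_risk('MAT'):.1f}%",
            f"share of cells at risk (MAP): {100 * self.share_at_risk('MAP'):.1f}%",
            f"safety margin MAT range: {c['s_mat'].min():.2f} to "
            f"{c['s_mat'].max():.2f} degC",
            f"safety margin MAP range: {c['s_map'].min():.0f} to "
            f"{c['s_map'].max():.0f} mm",
        ]
        for f, share in sorted(self.drying_fractions.items()):
            lines.append(
                f"proportional {int(100 * f)}% MAP reduction exceeds the margin in "
                f"{100 * share:.1f}% of cells"
            )
        for var in ("MAT", "MAP"):
            lines.append(
                f"z-share larger than chance ({var}): "
                f"{100 * self.z_share(var, 'higher'):.1f}%; smaller: "
                f"{100 * self.z_share(var, 'lower'):.1f}%"
            )
        for var, reg in self.regressions.items():
            if reg is not None:
                lines.append("risk ~ adaptive capacity " + reg.summary_line())
        if self.veg_summary is not None and len(self.veg_summary):
            worst = self.veg_summary.sort_values(
                "pct_at_risk_mat", ascending=False).iloc[0]
            lines.append(
                f"most at-risk vegetation class (MAT): {worst['class_name']} "
                f"({worst['pct_at_risk_mat']:.1f}% of extent)"
            )
        return "\n".join(lines)

    # -- export -------------------------------------------------------------
    def to_csv(self, outdir: str | Path) -> dict[str, str]:
        """Write every result table as CSV; returns {name: path}."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = {}

        def _w(name: str, df: pd.DataFrame) -> None:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            written[name] = str(p)

        _w("occurrences_clean", self.clean_records)
        _w("cleaning_report", self.cleaning_report.to_frame())
        _w("species_niches", self.niches)
        _w("completeness", self.completeness)
        _w("risk_cells", self.cells)
        _w("null_results", self.null_results)
        _w("joint_classification", self.joint_classification)
        if self.veg_summary is not None:
            _w("veg_summary", self.veg_summary)
        reg = {
            var: None if r is None else {
                "params": [float(v) for v in r.params],
                "bse": [float(v) for v in r.bse],
                "r_squared": r.r_squared,
                "f_value": r.f_value,
                "df_model": r.df_model,
                "df_resid": r.df_resid,
                "p_value": r.p_value,
                "n": r.n,
                "alpha": r.alpha,
            }
            for var, r in self.regressions.items()
        }
        extra = {
            "drying_fractions": {str(k): v for k, v in self.drying_fractions.items()},
            "share_at_risk_mat": self.share_at_risk("MAT"),
            "share_at_risk_map": self.share_at_risk("MAP"),
            "regressions": reg,
            "log": self.log,
        }
        p = outdir / "summary_stats.json"
        p.write_text(json.dumps(extra, sort_keys=True, indent=1))
        written["summary_stats"] = str(p)
        (outdir / "summary.txt").write_text(self.summary() + "\n")
        written["summary"] = str(outdir / "summary.txt")
        return written

    # -- plotting -----------------------------------------------------------
    def _cell_raster(self, column: str) -> np.ndarray:
        arr = np.full((self.grid.nrows, self.grid.ncols), np.nan)
        for rec in self.cells.itertuples(index=False):
            r, c = divmod(int(rec.cell_id), self.grid.ncols)
            arr[r, c] = getattr(rec, column)
        return arr

    def plot_map(self, column: str = "risk_mat", ax=None):
        """Map a per-cell metric on the coarse grid (origin lower-left)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        arr = self._cell_raster(column)
        im = ax.imshow(arr, origin="lower", extent=(
            self.grid.x0, self.grid.x0 + self.grid.ncols * self.grid.edge,
            self.grid.y0, self.grid.y0 + self.grid.nrows * self.grid.edge,
        ))
        ax.set_title(column)
        ax.set_xlabel("x (km)")
        ax.set_ylabel("y (km)")
        plt.colorbar(im, ax=ax)
        return ax

    def plot_risk_capacity(self, variable: str = "MAT", ax=None):
        """Risk vs adaptive capacity with the display smoother.

        MAP risk is negated for display so drying tolerance deficits plot
        downward, matching the field's plotting convention.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rc, ac = (("risk_mat", "ac_mat") if variable == "MAT"
                  else ("risk_map", "ac_map"))
        sub = self.cells[self.cells["cell_id"].isin(self.completeness_passing)]
        sign = 1.0 if variable == "MAT" else -1.0
        ax.scatter(sub[ac], sign * sub[rc], s=12, alpha=0.6)
        reg = self.regressions.get(variable)
        if reg is not None:
            ax.plot(reg.lowess[:, 0], sign * reg.lowess[:, 1], color="k")
        ax.set_xlabel(f"adaptive capacity ({variable})")
        ax.set_ylabel(f"risk ({variable})")
        return ax
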