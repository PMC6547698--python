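"""Self-contained synthetic studies with known ground truth.

The generator emulates the shape of a continental herbarium-occurrence
analysis: a smooth, spatially autocorrelated climate (linear north-south
MAT gradient, east-west MAP gradient, plus a seeded Gaussian random field),
species with bounded climatic niches and disc-shaped geographic ranges,
heterogeneous per-cell collection effort, pseudo-GCM future surfaces, a
categorical vegetation map, and injected invalid records per contamination
category.  Every species' true upper MAT bound and lower MAP bound is
stored, so downstream stages can be tested by parameter recovery, and every
injected record carries its category label so QC removals can be audited
against the injection log.

Three generators cover the test designs:

* :func:`generate_scenario` — the standard bundle.
* :func:`generate_null_scenario` — per-cell species membership drawn at
  random from the climate-compatible pool, independent of limit values, so
  each observed safety margin is itself a draw from the constrained null;
  used to calibrate the false-positive rate of |z| >= 1.96.
* :func:`analytic_risk_scenario` — anomaly fields chosen against the
  generator's own brute-force per-cell medians so the at-risk set is known
  by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import ClimateField, CoarseGrid

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "NullScenario",
    "generate_scenario",
    "generate_null_scenario",
    "analytic_risk_scenario",
    "sample_matched_values",
    "INJECTION_CRITERION",
]

#: injection category -> QC criterion it must trip ("duplicate" is collapsed
#: by dedup rather than removed by a criterion)
INJECTION_CRITERION = {
    "invalid_name": "invalid_name",
    "missing_coords": "bad_coordinates",
    "out_of_extent": "bad_coordinates",
    "outlier": "outlier",
    "cultivated": "cultivated",
    "exotic": "exotic",
    "non_specimen": "non_specimen",
    "duplicate": None,
}

_COLLECTORS = [f"Collector {chr(65 + i)}." for i in range(24)]


def _default_contamination() -> dict[str, float]:
    return {
        "invalid_name": 0.01,
        "missing_coords": 0.02,
        "out_of_extent": 0.01,
        "outlier": 0.01,
        "cultivated": 0.02,
        "exotic": 0.03,
        "non_specimen": 0.01,
        "duplicate": 0.05,
    }


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Distances are km in an equal-area projection; the default extent gives
    an 8 x 8 grid of 100-km assemblage cells over an 80 x 80 fine climate
    grid.  Contamination rates are fractions of the valid record count
    injected per category.
    """

    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 800.0, 800.0)
    fine_resolution: float = 10.0
    coarse_resolution: float = 100.0
    n_species: int = 120
    mat_range: tuple[float, float] = (12.0, 30.0)
    map_range: tuple[float, float] = (200.0, 1800.0)
    mat_noise_sd: float = 0.5
    map_noise_sd: float = 50.0
    noise_correlation_km: float = 50.0
    disc_radius_km: tuple[float, float] = (80.0, 250.0)
    mat_bound_quantile: tuple[float, float] = (0.55, 0.95)
    map_bound_quantile: tuple[float, float] = (0.05, 0.45)
    effort_per_cell: float = 0.5
    effort_lognorm_sd: float = 1.8
    contamination_rates: dict[str, float] = field(default_factory=_default_contamination)
    n_gcms: int = 5
    warming_mean: float = 2.8
    warming_spread: float = 0.5
    dmap_mean: float = -40.0
    dmap_spread: float = 90.0
    n_veg_classes: int = 8
    null_richness: tuple[int, int] = (15, 30)  # inclusive range, null scenarios

    def validate(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("degenerate extent: zero or negative area")
        grid = CoarseGrid.from_extent(self.extent, self.coarse_resolution)
        if grid.n_cells < 4:
            raise ValueError("extent must hold at least 4 coarse cells")
        for k, v in self.contamination_rates.items():
            if k not in INJECTION_CRITERION:
                raise ValueError(f"unknown contamination category {k!r}")
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"contamination rate {k}={v} outside [0, 1]")
        if sum(self.contamination_rates.values()) > 0.95:
            raise ValueError("contamination rates sum beyond feasibility (>0.95)")
        if self.n_gcms < 1:
            raise ValueError("n_gcms must be >= 1")
        if self.fine_resolution <= 0 or self.coarse_resolution <= 0:
            raise ValueError("resolutions must be positive")

    @property
    def coarse_grid(self) -> CoarseGrid:
        return CoarseGrid.from_extent(self.extent, self.coarse_resolution)


@dataclass
class Scenario:
    """Bundle produced by :func:`generate_scenario`."""

    config: ScenarioConfig
    occurrences: pd.DataFrame  # contaminated table, `injected_category` label column
    current: dict[str, ClimateField]  # {"MAT": ..., "MAP": ...}
    futures: list[dict[str, ClimateField]]  # one dict per pseudo-GCM
    veg_map: ClimateField
    truth: pd.DataFrame  # species, true_upper_mat, true_lower_map, n_occupied_cells
    injection_log: pd.DataFrame  # category, count
    accepted_names: set[str]
    exotic_names: set[str]
    occupancy: dict[str, np.ndarray]  # species -> fine-grid bool mask

    @property
    def coarse_grid(self) -> CoarseGrid:
        return self.config.coarse_grid

    @property
    def valid_records(self) -> pd.DataFrame:
        """The generator's truth log: rows that should survive QC."""
        return self.occurrences[self.occurrences["injected_category"] == ""].copy()


@dataclass
class NullScenario:
    """Bundle from :func:`generate_null_scenario`.

    ``cells`` already carries observed margins in the shape the null model
    consumes (cell_id, richness, mat, map, s_mat, s_map).
    """

    config: ScenarioConfig
    cells: pd.DataFrame
    assemblages: pd.DataFrame  # cell_id, species, n_records
    niches: pd.DataFrame  # species, upper_mat_limit, lower_map_limit, breadths
    occurrences: pd.DataFrame
    current: dict[str, ClimateField]
    futures: list[dict[str, ClimateField]]


# ---------------------------------------------------------------------------
# climate surfaces


def _gaussian_field(rng: np.random.Generator, shape: tuple[int, int],
                    sigma_cells: float, sd: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=max(sigma_cells, 1e-6), mode="nearest")
    s = smooth.std()
    if s > 0:
        smooth = smooth / s
    return smooth * sd


def _current_fields(cfg: ScenarioConfig, rng: np.random.Generator
                    ) -> dict[str, ClimateField]:
    xmin, ymin, xmax, ymax = cfg.extent
    nx = int(round((xmax - xmin) / cfg.fine_resolution))
    ny = int(round((ymax - ymin) / cfg.fine_resolution))
    ys = (np.arange(ny) + 0.5) / ny
    xs = (np.arange(nx) + 0.5) / nx
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    sigma = cfg.noise_correlation_km / cfg.fine_resolution

    mat_lo, mat_hi = cfg.mat_range
    mat = mat_hi - (mat_hi - mat_lo) * yy  # hot south edge -> cool north edge
    mat = mat + _gaussian_field(rng, (ny, nx), sigma, cfg.mat_noise_sd)

    map_lo, map_hi = cfg.map_range
    mp = map_lo + (map_hi - map_lo) * xx  # dry west edge -> wet east edge
    mp = mp + _gaussian_field(rng, (ny, nx), sigma, cfg.map_noise_sd)
    mp = np.clip(mp, 1.0, None)

    mk = lambda v, var: ClimateField(v, x0=xmin, y0=ymin, cell=cfg.fine_resolution,
                                     variable=var, epoch="current")
    return {"MAT": mk(mat, "MAT"), "MAP": mk(mp, "MAP")}


def _future_fields(cfg: ScenarioConfig, rng: np.random.Generator,
                   current: dict[str, ClimateField]
                   ) -> list[dict[str, ClimateField]]:
    ny, nx = current["MAT"].values.shape
    sigma = cfg.noise_correlation_km / cfg.fine_resolution
    n = cfg.n_gcms
    # symmetric per-GCM offsets so the ensemble median tracks the mean change
    mat_offsets = np.linspace(-cfg.warming_spread, cfg.warming_spread, n)
    map_offsets = np.linspace(-cfg.dmap_spread, cfg.dmap_spread, n)
    futures = []
    for g in range(n):
        d_mat = (cfg.warming_mean + mat_offsets[g]
                 + _gaussian_field(rng, (ny, nx), sigma, 0.3))
        d_map = (cfg.dmap_mean + map_offsets[g]
                 + _gaussian_field(rng, (ny, nx), sigma, 40.0))
        label = f"future:gcm{g + 1:02d}"
        futures.append({
            "MAT": current["MAT"].copy_with(current["MAT"].values + d_mat, epoch=label),
            "MAP": current["MAP"].copy_with(
                np.clip(current["MAP"].values + d_map, 0.0, None), epoch=label),
        })
    return futures


def _veg_field(cfg: ScenarioConfig, rng: np.random.Generator,
               template: ClimateField) -> ClimateField:
    # nearest-seed (Voronoi) patches of integer class codes 1..n
    ny, nx = template.values.shape
    k = max(cfg.n_veg_classes, 1)
    sx = rng.uniform(0, nx, size=k)
    sy = rng.uniform(0, ny, size=k)
    cols, rows_ = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5)
    d2 = (cols[..., None] - sx) ** 2 + (rows_[..., None] - sy) ** 2
    classes = np.argmin(d2, axis=-1) + 1.0
    return template.copy_with(classes, variable="VEG", epoch="current")


# ---------------------------------------------------------------------------
# species, records, contamination


def _quantile(sorted_vals: np.ndarray, q: float) -> float:
    # own linear-interpolation quantile so generator truth does not lean on
    # the estimation path
    n = sorted_vals.size
    h = (n - 1) * q
    lo = int(math.floor(h))
    hi = min(lo + 1, n - 1)
    return float(sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo]))


def _make_species(cfg: ScenarioConfig, rng: np.random.Generator,
                  mat: np.ndarray, mp: np.ndarray
                  ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    xmin, ymin, xmax, ymax = cfg.extent
    ny, nx = mat.shape
    xg = xmin + (np.arange(nx) + 0.5) * cfg.fine_resolution
    yg = ymin + (np.arange(ny) + 0.5) * cfg.fine_resolution
    xx, yy = np.meshgrid(xg, yg)

    rows = []
    occupancy: dict[str, np.ndarray] = {}
    i = 0
    attempts = 0
    while i < cfg.n_species:
        attempts += 1
        if attempts > 200 * cfg.n_species:
            raise RuntimeError(
                "could not place species ranges under this config "
                "(extent/disc radius/bound quantiles leave too few occupiable cells)"
            )
        cx = rng.uniform(xmin, xmax)
        cy = rng.uniform(ymin, ymax)
        r = rng.uniform(*cfg.disc_radius_km)
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        if disc.sum() < 30:
            continue
        disc_mat = np.sort(mat[disc])
        disc_map = np.sort(mp[disc])
        upper = _quantile(disc_mat, rng.uniform(*cfg.mat_bound_quantile))
        lower = _quantile(disc_map, rng.uniform(*cfg.map_bound_quantile))
        occ = disc & (mat <= upper) & (mp >= lower)
        if occ.sum() < 10:
            continue
        name = f"Simulatus species{i + 1:04d}"
        occupancy[name] = occ
        rows.append({
            "species": name,
            "true_upper_mat": upper,
            "true_lower_map": lower,
            "n_occupied_cells": int(occ.sum()),
        })
        i += 1
    return pd.DataFrame(rows), occupancy


def _effort_multipliers(cfg: ScenarioConfig, rng: np.random.Generator,
                        grid: CoarseGrid) -> np.ndarray:
    sd = cfg.effort_lognorm_sd
    return rng.lognormal(mean=-0.5 * sd * sd, sigma=sd, size=grid.n_cells)


def _sample_valid_records(cfg: ScenarioConfig, rng: np.random.Generator,
                          occupancy: dict[str, np.ndarray],
                          grid: CoarseGrid) -> pd.DataFrame:
    xmin, ymin, _, _ = cfg.extent
    effort = _effort_multipliers(cfg, rng, grid)
    recs: dict[str, list] = {k: [] for k in
                             ("species", "decimalLongitude", "decimalLatitude")}
    for name, occ in occupancy.items():
        ridx, cidx = np.nonzero(occ)
        cell_x = xmin + (cidx + 0.5) * cfg.fine_resolution
        cell_y = ymin + (ridx + 0.5) * cfg.fine_resolution
        coarse = grid.cell_of(cell_x, cell_y)
        lam = cfg.effort_per_cell * effort[coarse]
        counts = rng.poisson(lam)
        nz = counts > 0
        reps = counts[nz]
        base_x = xmin + cidx[nz] * cfg.fine_resolution
        base_y = ymin + ridx[nz] * cfg.fine_resolution
        n = int(reps.sum())
        if n == 0:
            continue
        jitter_x = rng.random(n)
        jitter_y = rng.random(n)
        recs["species"].extend([name] * n)
        recs["decimalLongitude"].extend(
            np.repeat(base_x, reps) + jitter_x * cfg.fine_resolution)
        recs["decimalLatitude"].extend(
            np.repeat(base_y, reps) + jitter_y * cfg.fine_resolution)
    n_total = len(recs["species"])
    df = pd.DataFrame(recs)
    df["year"] = rng.integers(1950, 2016, size=n_total)
    df["month"] = rng.integers(1, 13, size=n_total)
    df["recordedBy"] = rng.choice(_COLLECTORS, size=n_total)
    df["basisOfRecord"] = "PreservedSpecimen"
    df["outlier_flag"] = False
    df["cultivated_flag"] = False
    df["free_text"] = ""
    df["injected_category"] = ""
    return df


def _fresh_rows(cfg: ScenarioConfig, rng: np.random.Generator, n: int,
                species_pool: list[str]) -> pd.DataFrame:
    """Template rows that pass every criterion except the one injected."""
    xmin, ymin, xmax, ymax = cfg.extent
    return pd.DataFrame({
        "species": rng.choice(species_pool, size=n),
        "decimalLongitude": rng.uniform(xmin, xmax, size=n),
        "decimalLatitude": rng.uniform(ymin, ymax, size=n),
        "year": rng.integers(1950, 2016, size=n),
        "month": rng.integers(1, 13, size=n),
        "recordedBy": rng.choice(_COLLECTORS, size=n),
        "basisOfRecord": "PreservedSpecimen",
        "outlier_flag": False,
        "cultivated_flag": False,
        "free_text": "",
        "injected_category": "",
    })


def _inject_contamination(cfg: ScenarioConfig, rng: np.random.Generator,
                          valid: pd.DataFrame, species_pool: list[str],
                          exotic_names: list[str]
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    xmin, ymin, xmax, ymax = cfg.extent
    n_valid = len(valid)
    parts = [valid]
    log_rows = []
    for cat, rate in cfg.contamination_rates.items():
        n = int(round(rate * n_valid))
        log_rows.append({"category": cat, "count": n})
        if n == 0:
            continue
        if cat == "duplicate":
            # verbatim copies of distinct valid rows: each collapses by one
            src = rng.choice(n_valid, size=min(n, n_valid), replace=False)
            rows = valid.iloc[np.sort(src)].copy()
        else:
            rows = _fresh_rows(cfg, rng, n, species_pool)
            if cat == "invalid_name":
                rows["species"] = [f"Unratified taxon{j + 1:03d}" for j in range(n)]
            elif cat == "missing_coords":
                half = n // 2
                rows.iloc[:half, rows.columns.get_loc("decimalLatitude")] = np.nan
                rows.iloc[half:, rows.columns.get_loc("decimalLongitude")] = np.nan
            elif cat == "out_of_extent":
                rows["decimalLongitude"] = xmax + rng.uniform(10, 200, size=n)
            elif cat == "outlier":
                rows["outlier_flag"] = True
            elif cat == "cultivated":
                texts = ["Botanic Gardens, cultivated specimen",
                         "ex garden bed, suburban planting",
                         "Cultivated in nursery"]
                rows["free_text"] = rng.choice(texts, size=n)
            elif cat == "exotic":
                rows["species"] = rng.choice(exotic_names, size=n)
            elif cat == "non_specimen":
                rows["basisOfRecord"] = "HumanObservation"
        rows = rows.copy()
        rows["injected_category"] = cat
        parts.append(rows)
    table = pd.concat(parts, ignore_index=True)
    perm = rng.permutation(len(table))
    table = table.iloc[perm].reset_index(drop=True)
    table.insert(0, "record_id", np.arange(len(table)))
    return table, pd.DataFrame(log_rows)


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate the full synthetic bundle; bit-identical for a given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    current = _current_fields(config, rng)
    futures = _future_fields(config, rng, current)
    veg = _veg_field(config, rng, current["MAT"])
    truth, occupancy = _make_species(config, rng,
                                     current["MAT"].values, current["MAP"].values)
    grid = config.coarse_grid
    valid = _sample_valid_records(config, rng, occupancy, grid)
    species_pool = truth["species"].tolist()
    exotic_names = [f"Exoticus weedii{j + 1:03d}" for j in range(20)]
    occ_table, log = _inject_contamination(config, rng, valid, species_pool,
                                           exotic_names)
    # the accepted-names authority covers natives and naturalised exotics;
    # exotics are removed by the origin criterion, not the name criterion
    accepted = set(species_pool) | set(exotic_names)
    return Scenario(
        config=config,
        occurrences=occ_table,
        current=current,
        futures=futures,
        veg_map=veg,
        truth=truth,
        injection_log=log,
        accepted_names=accepted,
        exotic_names=set(exotic_names),
        occupancy=occupancy,
    )


# ---------------------------------------------------------------------------
# controlled record sampling for parameter-recovery designs


def sample_matched_values(scenario: Scenario, n_per_species: int,
                          seed: int) -> pd.DataFrame:
    """Matched climate values with a fixed record count per species.

    Draws ``n_per_species`` occupied fine cells per species (with
    replacement, uniform over the species' occupied cells) and returns the
    (species, mat, map) value table the limit estimator consumes — the
    design used to study how limit-recovery error scales with sample size.
    """
    rng = np.random.default_rng(seed)
    mat = scenario.current["MAT"].values
    mp = scenario.current["MAP"].values
    frames = []
    for name, occ in scenario.occupancy.items():
        ridx, cidx = np.nonzero(occ)
        pick = rng.integers(0, ridx.size, size=n_per_species)
        frames.append(pd.DataFrame({
            "species": name,
            "mat": mat[ridx[pick], cidx[pick]],
            "map": mp[ridx[pick], cidx[pick]],
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# null scenario


def generate_null_scenario(config: ScenarioConfig) -> NullScenario:
    """Assemblages whose membership is random with respect to limit values.

    Species limits are assigned independently of geography; each cell's
    members are drawn uniformly, without replacement, from the pool of
    species whose upper MAT limit is compatible with the cell (lower MAP
    limits are placed below every cell's MAP, and independently of the MAT
    limits, so the same exchangeability holds for both variables).  The
    observed safety margin of every cell is then a draw from the very null
    the z-score machinery builds, which is what calibrating the
    false-positive rate requires.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    current = _current_fields(config, rng)
    futures = _future_fields(config, rng, current)
    grid = config.coarse_grid

    # long-term coarse climate (generator-side block means)
    mat_f, map_f = current["MAT"], current["MAP"]
    xg, yg = np.meshgrid(mat_f.x_centers(), mat_f.y_centers())
    cid = grid.cell_of(xg.ravel(), yg.ravel())
    n_per = np.bincount(cid, minlength=grid.n_cells)
    cell_mat = np.bincount(cid, weights=mat_f.values.ravel(),
                           minlength=grid.n_cells) / np.maximum(n_per, 1)
    cell_map = np.bincount(cid, weights=map_f.values.ravel(),
                           minlength=grid.n_cells) / np.maximum(n_per, 1)
    live = n_per > 0

    # species pool: enough limits above the hottest cell that every cell's
    # compatible pool exceeds the richest assemblage
    n_sp = config.n_species
    max_mat, min_mat = float(cell_mat[live].max()), float(cell_mat[live].min())
    n_high = max(int(0.4 * n_sp), config.null_richness[1] + 5)
    upper = np.concatenate([
        rng.uniform(max_mat, max_mat + 3.0, size=n_high),
        rng.uniform(min_mat, max_mat, size=n_sp - n_high),
    ])
    upper = rng.permutation(upper)
    lower = rng.uniform(0.0, 0.9 * float(cell_map[live].min()), size=n_sp)
    names = [f"Nullius species{i + 1:04d}" for i in range(n_sp)]
    niches = pd.DataFrame({
        "species": names,
        "upper_mat_limit": upper,
        "lower_map_limit": lower,
        "mat_breadth": rng.uniform(2.0, 10.0, size=n_sp),
        "map_breadth": rng.uniform(150.0, 1500.0, size=n_sp),
        "n_records": 1,
    })

    lo_r, hi_r = config.null_richness
    cell_rows, asm_rows, occ_rows = [], [], []
    xmin, ymin, _, _ = config.extent
    for c in np.nonzero(live)[0]:
        k = int(rng.integers(lo_r, hi_r + 1))
        pool = np.nonzero(upper >= cell_mat[c])[0]
        if pool.size < k:  # cannot occur under the default pool mix
            k = pool.size
        members = rng.choice(pool, size=k, replace=False)
        s_mat = float(np.median(upper[members])) - cell_mat[c]
        s_map = cell_map[c] - float(np.median(lower[members]))
        cell_rows.append({"cell_id": int(c), "richness": k,
                          "mat": cell_mat[c], "map": cell_map[c],
                          "s_mat": s_mat, "s_map": s_map})
        row, col = divmod(int(c), grid.ncols)
        for m in members:
            asm_rows.append({"cell_id": int(c), "species": names[m], "n_records": 2})
            x = xmin + (col + rng.random()) * grid.edge
            y = ymin + (row + rng.random()) * grid.edge
            occ_rows.append({"species": names[m], "decimalLongitude": x,
                             "decimalLatitude": y})
    occurrences = pd.DataFrame(occ_rows)
    occurrences["year"] = rng.integers(1950, 2016, size=len(occurrences))
    occurrences["month"] = rng.integers(1, 13, size=len(occurrences))
    occurrences["recordedBy"] = rng.choice(_COLLECTORS, size=len(occurrences))
    occurrences["basisOfRecord"] = "PreservedSpecimen"
    occurrences["outlier_flag"] = False
    occurrences["cultivated_flag"] = False
    occurrences["free_text"] = ""
    occurrences["injected_category"] = ""
    return NullScenario(
        config=config,
        cells=pd.DataFrame(cell_rows),
        assemblages=pd.DataFrame(asm_rows),
        niches=niches,
        occurrences=occurrences,
        current=current,
        futures=futures,
    )


# ---------------------------------------------------------------------------
# analytic at-risk construction


def analytic_risk_scenario(config: ScenarioConfig, n_at_risk: int,
                           margin: float = 1.0) -> tuple[Scenario, set[int]]:
    """Scenario whose MAT at-risk cell set is known by construction.

    The generator recomputes, by brute force from its own record log (not
    through the analysis modules), each coarse cell's reference safety
    margin — the median across present species of the 98th-percentile MAT
    of that species' record-matched values, minus the cell's mean MAT — and
    then builds future layers whose ensemble-median warming in a chosen set
    K of cells exceeds the reference margin by ``margin`` degC, and falls
    short of it by the same amount everywhere else.  MAP futures are mildly
    wetting, so no drying risk arises.  Returns the scenario and K.
    """
    scen = generate_scenario(config)
    cfg = scen.config
    grid = cfg.coarse_grid
    mat_field = scen.current["MAT"]
    xmin, ymin, _, _ = cfg.extent

    valid = scen.valid_records
    # record -> fine-cell MAT via the generator's own floor arithmetic
    col = np.floor((valid["decimalLongitude"].to_numpy(float) - xmin)
                   / cfg.fine_resolution).astype(int)
    row = np.floor((valid["decimalLatitude"].to_numpy(float) - ymin)
                   / cfg.fine_resolution).astype(int)
    rec_mat = mat_field.values[row, col]
    rec_cell = grid.cell_of(valid["decimalLongitude"].to_numpy(float),
                            valid["decimalLatitude"].to_numpy(float))

    per_species: dict[str, float] = {}
    for sp, vals in pd.Series(rec_mat).groupby(valid["species"].to_numpy()):
        per_species[sp] = _quantile(np.sort(vals.to_numpy()), 0.98)

    # coarse-cell mean MAT over all fine cells
    xg, yg = np.meshgrid(mat_field.x_centers(), mat_field.y_centers())
    cid = grid.cell_of(xg.ravel(), yg.ravel())
    n_per = np.bincount(cid, minlength=grid.n_cells)
    cell_mat = np.bincount(cid, weights=mat_field.values.ravel(),
                           minlength=grid.n_cells) / np.maximum(n_per, 1)

    ref_margin: dict[int, float] = {}
    df = pd.DataFrame({"cell": rec_cell, "species": valid["species"].to_numpy()})
    for c, grp in df[df["cell"] >= 0].groupby("cell"):
        limits = np.array(sorted(per_species[s] for s in grp["species"].unique()))
        ref_margin[int(c)] = float(np.median(limits)) - cell_mat[int(c)]

    rng = np.random.default_rng(cfg.seed + 1)
    cells = sorted(ref_margin)
    if n_at_risk > len(cells):
        raise ValueError("n_at_risk exceeds the number of assembled cells")
    at_risk = set(int(c) for c in rng.choice(cells, size=n_at_risk, replace=False))

    delta_coarse = np.zeros(grid.n_cells)
    for c in cells:
        delta_coarse[c] = ref_margin[c] + (margin if c in at_risk else -margin)
    # broadcast the per-coarse-cell warming to the fine grid
    delta_fine = delta_coarse[cid].reshape(mat_field.values.shape)

    offsets = np.linspace(-0.2, 0.2, cfg.n_gcms)  # symmetric: ensemble median 0
    futures = []
    for g in range(cfg.n_gcms):
        label = f"future:gcm{g + 1:02d}"
        futures.append({
            "MAT": mat_field.copy_with(mat_field.values + delta_fine + offsets[g],
                                       epoch=label),
            "MAP": scen.current["MAP"].copy_with(
                scen.current["MAP"].values + 10.0, epoch=label),
        })
    return replace(scen, futures=futures), at_risk
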