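"""Safety margins, exposure, risk, adaptive capacity and their relationship.

Each 100 km equal-area cell carries an assemblage (the species with at
least one cleaned record inside it) and long-term MAT/MAP.  The safety
margin is the distance from the cell's long-term climate to the observed
limit of its median — "typical" — species:

    S_MAT = median(upper MAT limits) - cell MAT      [degC of headroom]
    S_MAP = cell MAP - median(lower MAP limits)      [mm of headroom]

Exposure is the projected change: E_MAT is the median MAT anomaly across
GCMs; drying exposure E_dry = max(0, -median MAP anomaly) (projected
wetting carries no drying exposure).  Risk = E - S, and a cell is at risk
when exposure strictly exceeds its safety margin.  Adaptive capacity is
the median climatic breadth of the species present.  Internally both
risk values are positive-when-at-risk; display layers may negate the MAP
risk so that tolerance deficits for drying plot downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import ClimateField, CoarseGrid, aggregate_to_coarse, median_anomaly

__all__ = [
    "build_assemblages",
    "cell_risk_table",
    "safety_margins",
    "exposure",
    "risk",
    "adaptive_capacity",
    "proportional_drying_fraction",
    "risk_capacity_regression",
    "RegressionResult",
]


def build_assemblages(
    records: pd.DataFrame,
    grid: CoarseGrid,
) -> pd.DataFrame:
    """Species membership and record counts per coarse cell.

    ``records`` needs ``species``, ``decimalLongitude``, ``decimalLatitude``
    (projected km in synthetic runs).  Returns one row per (cell_id,
    species) with ``n_records``; records falling outside the grid are
    dropped.
    """
    cid = grid.cell_of(
        records["decimalLongitude"].to_numpy(float),
        records["decimalLatitude"].to_numpy(float),
    )
    df = pd.DataFrame({"cell_id": cid, "species": records["species"].to_numpy()})
    df = df[df["cell_id"] >= 0]
    out = (
        df.groupby(["cell_id", "species"], sort=True)
        .size()
        .rename("n_records")
        .reset_index()
    )
    return out


def _median(values: np.ndarray) -> float:
    # even count -> mean of the two central values
    return float(np.median(values))


def safety_margins(
    species: np.ndarray, niches: pd.DataFrame, cell_mat: float, cell_map: float
) -> tuple[float, float, int]:
    """(S_MAT, S_MAP, n_species_used) for one cell.

    Species absent from the niche table are skipped (callers log them); a
    cell whose species all lack niche rows is excluded upstream.
    """
    nid = niches.set_index("species") if niches.index.name != "species" else niches
    present = nid.reindex(pd.Index(np.unique(species))).dropna(
        subset=["upper_mat_limit", "lower_map_limit"]
    )
    if len(present) == 0:
        raise ValueError("no species in this cell has a niche row")
    s_mat = _median(present["upper_mat_limit"].to_numpy(float)) - cell_mat
    s_map = cell_map - _median(present["lower_map_limit"].to_numpy(float))
    return s_mat, s_map, len(present)


def adaptive_capacity(
    species: np.ndarray, niches: pd.DataFrame
) -> tuple[float, float]:
    """Median MAT and MAP breadth across the species present (AC_MAT, AC_MAP)."""
    nid = niches.set_index("species") if niches.index.name != "species" else niches
    present = nid.reindex(pd.Index(np.unique(species))).dropna(
        subset=["mat_breadth", "map_breadth"]
    )
    if len(present) == 0:
        raise ValueError("no species in this cell has a niche row")
    return (
        _median(present["mat_breadth"].to_numpy(float)),
        _median(present["map_breadth"].to_numpy(float)),
    )


def exposure(d_mat: float, d_map: float) -> tuple[float, float]:
    """(E_MAT, E_dry) from median anomalies.

    Drying exposure is the magnitude of a projected MAP decrease; projected
    wetting clamps to zero.
    """
    e_mat = float(d_mat)
    e_dry = float(-d_map) if d_map < 0 else 0.0
    return e_mat, e_dry


def risk(s: float, e: float) -> tuple[float, bool]:
    """Risk = E - S; at risk iff exposure strictly exceeds the margin."""
    r = e - s
    return r, e > s


def cell_risk_table(
    assemblages: pd.DataFrame,
    niches: pd.DataFrame,
    cell_mat: pd.Series,
    cell_map: pd.Series,
    anomaly_mat: pd.Series,
    anomaly_map: pd.Series,
) -> pd.DataFrame:
    """Per-cell risk metrics for every cell with climate, anomaly and niches.

    Parameters
    ----------
    assemblages : DataFrame
        (cell_id, species, n_records) rows from :func:`build_assemblages`.
    niches : DataFrame
        Output of :func:`vegrisk.niche.estimate_limits`.
    cell_mat, cell_map, anomaly_mat, anomaly_map : Series
        Indexed by cell_id: long-term climate and median anomalies on the
        coarse grid.

    Cells missing climate or anomaly values, and cells whose species all
    lack niche rows, are dropped (not zero-filled).
    """
    nid = niches.set_index("species")
    rows = []
    for cid, grp in assemblages.groupby("cell_id", sort=True):
        if cid not in cell_mat.index or cid not in anomaly_mat.index:
            continue
        cm, cp = cell_mat.loc[cid], cell_map.loc[cid]
        dm, dp = anomaly_mat.loc[cid], anomaly_map.loc[cid]
        if not np.all(np.isfinite([cm, cp, dm, dp])):
            continue
        sp = grp["species"].to_numpy()
        present = nid.reindex(pd.Index(np.unique(sp))).dropna(
            subset=["upper_mat_limit", "lower_map_limit"]
        )
        if len(present) == 0:
            continue
        s_mat = _median(present["upper_mat_limit"].to_numpy(float)) - cm
        s_map = cp - _median(present["lower_map_limit"].to_numpy(float))
        ac_mat = _median(present["mat_breadth"].to_numpy(float))
        ac_map = _median(present["map_breadth"].to_numpy(float))
        e_mat, e_dry = exposure(dm, dp)
        r_mat, at_mat = risk(s_mat, e_mat)
        r_map, at_map = risk(s_map, e_dry)
        rows.append(
            {
                "cell_id": cid,
                "richness": len(present),
                "mat": cm,
                "map": cp,
                "s_mat": s_mat,
                "s_map": s_map,
                "e_mat": e_mat,
                "e_dry": e_dry,
                "risk_mat": r_mat,
                "risk_map": r_map,
                "at_risk_mat": at_mat,
                "at_risk_map": at_map,
                "ac_mat": ac_mat,
                "ac_map": ac_map,
            }
        )
    return pd.DataFrame(rows)


def proportional_drying_fraction(cells: pd.DataFrame, fraction: float) -> float:
    """Share of cells whose MAP safety margin is exceeded by a proportional
    MAP reduction of ``fraction`` (S_MAP < fraction * cell MAP)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    if len(cells) == 0:
        return 0.0
    hit = cells["s_map"] < fraction * cells["map"]
    return float(hit.mean())


@dataclass
class RegressionResult:
    """Quadratic OLS of risk on adaptive capacity, with a display smoother."""

    variable: str
    params: np.ndarray  # intercept, linear, quadratic
    bse: np.ndarray
    r_squared: float
    f_value: float
    df_model: int
    df_resid: int
    p_value: float
    n: int
    alpha: float
    lowess: np.ndarray  # (k, 2) smoothed curve for plotting only

    def summary_line(self) -> str:
        return (
            f"{self.variable}: R^2 = {self.r_squared:.2f}, "
            f"F({self.df_model},{self.df_resid}) = {self.f_value:.1f}, "
            f"p = {self.p_value:.3g}, n = {self.n} (alpha = {self.alpha})"
        )


def risk_capacity_regression(
    cells: pd.DataFrame,
    risk_col: str = "risk_mat",
    capacity_col: str = "ac_mat",
    alpha: float = 0.05,
) -> RegressionResult:
    """Curvilinear (quadratic) OLS of per-cell risk on adaptive capacity.

    Run on the completeness-passing subset of cells.  Two slope terms give
    the df pattern (2, n-3).  A LOWESS smoother over the same points is
    returned for display only.
    """
    if len(cells) < 10:
        raise ValueError("regression requires at least 10 cells")
    x = cells[capacity_col].to_numpy(float)
    y = cells[risk_col].to_numpy(float)
    X = sm.add_constant(np.column_stack([x, x**2]))
    fit = sm.OLS(y, X).fit()
    smooth = sm.nonparametric.lowess(y, x, frac=0.6)
    return RegressionResult(
        variable=risk_col,
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
        r_squared=float(fit.rsquared),
        f_value=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
        n=len(y),
        alpha=alpha,
        lowess=np.asarray(smooth),
    )
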