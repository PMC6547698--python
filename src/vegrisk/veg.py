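"""Vegetation-class risk summaries.

Overlays a categorical vegetation map (fine-grid raster of class codes) on
the at-risk classification of the coarse assemblage grid and reports, per
class, total mapped area and the share of that area falling in at-risk
cells — the analogue of a per-vegetation-group risk table.  Because both
grids are equal-area, fine-cell counts are areas, and the intersection is
area-weighted by construction (a class partially overlapping an at-risk
coarse cell contributes only the overlapping fine cells).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .grids import ClimateField, CoarseGrid

__all__ = ["class_risk_summary"]


def class_risk_summary(
    veg_map: ClimateField,
    grid: CoarseGrid,
    risk_cells: pd.DataFrame,
    excluded_codes: set[int] | None = None,
    class_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-class extent and percentage at risk (MAT and MAP).

    Parameters
    ----------
    veg_map : ClimateField
        Fine-grid raster of integer class codes (NaN = unmapped).
    grid : CoarseGrid
        The assemblage grid carrying the risk classification.
    risk_cells : DataFrame
        Needs ``cell_id``, ``at_risk_mat``, ``at_risk_map``.  Coarse cells
        absent from the table (no assemblage) count as not at risk.
    excluded_codes : set of int
        Class codes dropped before percentages are computed (non-vegetation
        categories); a listed code absent from the map warns, not errors.
    class_names : dict
        Optional code -> name lookup for the output table.

    Returns
    -------
    DataFrame with columns ``class_code``, ``class_name``, ``n_fine_cells``,
    ``area_share_pct``, ``pct_at_risk_mat``, ``pct_at_risk_map``.  The
    denominator of each class's at-risk percentage is its own total mapped
    extent after exclusions.
    """
    excluded_codes = set(excluded_codes or ())
    class_names = class_names or {}

    xs = veg_map.x_centers()
    ys = veg_map.y_centers()
    xg, yg = np.meshgrid(xs, ys)
    cell_ids = grid.cell_of(xg.ravel(), yg.ravel())
    codes = veg_map.values.ravel()

    ok = np.isfinite(codes) & (cell_ids >= 0)
    codes = codes[ok].astype(int)
    cell_ids = cell_ids[ok]

    present_codes = set(np.unique(codes).tolist())
    for code in excluded_codes - present_codes:
        warnings.warn(f"excluded vegetation code {code} is absent from the map",
                      stacklevel=2)
    keep = ~np.isin(codes, sorted(excluded_codes))
    codes, cell_ids = codes[keep], cell_ids[keep]

    at_mat = np.zeros(grid.n_cells, dtype=bool)
    at_map = np.zeros(grid.n_cells, dtype=bool)
    rc = risk_cells.set_index("cell_id")
    idx = rc.index.to_numpy(int)
    at_mat[idx] = rc["at_risk_mat"].to_numpy(bool)
    at_map[idx] = rc["at_risk_map"].to_numpy(bool)

    total_kept = codes.size
    rows = []
    for code in sorted(np.unique(codes).tolist()):
        sel = codes == code
        n = int(sel.sum())
        n_risk_mat = int(at_mat[cell_ids[sel]].sum())
        n_risk_map = int(at_map[cell_ids[sel]].sum())
        rows.append(
            {
                "class_code": code,
                "class_name": class_names.get(code, f"class_{code}"),
                "n_fine_cells": n,
                "area_share_pct": 100.0 * n / total_kept if total_kept else 0.0,
                "pct_at_risk_mat": 100.0 * n_risk_mat / n,
                "pct_at_risk_map": 100.0 * n_risk_map / n,
            }
        )
    return pd.DataFrame(rows)
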