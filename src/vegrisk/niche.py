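"""Observed climatic limits and breadths per species.

The realized-niche edge of each species is summarised by percentile bounds
of the long-term climate values matched to its cleaned occurrence records:
the 98th percentile of MAT is the upper thermal limit, the 2nd percentile
of MAP the lower precipitation limit, and the 98th-minus-2nd spread of each
variable its climatic breadth.  Percentiles use linear interpolation of
order statistics at position h = (n-1)p + 1, the shared default of the
major statistical environments; the rule is recorded in run metadata since
small-sample limits are mildly sensitive to it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["percentile", "estimate_limits", "compare_limit_sources",
            "UPPER_PCT", "LOWER_PCT", "PERCENTILE_RULE"]

UPPER_PCT = 98.0
LOWER_PCT = 2.0
PERCENTILE_RULE = "linear interpolation of order statistics, h=(n-1)p+1"


def percentile(values: np.ndarray, q: float) -> float:
    """Percentile with linear interpolation between order statistics."""
    return float(np.percentile(np.asarray(values, dtype=float), q, method="linear"))


def estimate_limits(
    matched: pd.DataFrame,
    upper_pct: float = UPPER_PCT,
    lower_pct: float = LOWER_PCT,
    min_records: int = 1,
) -> pd.DataFrame:
    """Species-level observed climate limits from matched climate values.

    Parameters
    ----------
    matched : DataFrame
        One row per record with columns ``species``, ``mat``, ``map``
        (climate values already matched at the fine grid).  Rows with NaN in
        either climate value are dropped first (unmatched records).
    upper_pct, lower_pct : float
        Percentile levels for the upper MAT and lower MAP limits.
    min_records : int
        Species with fewer matched records are omitted.

    Returns
    -------
    DataFrame indexed by default integers with columns ``species``,
    ``upper_mat_limit``, ``lower_map_limit``, ``mat_breadth``,
    ``map_breadth``, ``n_records``.  Species with zero matched values are
    omitted (callers log the count).  Duplicate climate values from several
    records in one fine cell are retained deliberately: deduplication acts
    on specimens, not on climate values.
    """
    for col in ("species", "mat", "map"):
        if col not in matched.columns:
            raise KeyError(f"matched-value table is missing column {col!r}")
    ok = matched.dropna(subset=["mat", "map"])
    rows = []
    for sp, grp in ok.groupby("species", sort=True):
        n = len(grp)
        if n < max(min_records, 1):
            continue
        mat = grp["mat"].to_numpy(float)
        mp = grp["map"].to_numpy(float)
        up = percentile(mat, upper_pct)
        lo_mat = percentile(mat, lower_pct)
        lo = percentile(mp, lower_pct)
        up_map = percentile(mp, upper_pct)
        rows.append(
            {
                "species": sp,
                "upper_mat_limit": up,
                "lower_map_limit": lo,
                "mat_breadth": up - lo_mat,
                "map_breadth": up_map - lo,
                "n_records": n,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["species", "upper_mat_limit", "lower_map_limit",
                 "mat_breadth", "map_breadth", "n_records"],
    )


def compare_limit_sources(
    limits_a: pd.DataFrame,
    limits_b: pd.DataFrame,
    column: str = "upper_mat_limit",
) -> tuple[int, float, pd.DataFrame]:
    """How often source B's upper limits exceed source A's.

    Used to ask whether an alternative record source (e.g. cultivated
    occurrences) pushes species' observed upper limits beyond the
    native-range estimates.  Comparison runs over the species shared by the
    two tables; exceedance is strict.

    Returns
    -------
    (count, fraction, per_species)
        ``per_species`` has columns ``species``, ``a``, ``b``,
        ``exceedance`` (= b - a, positive where B exceeds A).
    """
    a = limits_a.set_index("species")[column]
    b = limits_b.set_index("species")[column]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("limit tables share no species")
    a, b = a.loc[shared], b.loc[shared]
    exceed = b - a
    count = int((exceed > 0).sum())
    per_species = pd.DataFrame(
        {"species": shared, "a": a.to_numpy(), "b": b.to_numpy(),
         "exceedance": exceed.to_numpy()}
    )
    return count, count / len(shared), per_species
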