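"""Per-cell sampling completeness via the bias-corrected Chao1 estimator.

Collection effort in herbarium data is spatially uneven, so observed
richness under-counts true richness where sampling is thin.  Expected
richness per assemblage cell is estimated from record counts with the
bias-corrected Chao1 form

    S_chao1 = S_obs + f1 (f1 - 1) / (2 (f2 + 1))

where f1 and f2 are the numbers of species seen exactly once and twice.
Completeness is S_obs / S_chao1; cells below the threshold (default 0.7,
boundary counts as passing) are excluded from regression-stage statistics
but still mapped.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["chao1_expected", "completeness_table", "filter_cells",
           "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 0.7


def chao1_expected(counts: Sequence[int]) -> float:
    """Bias-corrected Chao1 expected richness from per-species counts.

    ``counts`` holds one positive integer per observed species (its record
    count in the cell).  Raises on an empty cell — callers exclude such
    cells with a log entry.
    """
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0:
        raise ValueError("Chao1 is undefined for an empty cell")
    if np.any(arr <= 0) or np.any(arr != np.round(arr)):
        raise ValueError("record counts must be positive integers")
    s_obs = arr.size
    f1 = int(np.sum(arr == 1))
    f2 = int(np.sum(arr == 2))
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def completeness_table(
    cell_species_counts: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Completeness per cell from a (cell_id, species, n_records) table.

    Returns columns ``cell_id``, ``s_obs``, ``f1``, ``f2``, ``s_chao1``,
    ``ratio``, ``passes``.
    """
    for col in ("cell_id", "species", "n_records"):
        if col not in cell_species_counts.columns:
            raise KeyError(f"count table is missing column {col!r}")
    rows = []
    for cid, grp in cell_species_counts.groupby("cell_id", sort=True):
        counts = grp["n_records"].to_numpy(float)
        s_obs = len(counts)
        f1 = int(np.sum(counts == 1))
        f2 = int(np.sum(counts == 2))
        s_chao1 = chao1_expected(counts)
        ratio = s_obs / s_chao1
        rows.append(
            {"cell_id": cid, "s_obs": s_obs, "f1": f1, "f2": f2,
             "s_chao1": s_chao1, "ratio": ratio, "passes": ratio >= threshold}
        )
    return pd.DataFrame(
        rows, columns=["cell_id", "s_obs", "f1", "f2", "s_chao1", "ratio", "passes"]
    )


def filter_cells(
    results: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> tuple[list, list]:
    """Partition cell ids into completeness-passing and failing lists.

    Passing means ratio >= threshold (a cell exactly at the threshold is
    retained).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    passing = results.loc[results["ratio"] >= threshold, "cell_id"].tolist()
    failing = results.loc[results["ratio"] < threshold, "cell_id"].tolist()
    return passing, failing
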