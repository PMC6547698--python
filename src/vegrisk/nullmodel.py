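"""Constrained-randomization null model for safety margins.

MAT margins are in degC and MAP margins in mm, so raw margins cannot be
compared across variables.  Each cell's observed margin is therefore
standardized against a null distribution built by reassigning observed
climate limits: a draw samples, without replacement, as many species as the
cell actually holds from the pool of species whose limit is compatible with
the cell's long-term climate (upper MAT limit at or above cell MAT for the
MAT null; lower MAP limit at or below cell MAP for the MAP null), takes the
median limit, and turns it into a null safety margin.  With 1000 draws,

    z = (observed margin - null mean) / null sd,

and |z| >= 1.96 marks a margin significantly smaller or larger than chance
expectation given the cell's richness.

The compatibility direction is configurable: ``"compatible"`` (default)
draws from species that could tolerate the cell; ``"literal"`` draws from
the complementary, intolerant pool.  If a pool is smaller than the cell's
richness the draw falls back to sampling with replacement and the cell is
flagged.  Randomness derives one independent stream per (cell, variable)
from the master seed, so evaluation order cannot change results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["null_zscore", "null_zscore_table", "classify_cells", "Z_THRESHOLD"]

Z_THRESHOLD = 1.96
_VAR_CODE = {"MAT": 0, "MAP": 1}


@dataclass
class _NullDraws:
    mean: float
    sd: float
    pool_size: int
    with_replacement: bool


def _null_margins(
    rng: np.random.Generator,
    pool_limits: np.ndarray,
    richness: int,
    n_draws: int,
    sign: float,
    cell_climate: float,
) -> tuple[np.ndarray, int, bool]:
    """Null safety margins from random reassignments of pool limits.

    ``sign`` is +1 for MAT (margin = median limit - climate) and -1 for MAP
    (margin = climate - median limit).
    """
    pool_n = pool_limits.size
    replace = pool_n < richness
    if replace:
        idx = rng.integers(0, pool_n, size=(n_draws, richness))
        draws = pool_limits[idx]
    else:
        # top-k of random keys == uniform sampling without replacement
        keys = rng.random((n_draws, pool_n))
        idx = np.argpartition(keys, richness - 1, axis=1)[:, :richness]
        draws = pool_limits[idx]
    medians = np.median(draws, axis=1)
    margins = sign * (medians - cell_climate)
    return margins, pool_n, replace


def null_zscore(
    cell_id: int,
    variable: str,
    observed_margin: float,
    cell_climate: float,
    richness: int,
    niches: pd.DataFrame,
    n_draws: int = 1000,
    seed: int = 0,
    pool_constraint: str = "compatible",
) -> dict:
    """NullResult row for one cell and one variable.

    Parameters
    ----------
    variable : "MAT" or "MAP"
    observed_margin : the cell's observed safety margin for that variable.
    cell_climate : long-term cell MAT (degC) or MAP (mm).
    richness : number of species drawn per reassignment (the cell's
        observed richness).
    niches : species table with ``upper_mat_limit`` / ``lower_map_limit``
        columns — the pool of observed limits of all species in the study.
    seed : master seed; the stream is derived per (cell, variable).
    """
    if variable not in _VAR_CODE:
        raise ValueError("variable must be 'MAT' or 'MAP'")
    if pool_constraint not in {"compatible", "literal"}:
        raise ValueError("pool_constraint must be 'compatible' or 'literal'")
    limits = (
        niches["upper_mat_limit"] if variable == "MAT" else niches["lower_map_limit"]
    ).to_numpy(float)
    limits = limits[np.isfinite(limits)]
    if variable == "MAT":
        compatible = limits >= cell_climate
        sign = 1.0
    else:
        compatible = limits <= cell_climate
        sign = -1.0
    pool = limits[compatible] if pool_constraint == "compatible" else limits[~compatible]

    row = {
        "cell_id": cell_id,
        "variable": variable,
        "observed": observed_margin,
        "null_mean": np.nan,
        "null_sd": np.nan,
        "z": np.nan,
        "n_draws": n_draws,
        "pool_size": int(pool.size),
        "with_replacement": False,
        "defined": False,
        "category": "undefined",
    }
    if pool.size == 0 or richness <= 0:
        return row
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(cell_id), _VAR_CODE[variable]))
    )
    margins, pool_n, replaced = _null_margins(
        rng, pool, richness, n_draws, sign, cell_climate
    )
    mean = float(margins.mean())
    sd = float(margins.std(ddof=1))
    row.update(null_mean=mean, null_sd=sd, with_replacement=replaced)
    if sd <= 0.0:
        return row  # degenerate pool: z undefined, flagged
    z = (observed_margin - mean) / sd
    row.update(z=float(z), defined=True, category=_categorize(z))
    return row


def _categorize(z: float, threshold: float = Z_THRESHOLD) -> str:
    if z >= threshold:
        return "higher"
    if z <= -threshold:
        return "lower"
    return "neither"


def null_zscore_table(
    cells: pd.DataFrame,
    niches: pd.DataFrame,
    n_draws: int = 1000,
    seed: int = 0,
    pool_constraint: str = "compatible",
    variables: tuple[str, ...] = ("MAT", "MAP"),
) -> pd.DataFrame:
    """Null z-scores for every cell of a risk table, both variables.

    ``cells`` is the output of :func:`vegrisk.risk.cell_risk_table` (needs
    ``cell_id``, ``richness``, ``mat``, ``map``, ``s_mat``, ``s_map``).
    """
    rows = []
    for rec in cells.itertuples(index=False):
        for var in variables:
            obs = rec.s_mat if var == "MAT" else rec.s_map
            clim = rec.mat if var == "MAT" else rec.map
            rows.append(
                null_zscore(
                    cell_id=int(rec.cell_id),
                    variable=var,
                    observed_margin=float(obs),
                    cell_climate=float(clim),
                    richness=int(rec.richness),
                    niches=niches,
                    n_draws=n_draws,
                    seed=seed,
                    pool_constraint=pool_constraint,
                )
            )
    return pd.DataFrame(rows)


def classify_cells(
    null_results: pd.DataFrame, threshold: float = Z_THRESHOLD
) -> pd.DataFrame:
    """Joint MAT x MAP significance class per cell.

    ``both_larger`` (both z >= threshold), ``both_smaller`` (both z <=
    -threshold), else ``mixed_or_neither``.  Cells with an undefined z in
    either variable are excluded (callers log the count).  Area shares over
    classified cells accompany the table attributes.
    """
    wide = null_results.pivot(index="cell_id", columns="variable", values="z")
    if not {"MAT", "MAP"}.issubset(wide.columns):
        raise ValueError("null results must cover both MAT and MAP")
    wide = wide.dropna()
    cls = pd.Series("mixed_or_neither", index=wide.index, name="joint_category")
    cls[(wide["MAT"] >= threshold) & (wide["MAP"] >= threshold)] = "both_larger"
    cls[(wide["MAT"] <= -threshold) & (wide["MAP"] <= -threshold)] = "both_smaller"
    out = cls.reset_index()
    shares = cls.value_counts(normalize=True).to_dict()
    out.attrs["area_shares"] = shares
    return out
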