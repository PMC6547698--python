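"""Occurrence-record quality control: six exclusion criteria plus dedup.

Herbarium aggregates carry records that are unusable for climatic-niche
estimation: unaccepted names, missing or out-of-region coordinates,
environmental-space outliers, cultivated material, naturalised exotics, and
non-specimen observations.  ``apply_filters`` removes a record if it meets
at least one criterion, while the report tallies every criterion a record
met (the same record frequently fails several).  ``deduplicate`` keeps one
record per (species, latitude, longitude, month, year, collector) key — the
signature of one collection event lodged with several herbaria.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CleaningReport", "apply_filters", "deduplicate", "clean_occurrences",
           "CRITERIA", "REQUIRED_COLUMNS"]

#: criterion key -> human-readable label
CRITERIA = {
    "invalid_name": "no accepted species name",
    "bad_coordinates": "missing or out-of-extent coordinates",
    "outlier": "flagged as suspected outlier",
    "cultivated": "cultivated origin (flag or free-text)",
    "exotic": "non-native origin",
    "non_specimen": "not a preserved specimen",
}

REQUIRED_COLUMNS = [
    "species",
    "decimalLongitude",
    "decimalLatitude",
    "year",
    "month",
    "recordedBy",
    "basisOfRecord",
    "outlier_flag",
    "cultivated_flag",
]

_CULTIVATED_RE = re.compile(r"cultivat|garden", re.IGNORECASE)

DEDUP_KEY = ["species", "decimalLatitude", "decimalLongitude", "month", "year",
             "recordedBy"]


@dataclass
class CleaningReport:
    """Per-criterion removal tallies for one QC run.

    ``removed_unique`` counts each record once however many criteria it met,
    so ``retained = n_input - removed_unique`` always holds;
    ``per_criterion`` reports every criterion independently and can sum to
    more than ``removed_unique``.
    """

    n_input: int = 0
    per_criterion: dict[str, int] = field(default_factory=dict)
    removed_unique: int = 0
    retained: int = 0
    n_duplicates_removed: int = 0
    retained_after_dedup: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": key, "label": CRITERIA[key], "count": self.per_criterion.get(key, 0),
             "fraction_of_input": (self.per_criterion.get(key, 0) / self.n_input
                                   if self.n_input else 0.0)}
            for key in CRITERIA
        ]
        rows.append({"stage": "removed_unique", "label": "records removed (any criterion)",
                     "count": self.removed_unique,
                     "fraction_of_input": self.removed_unique / self.n_input if self.n_input else 0.0})
        rows.append({"stage": "duplicates", "label": "duplicate records collapsed",
                     "count": self.n_duplicates_removed,
                     "fraction_of_input": self.n_duplicates_removed / self.n_input if self.n_input else 0.0})
        rows.append({"stage": "retained", "label": "records retained",
                     "count": self.retained_after_dedup or self.retained,
                     "fraction_of_input": (self.retained_after_dedup or self.retained) / self.n_input
                     if self.n_input else 0.0})
        return pd.DataFrame(rows)

    def log_lines(self) -> list[str]:
        lines = [f"input records: {self.n_input}"]
        for key, label in CRITERIA.items():
            n = self.per_criterion.get(key, 0)
            pct = 100.0 * n / self.n_input if self.n_input else 0.0
            lines.append(f"criterion {label}: {n} ({pct:.1f}%)")
        lines.append(f"removed (>=1 criterion): {self.removed_unique}")
        lines.append(f"duplicates collapsed: {self.n_duplicates_removed}")
        lines.append(f"retained: {self.retained_after_dedup or self.retained}")
        return lines


def _check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise KeyError(f"occurrence table is missing required column(s): {missing}")


def apply_filters(
    records: pd.DataFrame,
    accepted_names: set[str] | None = None,
    exotic_names: set[str] | None = None,
    extent: tuple[float, float, float, float] | None = None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Remove records meeting any exclusion criterion.

    Parameters
    ----------
    records : DataFrame
        Occurrence table with the Darwin-Core-aligned columns of
        :data:`REQUIRED_COLUMNS` (plus optional ``free_text``).
    accepted_names : set or None
        Accepted species names; a record whose name is not in the set fails
        the valid-name criterion.  ``None`` disables the check.
    exotic_names : set or None
        Names on the exotic/naturalised checklist; membership fails the
        native-origin criterion.  ``None`` or empty disables it.
    extent : (xmin, ymin, xmax, ymax) or None
        Study-region boundary in the table's coordinate system; coordinates
        outside it (or missing) fail the geo-reference criterion.

    Returns
    -------
    (clean, report)
        ``clean`` preserves input order and the original index; ``report``
        tallies each criterion independently.
    """
    _check_columns(records)
    n = len(records)
    report = CleaningReport(n_input=n)
    if n == 0:
        report.per_criterion = {k: 0 for k in CRITERIA}
        return records.copy(), report

    name = records["species"].astype("string").str.strip()
    lon = pd.to_numeric(records["decimalLongitude"], errors="coerce")
    lat = pd.to_numeric(records["decimalLatitude"], errors="coerce")

    fails: dict[str, pd.Series] = {}
    if accepted_names is not None:
        fails["invalid_name"] = ~name.isin(accepted_names).fillna(False).astype(bool)
    else:
        fails["invalid_name"] = pd.Series(False, index=records.index)

    bad_coord = lon.isna() | lat.isna()
    if extent is not None:
        xmin, ymin, xmax, ymax = extent
        inside = (lon >= xmin) & (lon <= xmax) & (lat >= ymin) & (lat <= ymax)
        bad_coord |= ~inside.fillna(False)
    fails["bad_coordinates"] = bad_coord

    fails["outlier"] = records["outlier_flag"].fillna(False).astype(bool)

    cult = records["cultivated_flag"].fillna(False).astype(bool)
    if "free_text" in records.columns:
        text = records["free_text"].astype("string").fillna("")
        cult = cult | text.str.contains(_CULTIVATED_RE, regex=True).astype(bool)
    fails["cultivated"] = cult

    if exotic_names:
        fails["exotic"] = name.isin(exotic_names).fillna(False).astype(bool)
    else:
        fails["exotic"] = pd.Series(False, index=records.index)

    fails["non_specimen"] = (
        records["basisOfRecord"].astype("string").str.strip().str.lower()
        != "preservedspecimen"
    ).fillna(True)

    any_fail = pd.Series(False, index=records.index)
    for key, mask in fails.items():
        mask = mask.astype(bool)
        report.per_criterion[key] = int(mask.sum())
        any_fail |= mask

    clean = records.loc[~any_fail].copy()
    report.removed_unique = int(any_fail.sum())
    report.retained = len(clean)
    return clean, report


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse records sharing the six-field collection-event key.

    The first record in stable input order wins.  String key fields are
    compared after stripping surrounding whitespace (no case folding);
    coordinates at full stored precision; missing values participate in the
    key as missing.
    """
    _check_columns(records)
    if len(records) == 0:
        return records.copy()
    key = pd.DataFrame(index=records.index)
    for col in DEDUP_KEY:
        s = records[col]
        if s.dtype == object or pd.api.types.is_string_dtype(s):
            key[col] = s.astype("string").str.strip()
        else:
            key[col] = s
    keep = ~key.duplicated(keep="first")
    return records.loc[keep].copy()


def clean_occurrences(
    records: pd.DataFrame,
    accepted_names: set[str] | None = None,
    exotic_names: set[str] | None = None,
    extent: tuple[float, float, float, float] | None = None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """``apply_filters`` followed by ``deduplicate``, with a joint report."""
    clean, report = apply_filters(records, accepted_names, exotic_names, extent)
    deduped = deduplicate(clean)
    report.n_duplicates_removed = len(clean) - len(deduped)
    report.retained_after_dedup = len(deduped)
    return deduped, report
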