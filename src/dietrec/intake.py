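"""Intake tables: validation, energy-plausibility filtering, item collapsing.

An intake table is a :class:`pandas.DataFrame` indexed by participant id
with an ``energy_kcal`` column (total daily energy intake, kcal/day) and
one column per catalog food group (daily intake in grams/day; 0 means the
group is not consumed). Extra columns (sex, age, center, ...) are carried
opaquely as covariates.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

from .catalog import FoodGroupCatalog

__all__ = [
    "ENERGY_COL",
    "EnergyFilterResult",
    "validate_intake",
    "filter_by_energy",
    "collapse_items",
    "read_intake_csv",
    "write_intake_csv",
]

logger = logging.getLogger(__name__)

ENERGY_COL = "energy_kcal"

#: Plausible daily energy intake bounds, kcal/day. Rows strictly below the
#: lower bound or strictly above the upper bound are excluded.
DEFAULT_ENERGY_BOUNDS = (500.0, 4000.0)


class EnergyFilterResult(NamedTuple):
    table: pd.DataFrame
    n_excluded: int


def validate_intake(table: pd.DataFrame, catalog: FoodGroupCatalog) -> pd.DataFrame:
    """Validate an intake table against a catalog.

    Checks: unique participant ids, energy column present / positive /
    finite, every catalog group present, intake values finite and
    non-negative. Returns the table with group columns reordered to
    catalog order (covariates keep their position after the groups).
    """
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate participant ids: {dupes[:5]}")
    if ENERGY_COL not in table.columns:
        raise ValueError(f"intake table lacks required column '{ENERGY_COL}'")
    missing = [g for g in catalog.groups if g not in table.columns]
    if missing:
        raise ValueError(f"intake table missing catalog group columns: {missing}")

    energy = table[ENERGY_COL].to_numpy(dtype=float)
    bad_energy = ~np.isfinite(energy) | (energy <= 0)
    if bad_energy.any():
        who = table.index[bad_energy].tolist()
        raise ValueError(f"non-positive or missing energy for participants: {who[:5]}")

    groups = list(catalog.groups)
    values = table[groups].to_numpy(dtype=float)
    bad = ~np.isfinite(values) | (values < 0)
    if bad.any():
        rows = np.unique(np.nonzero(bad)[0])
        who = table.index[rows].tolist()
        raise ValueError(f"negative or non-finite intake for participants: {who[:5]}")

    covariates = [c for c in table.columns if c not in groups and c != ENERGY_COL]
    return table[[ENERGY_COL] + groups + covariates]


def filter_by_energy(
    table: pd.DataFrame,
    lo: float = DEFAULT_ENERGY_BOUNDS[0],
    hi: float = DEFAULT_ENERGY_BOUNDS[1],
) -> EnergyFilterResult:
    """Drop participants with implausible daily energy intake.

    A row is kept iff ``lo <= energy_kcal <= hi`` (exclusion is strict:
    "less than lo or greater than hi", so the boundary values stay).
    Row order is preserved. Returns the filtered table and the number of
    rows excluded.
    """
    if not lo < hi:
        raise ValueError(f"energy bounds must satisfy lo < hi, got ({lo}, {hi})")
    if ENERGY_COL not in table.columns:
        raise ValueError(f"intake table lacks required column '{ENERGY_COL}'")
    energy = table[ENERGY_COL].to_numpy(dtype=float)
    bad = ~np.isfinite(energy) | (energy < 0)
    if bad.any():
        who = table.index[bad].tolist()
        raise ValueError(f"missing or negative energy for participants: {who[:5]}")
    keep = (energy >= lo) & (energy <= hi)
    n_excluded = int((~keep).sum())
    logger.info("energy filter [%g, %g] kcal/day: kept %d, excluded %d",
                lo, hi, int(keep.sum()), n_excluded)
    return EnergyFilterResult(table.loc[keep], n_excluded)


def collapse_items(ffq_items: pd.DataFrame, catalog: FoodGroupCatalog) -> pd.DataFrame:
    """Collapse a per-FFQ-item intake table into food-group intake.

    Each group's intake is the sum of its mapped items' intakes (total
    grams per participant are conserved). Non-item columns ``energy_kcal``
    and any column already named like a catalog group are passed through
    untouched. Output group columns follow catalog order.
    """
    if catalog.item_mapping is None:
        raise ValueError("catalog has no item_mapping; cannot collapse FFQ items")
    mapping = dict(catalog.item_mapping)
    passthrough = [c for c in ffq_items.columns
                   if c == ENERGY_COL or c in set(catalog.groups)]
    item_cols = [c for c in ffq_items.columns if c not in passthrough]
    unmapped = [c for c in item_cols if c not in mapping]
    if unmapped:
        raise ValueError(f"FFQ items not present in item_mapping: {unmapped}")

    out = pd.DataFrame(index=ffq_items.index)
    for c in passthrough:
        out[c] = ffq_items[c]
    grouped = ffq_items[item_cols].T.groupby(lambda item: mapping[item]).sum().T
    for g in catalog.groups:
        if g in grouped.columns:
            out[g] = grouped[g]
        elif g not in out.columns:
            out[g] = 0.0
    order = ([ENERGY_COL] if ENERGY_COL in out.columns else []) + list(catalog.groups)
    return out[order]


def read_intake_csv(path, catalog: FoodGroupCatalog | None = None) -> pd.DataFrame:
    """Read an intake CSV (``participant_id,energy_kcal,<groups...>``)."""
    table = pd.read_csv(path, index_col="participant_id")
    if table.isna().any().any():
        bad_cols = table.columns[table.isna().any()].tolist()
        raise ValueError(
            f"missing values are not permitted in intake CSVs (zeros are explicit); "
            f"found NA in columns {bad_cols}"
        )
    if catalog is not None:
        table = validate_intake(table, catalog)
    return table


def write_intake_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index_label="participant_id")
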