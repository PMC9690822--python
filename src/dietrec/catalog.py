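"""Food-group catalog: the item universe of the recommender.

A catalog names the food groups (the "items" in collaborative-filtering
terms), flags the subset that is *eligible* to appear in a recommendation
list (groups aligned with dietary guidelines), and optionally carries a
mapping from individual FFQ items to groups so that item-level intake
tables can be collapsed.

The default catalog ships the 21 food groups used throughout the package
and the 8 guideline-aligned eligible groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = ["FoodGroupCatalog", "default_catalog", "load_catalog", "DEFAULT_GROUPS", "DEFAULT_ELIGIBLE"]

#: The 21 food groups, collapsed from FFQ items by preparation and
#: nutritional characteristics, in canonical order.
DEFAULT_GROUPS: tuple[str, ...] = (
    "refined_cereals",
    "whole_cereals",
    "tubers_and_roots",
    "breads",
    "confectionery",
    "beans_and_other_legumes",
    "oilseeds",
    "fruits",
    "vegetables",
    "red_meats",
    "white_meats_and_fish",
    "processed_meats",
    "eggs",
    "high_fat_dairy",
    "low_fat_dairy",
    "oils_and_fats",
    "pasta",
    "salted_snacks",
    "juices_and_other_beverages",
    "soft_drinks",
    "alcoholic_beverages",
)

#: The 8 groups eligible as recommendation outputs (guideline-aligned:
#: health promotion and chronic-disease risk reduction).
DEFAULT_ELIGIBLE: tuple[str, ...] = (
    "whole_cereals",
    "tubers_and_roots",
    "beans_and_other_legumes",
    "oilseeds",
    "fruits",
    "vegetables",
    "white_meats_and_fish",
    "low_fat_dairy",
)


@dataclass(frozen=True)
class FoodGroupCatalog:
    """Ordered food groups, eligible subset, and optional FFQ item mapping.

    Parameters
    ----------
    groups
        Ordered, unique group identifiers. Ordering is meaningful: it is
        the canonical column order of intake tables and the tie-break
        order of recommendation lists.
    eligible
        Subset of ``groups`` permitted as recommendation outputs.
    item_mapping
        Optional map from FFQ item name to a group identifier, used by
        :func:`dietrec.intake.collapse_items`.
    """

    groups: tuple[str, ...] = DEFAULT_GROUPS
    eligible: tuple[str, ...] = DEFAULT_ELIGIBLE
    item_mapping: Mapping[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        groups = tuple(self.groups)
        eligible = tuple(self.eligible)
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "eligible", eligible)
        if len(set(groups)) != len(groups):
            dupes = sorted({g for g in groups if list(groups).count(g) > 1})
            raise ValueError(f"duplicate group identifiers: {dupes}")
        bad = [g for g in eligible if g not in groups]
        if bad:
            raise ValueError(f"eligible groups not in catalog: {bad}")
        if len(set(eligible)) != len(eligible):
            raise ValueError("duplicate entries in eligible list")
        if self.item_mapping is not None:
            unknown = sorted({g for g in self.item_mapping.values() if g not in groups})
            if unknown:
                raise ValueError(f"item_mapping targets unknown groups: {unknown}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_eligible(self) -> int:
        return len(self.eligible)

    def is_eligible(self, group: str) -> bool:
        return group in set(self.eligible)

    def rank(self, group: str) -> int:
        """Position of ``group`` in catalog order (tie-break key)."""
        return self.groups.index(group)

    def to_dict(self) -> dict:
        d: dict = {"groups": list(self.groups), "eligible": list(self.eligible)}
        if self.item_mapping is not None:
            d["item_mapping"] = dict(self.item_mapping)
        return d


def default_catalog() -> FoodGroupCatalog:
    """The built-in 21-group / 8-eligible catalog."""
    return FoodGroupCatalog()


def load_catalog(path: str | Path) -> FoodGroupCatalog:
    """Load a catalog from a JSON or YAML config file.

    The file must contain ``groups`` (ordered list) and ``eligible``
    (list); ``item_mapping`` (mapping) is optional. JSON is a subset of
    YAML, so both formats are parsed by the same loader.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "groups" not in cfg:
        raise ValueError(f"catalog config {path} must define a 'groups' list")
    return FoodGroupCatalog(
        groups=tuple(cfg["groups"]),
        eligible=tuple(cfg.get("eligible", ())),
        item_mapping=cfg.get("item_mapping"),
    )
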