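"""Canonical DQQ food-group taxonomy and indicator membership tables.

The Diet Quality Questionnaire (DQQ) records yes/no consumption of 29 food
groups over the previous 24 hours.  This module is the single source of truth
for those groups (loaded from a packaged CSV), for the partition into "foods
to promote" (17 groups) and "foods to limit" (12 groups), and for the frozen
membership mappings that define each population-level diet-quality indicator:

* ``FGDS10``        — the ten aggregated food groups of the food group
                      diversity score (MDD-W construction),
* ``ALL5``          — the five food groups recommended for daily consumption,
* ``NCD_PROTECT``   — nine groups protective against non-communicable disease,
* ``NCD_RISK``      — eight scored items (processed meat double-weighted),
* ``SWEET_BEV``     — the three sweet-beverage groups,
* ``UPF``           — the six unhealthy/ultra-processed food groups,
* ``FRUIT_VEG``     — the six fruit and vegetable groups,
* ``FOODS_TO_LIMIT``— the ten unhealthy "foods to limit" groups.

Raw survey records are validated into :class:`FoodGroupVector` instances via
:func:`validate_vector`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping

CATEGORY_PROMOTE = "promote"
CATEGORY_LIMIT = "limit"

INDICATOR_IDS = (
    "FGDS10",
    "ALL5",
    "NCD_PROTECT",
    "NCD_RISK",
    "SWEET_BEV",
    "UPF",
    "FRUIT_VEG",
    "FOODS_TO_LIMIT",
)


@dataclass(frozen=True, slots=True)
class FoodGroup:
    """One of the 29 DQQ food groups."""

    code: str
    label: str
    category: str  # "promote" | "limit"
    table4_order: int


@lru_cache(maxsize=1)
def canonical_food_groups() -> tuple[FoodGroup, ...]:
    """All 29 food groups in fixed questionnaire/report order.

    Loaded once from the packaged taxonomy CSV and cached.  The order is the
    stable report order (promote groups first, then limit groups).
    """
    path = resources.files("dqqkit.data").joinpath("food_groups.csv")
    with path.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    groups = tuple(
        FoodGroup(
            code=r["code"],
            label=r["label"],
            category=r["category"],
            table4_order=int(r["table4_order"]),
        )
        for r in sorted(rows, key=lambda r: int(r["table4_order"]))
    )
    # structural guarantees the rest of the package relies on
    codes = [g.code for g in groups]
    if len(groups) != 29 or len(set(codes)) != 29:
        raise RuntimeError("taxonomy file must define exactly 29 distinct food groups")
    n_promote = sum(g.category == CATEGORY_PROMOTE for g in groups)
    n_limit = sum(g.category == CATEGORY_LIMIT for g in groups)
    if (n_promote, n_limit) != (17, 12):
        raise RuntimeError("taxonomy must partition into 17 promote / 12 limit groups")
    return groups


@lru_cache(maxsize=1)
def food_group_codes() -> tuple[str, ...]:
    """The 29 canonical codes (lower_snake_case column names) in order."""
    return tuple(g.code for g in canonical_food_groups())


def food_group(code: str) -> FoodGroup:
    for g in canonical_food_groups():
        if g.code == code:
            return g
    raise KeyError(f"unknown food group code: {code!r}")


# ---------------------------------------------------------------------------
# Indicator membership
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndicatorItem:
    """A scored item of an indicator: consumption of any member group counts."""

    label: str
    groups: frozenset[str]
    weight: int = 1


@dataclass(frozen=True)
class IndicatorMembership:
    indicator_id: str
    items: tuple[IndicatorItem, ...]

    @property
    def max_score(self) -> int:
        return sum(it.weight for it in self.items)

    @property
    def group_codes(self) -> frozenset[str]:
        out: set[str] = set()
        for it in self.items:
            out |= it.groups
        return frozenset(out)


def _item(label: str, groups: Iterable[str], weight: int = 1) -> IndicatorItem:
    return IndicatorItem(label=label, groups=frozenset(groups), weight=weight)


def _singletons(codes: Iterable[str]) -> tuple[IndicatorItem, ...]:
    return tuple(_item(food_group(c).label.lower(), [c]) for c in codes)


# FGDS follows the MDD-W ten-group aggregation of the 29 DQQ groups.  The
# finer DQQ fruit/vegetable split is folded: vitamin A-rich orange vegetables
# and vitamin A-rich fruits form the "other vitamin A-rich fruits/vegetables"
# item, and citrus fruits count with "other fruits".  Processed meat counts
# toward meat/poultry/fish (DQQ convention; configurable upstream of this
# frozen table only by editing it).
_FGDS10 = (
    _item("grains/tubers", ["grain_based_staple_foods", "whole_grains", "roots_and_tubers"]),
    _item("pulses/legumes", ["pulses_legumes"]),
    _item("nuts/seeds", ["nuts_and_seeds"]),
    _item("dairy", ["cheese", "yogurt", "milk"]),
    _item(
        "meat/poultry/fish",
        [
            "unprocessed_red_meat_ruminants",
            "unprocessed_red_meat_non_ruminants",
            "processed_meats",
            "poultry",
            "fish_and_seafood",
        ],
    ),
    _item("eggs", ["eggs"]),
    _item("dark green leafy vegetables", ["dark_green_leafy_vegetables"]),
    _item(
        "other vitamin A-rich fruits/vegetables",
        ["vitamin_a_rich_orange_vegetables", "vitamin_a_rich_fruits"],
    ),
    _item("other vegetables", ["other_vegetables"]),
    _item("other fruits", ["citrus_fruits", "other_fruits"]),
)

_ALL5 = (
    _item(
        "vegetable",
        [
            "vitamin_a_rich_orange_vegetables",
            "dark_green_leafy_vegetables",
            "other_vegetables",
        ],
    ),
    _item("fruit", ["vitamin_a_rich_fruits", "citrus_fruits", "other_fruits"]),
    _item("pulse/nut/seed", ["pulses_legumes", "nuts_and_seeds"]),
    _item(
        "animal-source food",
        [
            "unprocessed_red_meat_ruminants",
            "unprocessed_red_meat_non_ruminants",
            "processed_meats",
            "poultry",
            "fish_and_seafood",
            "eggs",
            "cheese",
            "yogurt",
            "milk",
        ],
    ),
    _item(
        "starchy staple food",
        ["grain_based_staple_foods", "whole_grains", "roots_and_tubers"],
    ),
)

_NCD_PROTECT = _singletons(
    [
        "whole_grains",
        "pulses_legumes",
        "nuts_and_seeds",
        "vitamin_a_rich_orange_vegetables",
        "dark_green_leafy_vegetables",
        "other_vegetables",
        "vitamin_a_rich_fruits",
        "citrus_fruits",
        "other_fruits",
    ]
)

# Processed meat is double-weighted; fast food and instant noodles share one
# item, as do the two unprocessed red meat groups.  Total weight is 9.
_NCD_RISK = (
    _item("soft drinks", ["soft_drinks_and_energy_sports_drinks"]),
    _item("baked/grain-based sweets", ["baked_grain_based_sweets"]),
    _item("other sweets", ["other_sweets"]),
    _item("processed meat", ["processed_meats"], weight=2),
    _item(
        "unprocessed red meat",
        ["unprocessed_red_meat_ruminants", "unprocessed_red_meat_non_ruminants"],
    ),
    _item("deep-fried foods", ["deep_fried_foods"]),
    _item("fast food/instant noodles", ["fast_foods", "instant_noodles"]),
    _item("packaged ultra-processed salty snacks", ["salty_snacks"]),
)

# Sweetened tea/milk/coffee is the sweet tea/coffee/cocoa question; plain
# milk is not a sweet beverage.  Fruit juice counts here, never as fruit.
_SWEET_BEV = _singletons(
    [
        "soft_drinks_and_energy_sports_drinks",
        "fruit_juice_fruit_flavoured_drinks",
        "sweet_tea_coffee_cocoa",
    ]
)

_UPF = _singletons(
    [
        "baked_grain_based_sweets",
        "other_sweets",
        "salty_snacks",
        "instant_noodles",
        "deep_fried_foods",
        "fast_foods",
    ]
)

_FRUIT_VEG = _singletons(
    [
        "vitamin_a_rich_orange_vegetables",
        "dark_green_leafy_vegetables",
        "other_vegetables",
        "vitamin_a_rich_fruits",
        "citrus_fruits",
        "other_fruits",
    ]
)

_FOODS_TO_LIMIT = _singletons(
    [
        "processed_meats",
        "baked_grain_based_sweets",
        "other_sweets",
        "salty_snacks",
        "instant_noodles",
        "deep_fried_foods",
        "fast_foods",
        "sweet_tea_coffee_cocoa",
        "fruit_juice_fruit_flavoured_drinks",
        "soft_drinks_and_energy_sports_drinks",
    ]
)

_MEMBERSHIPS: dict[str, IndicatorMembership] = {
    "FGDS10": IndicatorMembership("FGDS10", _FGDS10),
    "ALL5": IndicatorMembership("ALL5", _ALL5),
    "NCD_PROTECT": IndicatorMembership("NCD_PROTECT", _NCD_PROTECT),
    "NCD_RISK": IndicatorMembership("NCD_RISK", _NCD_RISK),
    "SWEET_BEV": IndicatorMembership("SWEET_BEV", _SWEET_BEV),
    "UPF": IndicatorMembership("UPF", _UPF),
    "FRUIT_VEG": IndicatorMembership("FRUIT_VEG", _FRUIT_VEG),
    "FOODS_TO_LIMIT": IndicatorMembership("FOODS_TO_LIMIT", _FOODS_TO_LIMIT),
}


def indicator_membership(indicator_id: str) -> IndicatorMembership:
    """Frozen item/weight mapping for one indicator.

    Raises ``ValueError`` naming the valid indicator ids when unknown.
    """
    try:
        return _MEMBERSHIPS[indicator_id]
    except KeyError:
        raise ValueError(
            f"unknown indicator id {indicator_id!r}; valid ids: {', '.join(INDICATOR_IDS)}"
        ) from None


# ---------------------------------------------------------------------------
# Food-group vectors and record validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoodGroupVector:
    """Complete yes/no consumption vector over all 29 DQQ food groups."""

    consumed: Mapping[str, bool]

    def __post_init__(self) -> None:
        codes = set(food_group_codes())
        got = set(self.consumed)
        if got != codes:
            missing = sorted(codes - got)
            extra = sorted(got - codes)
            raise ValueError(
                f"food-group vector must cover all 29 groups; missing={missing}, extra={extra}"
            )

    def __getitem__(self, code: str) -> bool:
        return bool(self.consumed[code])

    def any(self, groups: Iterable[str]) -> bool:
        return any(self.consumed[g] for g in groups)

    @classmethod
    def from_groups(cls, consumed_groups: Iterable[str]) -> "FoodGroupVector":
        """Build a vector from the set of consumed group codes."""
        on = set(consumed_groups)
        unknown = on - set(food_group_codes())
        if unknown:
            raise ValueError(f"unknown food group codes: {sorted(unknown)}")
        return cls({c: (c in on) for c in food_group_codes()})

    def to_record(self) -> dict[str, int]:
        """0/1 record keyed by canonical column names, in canonical order."""
        return {c: int(self.consumed[c]) for c in food_group_codes()}


_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n"}
_MISSING = type("_Missing", (), {})()


def _coerce(value: object) -> bool | object:
    """Coerce a raw cell to bool; returns the missing sentinel or raises."""
    if value is None:
        return _MISSING
    if isinstance(value, bool):
        return value
    if isinstance(value, (int,)) and value in (0, 1):
        return bool(value)
    if isinstance(value, float):
        if value != value:  # NaN
            return _MISSING
        if value in (0.0, 1.0):
            return bool(value)
        raise ValueError(f"uninterpretable consumption value: {value!r}")
    s = str(value).strip().lower()
    if s == "":
        return _MISSING
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"uninterpretable consumption value: {value!r}")


def validate_vector(
    raw_record: Mapping[str, object], policy: str = "strict"
) -> tuple[FoodGroupVector, list[str]]:
    """Validate a raw record of food-group columns into a FoodGroupVector.

    Parameters
    ----------
    raw_record
        Mapping from food-group column name to a raw value.  Values may be
        0/1, booleans, or yes/no / true/false strings.
    policy
        ``"strict"`` rejects missing or uninterpretable values and requires
        all 29 columns.  ``"lenient"`` fills each missing group as
        not-consumed, emitting one warning per fill.

    Returns
    -------
    (vector, warnings)
    """
    if policy not in ("strict", "lenient"):
        raise ValueError("policy must be 'strict' or 'lenient'")
    codes = food_group_codes()
    unknown = set(raw_record) - set(codes)
    if unknown:
        raise ValueError(f"unrecognized food-group columns: {sorted(unknown)}")
    recognized = [c for c in codes if c in raw_record]
    if not recognized:
        raise ValueError("record contains no recognized food-group column")

    values: dict[str, bool] = {}
    warnings: list[str] = []
    bad: list[str] = []
    for code in codes:
        if code in raw_record:
            try:
                v = _coerce(raw_record[code])
            except ValueError:
                bad.append(code)
                continue
        else:
            v = _MISSING
        if v is _MISSING:
            if policy == "lenient":
                values[code] = False
                warnings.append(f"missing value for {code!r} filled as not-consumed")
            else:
                bad.append(code)
        else:
            values[code] = bool(v)

    if bad:
        raise ValueError(f"missing or uninterpretable food-group values: {sorted(bad)}")
    return FoodGroupVector(values), warnings
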