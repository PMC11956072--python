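"""Per-respondent diet-quality indicator scoring.

Nine population-level indicators computed from one day's yes/no food-group
consumption:

==================  =========================================================
FGDS                food group diversity score, 0-10 (count of ten items)
MDD-W               minimum dietary diversity for women: FGDS >= 5, defined
                    only for females aged 15-49 (otherwise not applicable)
All-5               all five daily-recommended food groups consumed
NCD-Protect         0-9, one point per protective group consumed
NCD-Risk            0-9, one point per risk item (processed meat counts 2)
GDR                 global dietary recommendations score,
                    NCD-Protect - NCD-Risk + 9, range 0-18
zero fruit/veg      no fruit or vegetable group consumed
sweet beverage      any of the three sweet-beverage groups consumed
unhealthy/UPF       any of the six unhealthy/ultra-processed groups consumed
==================  =========================================================

Scoring is pure: survey weights and design information play no role here and
enter only at estimation time (see :mod:`dqqkit.survey`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .taxonomy import FoodGroupVector, food_group_codes, indicator_membership

MDDW_FGDS_THRESHOLD = 5
MDDW_AGE_RANGE = (15, 49)  # inclusive; women of reproductive age

ALL5_COMPONENTS = (
    "vegetable",
    "fruit",
    "pulse/nut/seed",
    "animal-source food",
    "starchy staple food",
)


def fgds(v: FoodGroupVector) -> int:
    """Food group diversity score: number of the ten FGDS items consumed."""
    m = indicator_membership("FGDS10")
    return sum(v.any(item.groups) for item in m.items)


def mddw(
    v: FoodGroupVector,
    age_years: int,
    gender: str,
    age_range: tuple[int, int] = MDDW_AGE_RANGE,
) -> Optional[bool]:
    """Minimum dietary diversity for women.

    Returns ``None`` (not applicable) unless the respondent is female and
    inside ``age_range`` (inclusive); otherwise ``True`` iff FGDS >= 5.  The
    age window is a parameter because some analyses restrict the adult
    denominator further.
    """
    lo, hi = age_range
    if gender != "female" or not (lo <= age_years <= hi):
        return None
    return fgds(v) >= MDDW_FGDS_THRESHOLD


@dataclass(frozen=True)
class All5Result:
    flag: bool
    components: dict[str, bool]


def all5(v: FoodGroupVector) -> All5Result:
    """All-5: did the respondent consume each of the five recommended groups?"""
    m = indicator_membership("ALL5")
    components = {item.label: v.any(item.groups) for item in m.items}
    return All5Result(flag=all(components.values()), components=components)


def ncd_protect(v: FoodGroupVector) -> int:
    m = indicator_membership("NCD_PROTECT")
    return sum(item.weight for item in m.items if v.any(item.groups))


def ncd_risk(v: FoodGroupVector) -> int:
    m = indicator_membership("NCD_RISK")
    return sum(item.weight for item in m.items if v.any(item.groups))


def gdr(v: FoodGroupVector) -> int:
    """GDR score = NCD-Protect - NCD-Risk + 9 (range 0-18, higher = better)."""
    return ncd_protect(v) - ncd_risk(v) + 9


def zero_fruit_veg(v: FoodGroupVector) -> bool:
    m = indicator_membership("FRUIT_VEG")
    return not v.any(m.group_codes)


def sweet_beverage(v: FoodGroupVector) -> bool:
    m = indicator_membership("SWEET_BEV")
    return v.any(m.group_codes)


def unhealthy_upf(v: FoodGroupVector) -> bool:
    m = indicator_membership("UPF")
    return v.any(m.group_codes)


# ---------------------------------------------------------------------------
# Respondents and full result records
# ---------------------------------------------------------------------------

GENDERS = ("female", "male")
EDUCATION_LEVELS = ("completed_primary_or_less", "more_than_primary", "unknown")
RESIDENCES = ("urban", "rural")


@dataclass(frozen=True)
class Respondent:
    """One survey interview: demographics, design fields and the diet vector.

    The survey frame covers ages 15 and older; younger ages are rejected.
    """

    respondent_id: str
    country: str
    cluster_id: str
    age_years: int
    gender: str
    education: str
    residence: str
    wealth_quintile: int
    diet: FoodGroupVector
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.age_years < 15:
            raise ValueError("age_years must be >= 15 (survey frame is 15+)")
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}")
        if self.education not in EDUCATION_LEVELS:
            raise ValueError(f"education must be one of {EDUCATION_LEVELS}")
        if self.residence not in RESIDENCES:
            raise ValueError(f"residence must be one of {RESIDENCES}")
        if not 1 <= self.wealth_quintile <= 5:
            raise ValueError("wealth_quintile must be in 1..5")
        if not self.weight > 0:
            raise ValueError("weight must be positive")


@dataclass(frozen=True)
class IndicatorResult:
    """All nine indicator values (plus All-5 components) for one respondent."""

    fgds: int
    mddw: Optional[bool]  # None = not applicable
    all5: bool
    all5_components: dict[str, bool]
    ncd_protect: int
    ncd_risk: int
    gdr: int
    zero_fruit_veg: bool
    sweet_beverage: bool
    unhealthy_upf: bool

    def __post_init__(self) -> None:
        if self.gdr != self.ncd_protect - self.ncd_risk + 9:
            raise ValueError("gdr must equal ncd_protect - ncd_risk + 9")
        if self.all5 != all(self.all5_components.values()):
            raise ValueError("all5 flag inconsistent with its components")


def score_respondent(r: Respondent) -> IndicatorResult:
    """Compute the full indicator suite for one respondent."""
    v = r.diet
    a5 = all5(v)
    protect = ncd_protect(v)
    risk = ncd_risk(v)
    return IndicatorResult(
        fgds=fgds(v),
        mddw=mddw(v, r.age_years, r.gender),
        all5=a5.flag,
        all5_components=a5.components,
        ncd_protect=protect,
        ncd_risk=risk,
        gdr=protect - risk + 9,
        zero_fruit_veg=zero_fruit_veg(v),
        sweet_beverage=sweet_beverage(v),
        unhealthy_upf=unhealthy_upf(v),
    )


# ---------------------------------------------------------------------------
# Vectorized scoring over a respondent table
# ---------------------------------------------------------------------------

SCORE_COLUMNS = (
    "fgds",
    "mddw",
    "all5",
    "all5_vegetable",
    "all5_fruit",
    "all5_pulse_nut_seed",
    "all5_animal_source_food",
    "all5_starchy_staple_food",
    "ncd_protect",
    "ncd_risk",
    "gdr",
    "zero_fruit_veg",
    "sweet_beverage",
    "unhealthy_upf",
)

_COMPONENT_SLUG = {
    "vegetable": "all5_vegetable",
    "fruit": "all5_fruit",
    "pulse/nut/seed": "all5_pulse_nut_seed",
    "animal-source food": "all5_animal_source_food",
    "starchy staple food": "all5_starchy_staple_food",
}


def score_table(df: pd.DataFrame) -> pd.DataFrame:
    """Score every row of a respondent table at once.

    ``df`` must carry the 29 canonical food-group columns as 0/1 or boolean,
    plus ``age_years`` and ``gender`` for MDD-W applicability.  Returns a
    DataFrame indexed like ``df`` with one column per indicator;
    ``mddw`` is a nullable boolean (``pd.NA`` where not applicable).  Result
    equals row-wise :func:`score_respondent` (cross-checked in the test
    suite) but runs in vectorized time for large tables.
    """
    codes = food_group_codes()
    missing = [c for c in codes if c not in df.columns]
    if missing:
        raise ValueError(f"respondent table is missing food-group columns: {missing}")
    X = df[list(codes)].astype(bool)

    def item_any(groups: frozenset[str]) -> pd.Series:
        return X[list(groups)].any(axis=1)

    out = pd.DataFrame(index=df.index)

    fg = indicator_membership("FGDS10")
    out["fgds"] = sum(item_any(it.groups).astype(int) for it in fg.items)

    lo, hi = MDDW_AGE_RANGE
    eligible = (df["gender"] == "female") & df["age_years"].between(lo, hi)
    mddw_col = pd.Series(pd.NA, index=df.index, dtype="boolean")
    mddw_col[eligible] = out.loc[eligible, "fgds"] >= MDDW_FGDS_THRESHOLD
    out["mddw"] = mddw_col

    a5 = indicator_membership("ALL5")
    comp_cols = []
    for it in a5.items:
        col = _COMPONENT_SLUG[it.label]
        out[col] = item_any(it.groups)
        comp_cols.append(col)
    out["all5"] = out[comp_cols].all(axis=1)

    prot = indicator_membership("NCD_PROTECT")
    out["ncd_protect"] = sum(item_any(it.groups).astype(int) * it.weight for it in prot.items)
    risk = indicator_membership("NCD_RISK")
    out["ncd_risk"] = sum(item_any(it.groups).astype(int) * it.weight for it in risk.items)
    out["gdr"] = out["ncd_protect"] - out["ncd_risk"] + 9

    out["zero_fruit_veg"] = ~item_any(indicator_membership("FRUIT_VEG").group_codes)
    out["sweet_beverage"] = item_any(indicator_membership("SWEET_BEV").group_codes)
    out["unhealthy_upf"] = item_any(indicator_membership("UPF").group_codes)

    return out[list(SCORE_COLUMNS)]
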