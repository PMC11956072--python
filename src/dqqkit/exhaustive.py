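"""Exhaustive enumeration of indicator scores over consumption patterns.

Each indicator depends on at most 20 of the 29 food groups, so its full
behaviour can be verified by enumerating every subset of its constituent
groups (bitmask-vectorized with numpy).  These enumerations back the
analytic checks on the published score ranges (FGDS 0-10, NCD-Protect 0-9,
NCD-Risk 0-9, GDR 0-18, MDD-W threshold at FGDS 5).
"""

from __future__ import annotations

import numpy as np

from .indicators import mddw
from .taxonomy import FoodGroupVector, IndicatorMembership, indicator_membership


def _scores_over_patterns(
    membership: IndicatorMembership, groups: tuple[str, ...]
) -> np.ndarray:
    """Weighted score of every consumption pattern over ``groups``.

    Pattern ``i`` consumes group ``g`` iff bit ``groups.index(g)`` of ``i``
    is set.  Groups outside ``groups`` are treated as not consumed.
    """
    k = len(groups)
    if k > 24:
        raise ValueError("enumeration limited to 24 groups (2^24 patterns)")
    bit = {g: 1 << j for j, g in enumerate(groups)}
    patterns = np.arange(1 << k, dtype=np.int64)
    scores = np.zeros(1 << k, dtype=np.int64)
    for item in membership.items:
        mask = sum(bit[g] for g in item.groups if g in bit)
        if mask:
            scores += ((patterns & mask) != 0) * item.weight
    return scores


def enumerate_scores(indicator_id: str) -> np.ndarray:
    """Score of every subset of an indicator's own constituent groups."""
    m = indicator_membership(indicator_id)
    return _scores_over_patterns(m, tuple(sorted(m.group_codes)))


def enumerate_gdr_scores() -> np.ndarray:
    """GDR of every subset of the groups entering NCD-Protect or NCD-Risk."""
    protect = indicator_membership("NCD_PROTECT")
    risk = indicator_membership("NCD_RISK")
    groups = tuple(sorted(protect.group_codes | risk.group_codes))
    p = _scores_over_patterns(protect, groups)
    r = _scores_over_patterns(risk, groups)
    return p - r + 9


def min_fgds_among_mddw_positive(age_years: int = 17, gender: str = "female") -> int:
    """Smallest FGDS over all patterns an eligible woman could report while
    still being classified MDD-W positive.

    Enumerates every subset of the 20 groups entering FGDS, computes FGDS for
    each, and classifies MDD-W by calling :func:`dqqkit.indicators.mddw` on a
    representative diet for each attained FGDS value (MDD-W depends on the
    diet only through FGDS, which the probing also verifies).
    """
    m = indicator_membership("FGDS10")
    groups = tuple(sorted(m.group_codes))
    scores = _scores_over_patterns(m, groups)

    positive_scores = []
    for s in np.unique(scores):
        pattern = int(np.flatnonzero(scores == s)[0])
        consumed = [g for j, g in enumerate(groups) if pattern >> j & 1]
        v = FoodGroupVector.from_groups(consumed)
        flag = mddw(v, age_years, gender)
        if flag is None:
            raise ValueError("enumeration requires an MDD-W-eligible respondent")
        if flag:
            positive_scores.append(int(s))
    if not positive_scores:
        raise RuntimeError("no MDD-W-positive pattern found")
    return min(positive_scores)
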