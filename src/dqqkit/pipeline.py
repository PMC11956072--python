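"""End-to-end pipeline: validate, score, summarize, compare, report.

Builds the three report tables of a pooled diet-quality analysis:

* a sociodemographic table (gender, education, residence, country, wealth
  quintile by age group),
* a food-group consumption table (29 rows, percent and frequency per age
  group, cluster-adjusted chi-square comparisons),
* an indicator table (medians with IQR and Mann-Whitney tests for the four
  scores; percent and frequency with cluster-adjusted chi-square for the
  binary indicators; All-5 with its five sub-components; MDD-W over its
  restricted denominator of women 15-49),

with the indicator table also available disaggregated by gender and by
residence.  Display strings follow survey-report convention — "62.6 (300)",
"6 [5-8]", "p < 0.001", and an em dash for comparisons that are not
testable (zero-variance rows) — while full-precision numeric columns are
kept alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .indicators import score_table
from .simulate import GeneratedDataset, ScenarioConfig, generate_population
from .survey import (
    ComparisonResult,
    cluster_adjusted_chi2,
    format_p,
    mann_whitney_u,
    median_iqr,
    proportion_summary,
)
from .taxonomy import canonical_food_groups, food_group_codes, validate_vector

NOT_TESTABLE = "—"  # em dash, the report marker for untestable rows

GROUPINGS = {
    "age": ("age_group", ["adolescent", "adult"]),
    "gender": ("gender", ["female", "male"]),
    "residence": ("residence", ["urban", "rural"]),
}

DEMOGRAPHIC_COLUMNS = (
    "respondent_id",
    "country",
    "cluster_id",
    "age_years",
    "gender",
    "education",
    "residence",
    "wealth_quintile",
)


def assign_age_group(age_years: int) -> str:
    """15-19 -> adolescent; 20+ -> adult; younger ages are outside the frame."""
    if age_years < 15:
        raise ValueError("age_years below 15 is outside the survey frame")
    return "adolescent" if age_years <= 19 else "adult"


def load_respondents(
    source: Union[str, Path, pd.DataFrame], policy: str = "strict"
) -> tuple[pd.DataFrame, list[str]]:
    """Read and validate a respondent table (CSV path or DataFrame).

    Food-group columns are validated row by row via
    :func:`dqqkit.taxonomy.validate_vector`; validation failures carry the
    offending respondent_id and columns.  Returns the cleaned table (0/1
    food columns, derived ``age_group``) and accumulated warnings.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source)
    else:
        df = source.copy()
    missing = [c for c in DEMOGRAPHIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if "weight" not in df.columns:
        df["weight"] = 1.0

    codes = food_group_codes()
    present = [c for c in codes if c in df.columns]
    if policy == "strict":
        absent = [c for c in codes if c not in df.columns]
        if absent:
            raise ValueError(f"missing food-group columns: {absent}")

    warnings: list[str] = []
    vectors = []
    for idx, row in df.iterrows():
        record = {c: row[c] for c in present}
        try:
            vec, w = validate_vector(record, policy=policy)
        except ValueError as err:
            rid = row.get("respondent_id", f"row {idx}")
            raise ValueError(f"respondent {rid}: {err}") from None
        warnings.extend(f"respondent {row['respondent_id']}: {msg}" for msg in w)
        vectors.append(vec.to_record())
    food = pd.DataFrame(vectors, index=df.index)
    out = pd.concat([df.drop(columns=present), food], axis=1)

    if (out["age_years"] < 15).any():
        bad = out.loc[out["age_years"] < 15, "respondent_id"].tolist()
        raise ValueError(f"respondents below the 15+ frame: {bad}")
    out["age_group"] = out["age_years"].map(assign_age_group)
    return out, warnings


# ---------------------------------------------------------------------------
# Row helpers
# ---------------------------------------------------------------------------


def _fmt_pct(pct: float, freq: int) -> str:
    return f"{pct:.1f} ({freq})"


def _fmt_median(med: float, q1: float, q3: float) -> str:
    def _i(x: float) -> str:
        return f"{x:g}"

    return f"{_i(med)} [{_i(q1)}–{_i(q3)}]"


def _fmt_chi2(res: ComparisonResult) -> str:
    return (
        f"χ² ({res.design_df}, N = {res.n}) = {res.statistic:.1f}, "
        f"{format_p(res.p_value)}"
    )


def _fmt_mw(res: ComparisonResult) -> str:
    return format_p(res.p_value)


def _try_chi2(sub: pd.DataFrame, outcome: pd.Series, group_col: str) -> Optional[ComparisonResult]:
    """Cluster-adjusted chi-square, or None when the row is not testable."""
    try:
        return cluster_adjusted_chi2(
            outcome, sub[group_col], sub["cluster_id"], weights=sub["weight"]
        )
    except ValueError:
        return None


def _proportion_row(
    label: str,
    sub: pd.DataFrame,
    flags: pd.Series,
    group_col: str,
    levels: Sequence[str],
    section: str = "",
    test_res: Optional[ComparisonResult] = "compute",  # sentinel
) -> dict:
    row: dict = {"section": section, "label": label, "kind": "proportion"}
    for lev in levels:
        mask = sub[group_col] == lev
        if mask.sum() == 0:
            raise ValueError(f"grouping level {lev!r} is empty")
        s = proportion_summary(flags[mask], weights=sub.loc[mask, "weight"], group_label=lev)
        row[f"value_{lev}"] = s.proportion_pct
        row[f"freq_{lev}"] = s.frequency
        row[f"display_{lev}"] = _fmt_pct(s.proportion_pct, s.frequency)
    if isinstance(test_res, str) and test_res == "compute":
        test_res = _try_chi2(sub, flags, group_col)
    if isinstance(test_res, str) and test_res == "omit":
        # continuation row of a multi-level block; the omnibus test sits on
        # the block's first row
        row.update(test="", statistic=np.nan, p_value=np.nan, testable=False)
    elif test_res is None:
        row.update(test=NOT_TESTABLE, statistic=np.nan, p_value=np.nan, testable=False)
    else:
        row.update(
            test=_fmt_chi2(test_res),
            statistic=test_res.statistic,
            p_value=test_res.p_value,
            testable=True,
        )
    return row


def _median_row(
    label: str,
    sub: pd.DataFrame,
    values: pd.Series,
    group_col: str,
    levels: Sequence[str],
    section: str = "",
) -> dict:
    row: dict = {"section": section, "label": label, "kind": "median"}
    samples = []
    for lev in levels:
        mask = sub[group_col] == lev
        if mask.sum() == 0:
            raise ValueError(f"grouping level {lev!r} is empty")
        med, q1, q3 = median_iqr(values[mask])
        row[f"value_{lev}"] = med
        row[f"q1_{lev}"] = q1
        row[f"q3_{lev}"] = q3
        row[f"display_{lev}"] = _fmt_median(med, q1, q3)
        samples.append(values[mask].to_numpy(dtype=float))
    if len(samples) == 2:
        res = mann_whitney_u(samples[0], samples[1])
        row.update(
            test=_fmt_mw(res), statistic=res.statistic, p_value=res.p_value, testable=True
        )
    else:
        row.update(test=NOT_TESTABLE, statistic=np.nan, p_value=np.nan, testable=False)
    return row


# ---------------------------------------------------------------------------
# Table builders
# ---------------------------------------------------------------------------


def build_sociodemographic_table(df: pd.DataFrame) -> pd.DataFrame:
    """Demographics by age group with cluster-adjusted chi-square comparisons.

    Education unknowns are excluded from the education comparison and
    footnoted as a count; multi-level blocks (country, wealth quintile) carry
    one omnibus test on their first row.
    """
    levels = ["adolescent", "adult"]
    rows = []
    rows.append(
        _proportion_row("Gender, female", df, df["gender"] == "female", "age_group", levels)
    )

    known = df[df["education"] != "unknown"]
    n_unknown = int((df["education"] == "unknown").sum())
    edu_row = _proportion_row(
        "Completed primary education or less",
        known,
        known["education"] == "completed_primary_or_less",
        "age_group",
        levels,
    )
    edu_row["footnote"] = (
        f"education unknown/refused for {n_unknown} respondent(s), excluded"
        if n_unknown
        else ""
    )
    rows.append(edu_row)

    rows.append(
        _proportion_row("Residence, rural", df, df["residence"] == "rural", "age_group", levels)
    )

    # country block: one omnibus test on the first row
    omnibus = _try_chi2(df, df["country"], "age_group")
    for i, country in enumerate(sorted(df["country"].unique())):
        rows.append(
            _proportion_row(
                country,
                df,
                df["country"] == country,
                "age_group",
                levels,
                section="Country",
                test_res=omnibus if i == 0 else "omit",
            )
        )

    omnibus = _try_chi2(df, df["wealth_quintile"], "age_group")
    wealth_labels = {
        1: "Poorest quintile", 2: "Second quintile", 3: "Third quintile",
        4: "Fourth quintile", 5: "Wealthiest quintile",
    }
    for i, q in enumerate(sorted(df["wealth_quintile"].unique())):
        rows.append(
            _proportion_row(
                wealth_labels.get(q, str(q)),
                df,
                df["wealth_quintile"] == q,
                "age_group",
                levels,
                section="Wealth quintile",
                test_res=omnibus if i == 0 else "omit",
            )
        )
    table = pd.DataFrame(rows)
    if "footnote" not in table.columns:
        table["footnote"] = ""
    table["footnote"] = table["footnote"].fillna("")
    return table


def build_food_group_table(df: pd.DataFrame) -> pd.DataFrame:
    """29-row food-group consumption table by age group, in taxonomy order."""
    levels = ["adolescent", "adult"]
    for lev in levels:
        if (df["age_group"] == lev).sum() == 0:
            raise ValueError(f"age group {lev!r} is missing from the dataset")
    rows = []
    for fg in canonical_food_groups():
        section = "Foods to promote" if fg.category == "promote" else "Foods to limit"
        rows.append(
            _proportion_row(
                fg.label, df, df[fg.code].astype(bool), "age_group", levels, section=section
            )
        )
    return pd.DataFrame(rows)


_ALL5_SUBROWS = (
    ("all5_vegetable", "At least one vegetable"),
    ("all5_fruit", "At least one fruit"),
    ("all5_pulse_nut_seed", "At least one pulse/nut/seed"),
    ("all5_animal_source_food", "At least one animal-source food"),
    ("all5_starchy_staple_food", "At least one starchy staple food"),
)


def build_indicator_table(
    df: pd.DataFrame, scores: pd.DataFrame, grouping: str = "age"
) -> pd.DataFrame:
    """Diet-quality indicator table by age group, gender or residence.

    Score rows (FGDS, NCD-Protect, NCD-Risk, GDR) report median [IQR] and a
    Mann-Whitney test; binary rows report percent (frequency) and a
    cluster-adjusted chi-square; MDD-W is restricted to women aged 15-49.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {sorted(GROUPINGS)}")
    group_col, levels = GROUPINGS[grouping]
    for lev in levels:
        if (df[group_col] == lev).sum() == 0:
            raise ValueError(f"grouping level {lev!r} is empty")
    rows = []
    rows.append(
        _median_row("Food group diversity score", df, scores["fgds"], group_col, levels)
    )

    eligible = scores["mddw"].notna()
    if eligible.any():
        sub = df[eligible]
        flags = scores.loc[eligible, "mddw"].astype(bool)
        try:
            mrow = _proportion_row(
                "Minimum dietary diversity—women", sub, flags, group_col, levels
            )
        except ValueError:
            # a grouping level with no eligible women (e.g. gender = male)
            mrow = {
                "section": "", "label": "Minimum dietary diversity—women",
                "kind": "proportion", "test": NOT_TESTABLE,
                "statistic": np.nan, "p_value": np.nan, "testable": False,
            }
            for lev in levels:
                mask = sub[group_col] == lev
                if mask.sum():
                    s = proportion_summary(flags[mask], weights=sub.loc[mask, "weight"])
                    mrow[f"value_{lev}"] = s.proportion_pct
                    mrow[f"freq_{lev}"] = s.frequency
                    mrow[f"display_{lev}"] = _fmt_pct(s.proportion_pct, s.frequency)
                else:
                    mrow[f"display_{lev}"] = NOT_TESTABLE
        mrow["footnote"] = "among women of reproductive age (15–49 years)"
        rows.append(mrow)

    rows.append(_proportion_row("All-5", df, scores["all5"].astype(bool), group_col, levels))
    for col, label in _ALL5_SUBROWS:
        rows.append(_proportion_row(label, df, scores[col].astype(bool), group_col, levels))

    rows.append(_median_row("NCD-Protect score", df, scores["ncd_protect"], group_col, levels))
    rows.append(_median_row("NCD-Risk score", df, scores["ncd_risk"], group_col, levels))
    rows.append(
        _median_row("Global dietary recommendations score", df, scores["gdr"], group_col, levels)
    )
    for col, label in (
        ("zero_fruit_veg", "Zero fruit/vegetable consumption"),
        ("sweet_beverage", "Sweet beverage consumption"),
        ("unhealthy_upf", "Unhealthy/ultra-processed food consumption"),
    ):
        rows.append(_proportion_row(label, df, scores[col].astype(bool), group_col, levels))
    table = pd.DataFrame(rows)
    if "footnote" not in table.columns:
        table["footnote"] = ""
    table["footnote"] = table["footnote"].fillna("")
    return table


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


@dataclass
class ReportBundle:
    """All report tables plus run metadata."""

    sociodemographic: pd.DataFrame
    food_groups: pd.DataFrame
    indicators_by_age: pd.DataFrame
    indicators_by_gender: pd.DataFrame
    indicators_by_residence: pd.DataFrame
    scores: pd.DataFrame
    metadata: dict

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sociodemographic.to_csv(out / "sociodemographic.csv", index=False)
        self.food_groups.to_csv(out / "food_groups.csv", index=False)
        self.indicators_by_age.to_csv(out / "indicators_by_age.csv", index=False)
        self.indicators_by_gender.to_csv(out / "indicators_by_gender.csv", index=False)
        self.indicators_by_residence.to_csv(out / "indicators_by_residence.csv", index=False)
        self.scores.to_csv(out / "scores.csv", index=False)
        with open(out / "metadata.json", "w", encoding="utf-8") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)


def run_pipeline(
    source: Union[str, Path, pd.DataFrame, ScenarioConfig],
    out_dir: Optional[Union[str, Path]] = None,
    policy: str = "strict",
) -> ReportBundle:
    """Run the full analysis: load or simulate, score, summarize, compare.

    ``source`` may be a respondent CSV path, an in-memory respondent table,
    or a :class:`ScenarioConfig` (which is generated first).  Deterministic
    given the input and, for scenarios, the config seed.
    """
    warnings: list[str] = []
    if isinstance(source, ScenarioConfig):
        dataset = generate_population(source)
        df, w = load_respondents(dataset.frame, policy=policy)
        meta_source = {"scenario": source.to_dict(), "provenance": dataset.provenance}
    else:
        df, w = load_respondents(source, policy=policy)
        meta_source = {"input": str(source) if isinstance(source, (str, Path)) else "dataframe"}
    warnings.extend(w)

    scores = score_table(df)
    score_out = pd.concat([df[["respondent_id"]], scores], axis=1)
    # not-applicable MDD-W serialized as empty field
    score_out["mddw"] = scores["mddw"].map(lambda x: "" if pd.isna(x) else int(x))

    bundle = ReportBundle(
        sociodemographic=build_sociodemographic_table(df),
        food_groups=build_food_group_table(df),
        indicators_by_age=build_indicator_table(df, scores, "age"),
        indicators_by_gender=build_indicator_table(df, scores, "gender"),
        indicators_by_residence=build_indicator_table(df, scores, "residence"),
        scores=score_out,
        metadata={
            "dqqkit_version": __version__,
            "n_respondents": int(len(df)),
            "n_adolescents": int((df["age_group"] == "adolescent").sum()),
            "n_adults": int((df["age_group"] == "adult").sum()),
            "policy": policy,
            "warnings": warnings,
            **meta_source,
        },
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
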