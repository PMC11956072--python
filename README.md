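# dqqkit

Diet-quality indicator scoring and design-based survey analysis for
24-hour dietary recall data collected with the Diet Quality Questionnaire
(DQQ).

## The problem

Population surveys increasingly measure diet quality with the DQQ: a rapid
24-hour recall asking yes/no consumption of 29 food groups. From that
vector a standard suite of nine population-level indicators is computed,
covering both the healthy and the unhealthy side of the diet:

| indicator | definition | range |
|---|---|---|
| FGDS | count of 10 aggregated food groups consumed (grains/tubers, pulses, nuts/seeds, dairy, meat/poultry/fish, eggs, dark green leafy vegetables, other vitamin-A-rich fruits/vegetables, other vegetables, other fruits) | 0–10 |
| MDD-W | FGDS ≥ 5, defined for women aged 15–49 (proxy for micronutrient adequacy) | yes/no |
| All-5 | all five daily-recommended groups consumed: starchy staples, vegetables, fruits, pulses/nuts/seeds, animal-source foods | yes/no |
| NCD-Protect | one point per protective group consumed (whole grains, pulses, nuts/seeds, 3 vegetable groups, 3 fruit groups) | 0–9 |
| NCD-Risk | one point per risk item consumed — soft drinks, baked/grain-based sweets, other sweets, unprocessed red meat, deep-fried foods, fast food/instant noodles, salty snacks — and **two** points for processed meat | 0–9 |
| GDR | NCD-Protect − NCD-Risk + 9 | 0–18 |
| zero fruit/vegetable | none of the 6 fruit/vegetable groups consumed | yes/no |
| sweet beverage | any of soft/energy drinks, fruit juice/drinks, sweet tea/coffee/cocoa | yes/no |
| unhealthy/UPF | any of sweets (2 groups), salty snacks, instant noodles, deep-fried foods, fast food | yes/no |

Such surveys are multistage cluster samples: respondents within a primary
sampling unit are correlated, which inflates the variance of estimated
proportions. dqqkit therefore compares groups with a **Rao–Scott
cluster-adjusted Pearson χ²** (Satterthwaite second-order correction, F
reference) for proportions and the **Mann–Whitney U** rank-sum test for
score distributions, and reports proportions with frequencies and medians
with interquartile ranges in the conventional survey-report layout.

Because the microdata such analyses rest on are typically access-restricted,
dqqkit also ships a **synthetic survey generator**: five countries of ~1000
respondents aged 15+, in-person countries as 100–125 clusters × 8–10
interviews, telephone countries as independent respondents, a
beta-binomial cluster random effect with exact marginal prevalence and
configurable intra-cluster correlation, and per-food-group prevalences
configured separately for adolescents (15–19) and adults (20+). Every
downstream stage is testable against known generating parameters.

## Worked example

```python
from dqqkit import FoodGroupVector, Respondent, score_respondent

diet = FoodGroupVector.from_groups([
    "grain_based_staple_foods", "dark_green_leafy_vegetables",
    "other_vegetables", "eggs", "fish_and_seafood", "other_fruits",
    "instant_noodles", "other_sweets", "sweet_tea_coffee_cocoa",
])
r = Respondent(respondent_id="example-001", country="Cambodia",
               cluster_id="KH-C0001", age_years=17, gender="female",
               education="more_than_primary", residence="rural",
               wealth_quintile=3, diet=diet)
print(score_respondent(r))
```

prints (see `examples/score_one_day.py`)

```
FGDS (0-10 food groups):      6
MDD-W (FGDS >= 5, women 15-49): True
All-5:                        False  (no pulse/nut/seed consumed)
NCD-Protect (0-9):            3
NCD-Risk (0-9):               2
GDR = Protect - Risk + 9:     10
Zero fruit/vegetable:         False
Any sweet beverage:           True
Any unhealthy/UPF food:       True
```

— a diverse day (6 of 10 food groups, MDD-W met) that still includes three
foods-to-limit groups, so the GDR score sits mid-range.

The full pipeline — simulate, validate, score, build the
sociodemographic / food-group / indicator tables with cluster-adjusted
comparisons — is one call (`examples/full_report.py`), or from the shell:

```sh
dqq all --out report/ --seed 1
dqq simulate --out data.csv --seed 3
dqq score --in data.csv --out scores.csv
dqq report --in data.csv --out report/
```

Other narrative examples live in `examples/`: `simulate_survey.py`
(generator structure and parameter recovery) and `compare_groups.py` (the
two comparison tests on a simulated adolescent-vs-adult contrast).

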