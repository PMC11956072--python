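"""Score a single day's recall into the nine diet-quality indicators.

Builds one consumption vector by hand — a fairly typical Southeast Asian
day: rice, leafy greens and other vegetables, eggs, fish, fruit, plus
instant noodles, a sweet and a sweetened coffee — and prints every
indicator for a 17-year-old girl.
"""

from dqqkit import FoodGroupVector, Respondent, score_respondent

diet = FoodGroupVector.from_groups(
    [
        "grain_based_staple_foods",
        "dark_green_leafy_vegetables",
        "other_vegetables",
        "eggs",
        "fish_and_seafood",
        "other_fruits",
        "instant_noodles",
        "other_sweets",
        "sweet_tea_coffee_cocoa",
    ]
)

respondent = Respondent(
    respondent_id="example-001",
    country="Cambodia",
    cluster_id="KH-C0001",
    age_years=17,
    gender="female",
    education="more_than_primary",
    residence="rural",
    wealth_quintile=3,
    diet=diet,
)

result = score_respondent(respondent)

print(f"FGDS (0-10 food groups):      {result.fgds}")
print(f"MDD-W (FGDS >= 5, women 15-49): {result.mddw}")
print(f"All-5:                        {result.all5}  {result.all5_components}")
print(f"NCD-Protect (0-9):            {result.ncd_protect}")
print(f"NCD-Risk (0-9):               {result.ncd_risk}")
print(f"GDR = Protect - Risk + 9:     {result.gdr}")
print(f"Zero fruit/vegetable:         {result.zero_fruit_veg}")
print(f"Any sweet beverage:           {result.sweet_beverage}")
print(f"Any unhealthy/UPF food:       {result.unhealthy_upf}")
print()
print(
    "A FGDS of 6 with MDD-W met shows adequate diversity, but three of the\n"
    "unhealthy groups were consumed, so NCD-Risk pulls the GDR score below\n"
    "the protect-side maximum: diverse but not entirely healthy."
)
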