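"""Run the whole pipeline and print the indicator table by age group.

Equivalent to ``dqq all --out report/ --seed 1`` but from Python: simulate
the default scenario, validate, score, and build the three report tables
with cluster-adjusted comparisons.
"""

from dqqkit import default_scenario, run_pipeline

bundle = run_pipeline(default_scenario(seed=1), out_dir="scratch/example_report")

table = bundle.indicators_by_age
print(table[["label", "display_adolescent", "display_adult", "test"]].to_string(index=False))
print()
print(f"n = {bundle.metadata['n_respondents']} "
      f"({bundle.metadata['n_adolescents']} adolescents, "
      f"{bundle.metadata['n_adults']} adults)")
print("Score rows show median [IQR] with Mann-Whitney p-values; binary rows")
print("show percent (count) with cluster-adjusted chi-square tests; an em")
print("dash marks rows with no outcome variation, which are not testable.")
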