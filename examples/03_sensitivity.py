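"""One-way deterministic sensitivity analysis of the expenditure savings.

For each sex and intervention scenario, each input (incidence, prevalence,
mortality rates, relative risk, discount rate) is swung across its
confidence interval or plausible range while everything else stays at the
point estimate. Rows are sorted tornado-style, widest interval first.
"""

from milkstroke.parameters import load_parameter_set
from milkstroke.sensitivity import sensitivity_report

params = load_parameter_set("paper2023")
report = sensitivity_report(params)

print(report.to_string(index=False, float_format=lambda x: f"{x:,.0f}"))

widest = report.sort_values("width_usd", ascending=False).iloc[0]
print()
print(
    f"Most influential input: {widest['parameter']} "
    f"({widest['scenario']}, {widest['sex']}) — savings range "
    f"USD {widest['lower_usd']:,.0f} to {widest['upper_usd']:,.0f}"
)
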