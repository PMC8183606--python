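"""Evaluate the base-case decision model and print the headline results.

Both strategy arms are costed on a yearly cohort of 2,923,535 live births:
the screening arm bills every newborn the filter-paper 17-OHP test and pushes
screen-positive unaffected newborns through the recall cascade; the
clinical-diagnosis arm accrues deaths among unrecognized salt-wasting cases
plus the short- and long-term costs of delayed diagnosis.
"""

from cahscreen import evaluate_scenario, preset

params = preset("base")
screened, unscreened, result = evaluate_scenario(params)

print("screening-arm ledger:")
print(screened.to_frame().to_string(index=False))
print("\nclinical-diagnosis arm ledger:")
print(unscreened.to_frame().to_string(index=False))

print(f"\nscreening-arm total cost:   US$ {screened.total_cost:>13,}")
print(f"clinical-arm total cost:    US$ {unscreened.total_cost:>13,}")
print(f"incremental cost:           US$ {result.incremental_cost:>13,}")
print(f"deaths averted per year:    {result.deaths_averted}")
print(f"cost per death averted:     US$ {result.cost_per_death_averted:,}")
print(f"ICER:                       US$ {result.icer:,} per discounted life-year")

# The ICER divides the incremental cost by deaths averted x 30.2 discounted
# life-years per death (3% rate over 76 years of life expectancy). Values
# below roughly 3x GDP per capita are conventionally called cost-effective.
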