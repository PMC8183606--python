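"""One-way sensitivity analysis and scenario comparison.

Each of the four reference ranges (CAH incidence, the SW/SV clinical
recognition pair, SW mortality without screening, first-tier false-positive
rate) is swept while all other parameters stay at base case; the tornado
table orders them by how much they move the ICER.
"""

from cahscreen import preset, reference_ranges, scenario_comparison, tornado, tornado_to_frame

base = preset("base")

rows = tornado(base, reference_ranges())
print("tornado table (ICER at range endpoints, US$/LY, widest span first):")
print(tornado_to_frame(rows).to_string(index=False))

print("\nscenario comparison:")
table = scenario_comparison([preset(n) for n in ("base", "best", "worst", "group3_2000")])
print(table[["label", "incremental_cost_usd", "deaths_averted",
             "icer_usd_per_ly"]].to_string(index=False))

# Mortality and clinical recognition dominate the ICER: they differ most
# between health systems, which is why a local cost-effectiveness analysis
# can reach a different conclusion than one imported from another country.
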