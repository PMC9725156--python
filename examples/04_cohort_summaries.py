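"""Descriptive delay and node-count summaries of a cohort.

Produces the two standard summary shapes: cohort-wide node counts and
global delay measures split by demand/supply, and per-node-type encounter
frequency with each type's marginal-delay contribution per side.
"""

from ptcdelay import (aggregate_decompositions, decompose_delays,
                      default_config, simulate_cohort, summarize_global,
                      summarize_node_types)

cohort = simulate_cohort(default_config(seed=42))
ds = [decompose_delays(p) for p in cohort.pathways.values()]
table = aggregate_decompositions(ds, cohort.covariates)

gs = summarize_global(table)
print("global delay measures (days):")
print(gs.delays.round(1))
print("\nThe demand/supply percentages partition total delay-days;")
print("the onset-delay row shows how much of DUP precedes any help-seeking.")

nt = summarize_node_types(table).set_index("node_type")
cols = ["total_encounters", "demand_encounters", "supply_encounters",
        "demand_delay_median", "supply_delay_median"]
print("\nper-node-type summary (top rows):")
print(nt[cols].head(8).round(1))
print("\nClinical nodes with large per-encounter medians are the")
print("highest-leverage targets for delay-reduction outreach.")
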