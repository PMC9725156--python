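"""Decompose the fully dated worked-example pathway.

A single nine-day help-seeking journey is split into its onset delay and
per-encounter marginal delays, and the Duration of Untreated Psychosis is
partitioned into the demand side (onset to first antipsychotic) and the
supply side (antipsychotic to service enrollment).
"""

from ptcdelay import decompose_delays, demo_pathway

p = demo_pathway()
d = decompose_delays(p)

print(f"DUP-total  = {d.dup_total} days  (onset to enrollment)")
print(f"DUP-demand = {d.dup_demand} days  (onset to first antipsychotic)")
print(f"DUP-supply = {d.dup_supply} days  (antipsychotic to enrollment)")
print(f"onset delay = {d.onset_delay} days (onset to first help-seeking)")
print("\nper-encounter marginal delays (days until the next node):")
for m in d.marginal_delays:
    print(f"  {m.seq_index}. {m.node_type:<15} {m.side:<7} {m.delay}")
print("\nEvery day of the 9-day DUP is attributed to exactly one node:")
print("onset delay + sum of marginal delays =",
      d.onset_delay + sum(m.delay for m in d.marginal_delays))
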