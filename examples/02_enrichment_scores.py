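"""Compute log2E and Δlog2E from a simulated selection round.

One variant carries a 2x selection advantage per round over the parent; over
three rounds its expected enrichment relative to the parent is
3 * log2(2) = 3 log2 units.
"""

import mutascan as m
from mutascan.validation import default_panel

parent = m.SYNTHETIC_PARENT
mut = m.Mutation(5, "Y", "W")
variant = m.apply_mutations(parent, {mut})

model = m.AffinityModel(parent, ["CCL2"], effects={(mut, "CCL2"): 1.0})
cfg = m.SelectionSimConfig(rounds=3, depth=100_000, seed=7)
input_counts, outputs = m.simulate_selection({parent: 0.5, variant: 0.5}, model, cfg)

library = {parent, variant}
ft_in = m.compute_frequencies(input_counts, library, mode="add_one")
ft_out = m.compute_frequencies(outputs["CCL2"], library, mode="add_one")
table = m.compute_delta(m.build_enrichment(ft_in, {"CCL2": ft_out}), parent)

print(table[["variant", "target", "log2E", "delta_log2E"]].to_string(index=False))
delta = table.set_index("variant").loc[variant, "delta_log2E"]
print(f"\nΔlog2E of the advantaged variant: {delta:.3f} (expected ≈ 3.0)")
# Δlog2E is the variant's log2(output/input frequency) minus the parent's;
# proportional selection over r rounds gives r * log2(weight ratio).
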