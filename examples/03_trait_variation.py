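"""Trait-variation table: min, max, Max/Min, mean, CV and one-way ANOVA.

Shows how much each seed trait and tolerance index varies among
populations, and whether the among-population differences are significant.
"""

from seedtol import SimulationConfig, compute_indices, indices_to_frame, simulate_study, summarize_table
from seedtol.descriptives import format_summary

sites, traits, trials = simulate_study(SimulationConfig(random_seed=42))
table = traits.merge(indices_to_frame(compute_indices(trials)),
                     on=["population_id", "replicate"])

summary = format_summary(summarize_table(table), decimals=2)
print(summary.to_string(index=False))
print("\nMax/Min > 2 or CV > 20% flags a highly variable trait; the F test")
print("compares the 21 populations with replicates as observations (df = 20).")
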