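"""Compute germination and stress-tolerance indices for one population.

Builds a small hand-written drought/cold/saline experiment (5 levels x 1
replicate, 50 seeds per dish), computes the speed-weighted germination
index per dish and the three tolerance indices, and prints them.
"""

from seedtol import GerminationTrial, TreatmentScheme, compute_indices, germination_index

scheme = TreatmentScheme()

# daily newly-germinated counts per treatment level: germination gets
# slower and sparser as the stress level rises
counts_by_level = {
    1: (30, 12, 5),
    2: (22, 10, 4),
    3: (14, 8, 3),
    4: (6, 4, 2),
    5: (2, 1, 0),
}

trials = [
    GerminationTrial(
        population_id="P01",
        experiment=experiment,
        level_index=level,
        level_value=scheme.levels(experiment)[level - 1],
        replicate=1,
        daily_counts=counts,
    )
    for experiment in ("drought", "cold", "saline")
    for level, counts in counts_by_level.items()
]

print("GI per drought dish (speed-weighted germination count, Sum n_d/d):")
for trial in trials[:5]:
    print(f"  level {trial.level_index} ({trial.level_value:+.1f} MPa): "
          f"GI = {germination_index(trial):.2f}")

[indices] = compute_indices(trials, scheme)
print(f"\nGDTI = {indices.gdti:.2f}   (drought weights 1..2.2 on the 5 levels)")
print(f"GCTI = {indices.gcti:.2f}   (cold weights 1..5)")
print(f"GSTI = {indices.gsti:.2f}   (saline weights 1, 5..20)")
print("\nHigher values mean more germination retained under harsher stress.")
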