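"""Generate a seeded synthetic study and look at what it contains.

The generator emulates the real inputs of the signature pipeline: a
multi-source interaction edge list with a false-positive fraction, a
training expression cohort stratified by ER status and histologic grade,
a held-out test cohort, and the ground-truth planted module genes.
"""

from rrhge import SimulationConfig, generate_study

config = SimulationConfig(seed=42)
fixture = generate_study(config)

print(f"interaction records : {len(fixture.records)}")
print(f"training cohort     : {fixture.train_values.shape[0]} genes x "
      f"{fixture.train_values.shape[1]} samples")
print(fixture.train_metadata.groupby(['er_status', 'grade']).size()
      .rename('samples').to_string())
print(f"test cohort         : {fixture.test_values.shape[1]} samples")
print(f"planted ER+ module  : {', '.join(fixture.truth['er_pos'])}")
print(f"planted ER- module  : {', '.join(fixture.truth['er_neg'])}")
print()
print("Planted-module genes are shifted upward by 0.5 in their ER side's")
print("samples (all grades) and densely wired with rich multi-source")
print("evidence; everything is reproducible from the seed.")
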