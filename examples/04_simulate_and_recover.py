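"""Generate a synthetic survey and recover its ground truth.

The generator emits a 519-individual observation table shaped like the
reference survey (19 families, 196 species, family-specific pattern
frequencies, ~11% asymmetric individuals, ~21% polymorphic species) plus
per-row true identities.  Running the pipeline back over the table scores
how faithfully labeling, classification and the bilateral/polymorphism
flags recover the truth.
"""

from sixocellus import GeneratorConfig, generate_survey, verify_recovery

# noiseless study conditions: recovery must be exact
df, truth = generate_survey(GeneratorConfig(position_noise_sd=0.0, seed=11))
rep = verify_recovery(df, truth)
print(f"zero noise: {rep.n_observations} observations, "
      f"label accuracy {100 * rep.label_accuracy:.1f}%, "
      f"pattern accuracy {100 * rep.pattern_accuracy:.1f}%")

# default conditions: positional jitter around the sector templates
df, truth = generate_survey(GeneratorConfig(seed=11))
rep = verify_recovery(df, truth)
print(f"with noise:  label accuracy {100 * rep.label_accuracy:.2f}%, "
      f"asymmetric share {100 * rep.asymmetric_fraction_sighted:.1f}% of sighted, "
      f"{rep.polymorphic_species_count} polymorphic species")
# Zero-noise recovery is exact; under jitter, accuracy stays >99% and the
# recovered asymmetry sits near the configured 11% loss rate.
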