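"""Survey-wide statistics from an observation table.

Labels every side, reconciles each individual's two sides under the
bilateral subset rule, aggregates species morphs, and reports asymmetry
and polymorphism with explicit denominators.
"""

from sixocellus import GeneratorConfig, generate_survey, run_survey

df, _ = generate_survey(GeneratorConfig(seed=3))
labeled, species, report = run_survey(df)

print(f"{report.n_individuals} individuals, {report.n_species} species, "
      f"{report.n_genera} genera")
print(f"asymmetric individuals: {report.asymmetric_count} "
      f"({100 * report.asymmetric_fraction:.1f}% of all, "
      f"{100 * report.asymmetric_fraction_sighted:.1f}% of ocellus-bearing)")
print(f"polymorphic species: {report.polymorphic_species_count} "
      f"({100 * report.polymorphic_species_fraction:.1f}%)")
print("\nspecies modal patterns by family (nonzero columns):")
table = report.per_family_pattern
print(table.loc[:, table.sum() > 0])
# Asymmetry is a per-individual count difference between sides; the
# survey-style percentage uses all individuals, while the sighted
# denominator excludes eyeless taxa that cannot express it.
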