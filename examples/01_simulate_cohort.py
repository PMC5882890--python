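"""Generate a small synthetic cohort and inspect its ground truth.

The generator emulates a two-phase population study: plasma protein levels
(NPX) driven by covariates, sparse cis/trans genetic effects, confounded
medication use, plate batch shifts and noise, with per-protein limits of
detection.
"""

import plasmaprot as pp

cfg = pp.SimulationConfig(
    n_discovery=300, n_replication=150, n_proteins=30, n_variants=100,
    n_low_abundance=2, seed=42,
)
cohort = pp.generate_cohort(cfg)

print(f"individuals: {len(cohort.cohort)} "
      f"({(cohort.cohort.subcohort == 'discovery').sum()} discovery)")
print(f"NPX records: {len(cohort.npx)}  censored: {cohort.npx.below_lod.sum()}")
print(f"injected pQTLs: {len(cohort.truth.pqtl_effects)}  "
      f"drug-protein effects: {len(cohort.truth.medication_deltas)}")
print("\nrealized variance fractions (first 5 proteins):")
print(cohort.truth.variance_fractions.head().round(3).to_string())
# each row decomposes one protein's between-individual variance into the
# covariate, genetic, medication, batch and noise components the generator
# actually produced
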