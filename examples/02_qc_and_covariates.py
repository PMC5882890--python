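"""Batch normalization, LOD filtering and the covariate screen.

Prints, per the screen, how many proteins have at least one covariate
association at the nominal and at the Bonferroni level, and the span of
variance explained by the combined covariate models (Cox & Snell R2).
"""

import warnings

import plasmaprot as pp
from plasmaprot.io import medication_wide, npx_wide

warnings.filterwarnings("ignore")

cfg = pp.SimulationConfig(
    n_discovery=400, n_replication=200, n_proteins=60, n_variants=50,
    n_low_abundance=3, seed=7,
)
c = pp.generate_cohort(cfg)

normed, shifts = pp.normalize_batches(c.npx)
filtered, report = pp.filter_lod(normed)
print(f"proteins retained: {report.proteins_retained}/{report.proteins_in} "
      f"(removed: below 20% of measurements above LOD)")

wide = npx_wide(filtered)
med = medication_wide(c.medication, wide.index)
screen = pp.screen_all(wide, c.cohort, med)

n_prot = wide.shape[1]
nominal = screen.loc[screen.p_single < 0.05, "protein_id"].nunique()
bonf = screen.loc[screen.significant, "protein_id"].nunique()
r2 = screen.groupby("protein_id")["r2_combined"].first()
print(f"proteins with a nominal covariate association: {nominal}/{n_prot}")
print(f"after Bonferroni over (covariates x proteins):  {bonf}/{n_prot}")
print(f"combined-model variance explained: {100 * r2.min():.1f}% - {100 * r2.max():.1f}%")
# the Bonferroni-significant covariates of each protein are what the pQTL
# and medication stages adjust for
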