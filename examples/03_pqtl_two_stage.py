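"""Two-stage pQTL mapping: discovery, replication, cis/trans, top markers.

Each protein is residualized on its significant covariates, rank-inverse-
normal transformed, and scanned against all QC-passing variants; hits need
genome-wide Bonferroni significance in the discovery subcohort and
alpha/k significance in the replication subcohort.
"""

import warnings

import plasmaprot as pp
from plasmaprot.io import medication_wide, npx_wide

warnings.filterwarnings("ignore")

cfg = pp.SimulationConfig(
    n_discovery=500, n_replication=250, n_proteins=50, n_variants=400,
    n_low_abundance=2, seed=3,
)
c = pp.generate_cohort(cfg)
filtered, _ = pp.filter_lod(pp.normalize_batches(c.npx)[0])
wide = npx_wide(filtered)
med = medication_wide(c.medication, wide.index)
screen = pp.screen_all(wide, c.cohort, med)

res = pp.pqtl_pipeline(wide, c.cohort, c.dosage, c.genemap, screen, med)
print(f"variants passing QC: {int(res.variant_qc.passed.sum())}/{len(res.variant_qc)}")
print(f"discovery threshold: p < {res.two_stage.discovery_threshold:.3g}")
print(f"proteins with a discovery hit: {len(res.two_stage.proteins_discovery)}")
print(f"proteins replicated:            {len(res.two_stage.proteins_replicated)} "
      f"(of {len(c.truth.pqtl_effects)} injected pQTLs)")
top = res.top_markers
if len(top):
    pct_cis = 100 * top.cis.astype("boolean").mean()
    print(f"top markers in cis (<35 kb from the encoding gene): {pct_cis:.0f}%")
    print(f"raw-abundance variance explained by the top marker: "
          f"{100 * top.variance_explained.min():.1f}% - "
          f"{100 * top.variance_explained.max():.1f}%")
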