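"""The statin and hypertension clinical workflows.

Statins: poolability of substances, adjusted scan against non-users of
lipid-modifying drugs, and the LDL Spearman confounding screen.
Hypertension: group definition (blood pressure / self-report / medication),
per-drug-class transfer-adjusted comparisons and their overlap.
"""

import warnings

import plasmaprot as pp
from plasmaprot.io import medication_wide, npx_wide

warnings.filterwarnings("ignore")

cfg = pp.SimulationConfig(
    n_discovery=550, n_replication=250, n_proteins=40, n_variants=20,
    n_low_abundance=2, seed=8,
)
c = pp.generate_cohort(cfg)
filtered, _ = pp.filter_lod(pp.normalize_batches(c.npx)[0])
wide = npx_wide(filtered)
med = medication_wide(c.medication, wide.index)
screen = pp.screen_all(wide, c.cohort, med)

st = pp.statin_workflow(wide, c.cohort, med, screen)
print("statins")
print(st.lipid_comparisons.round(3).to_string(index=False))
print(f"substances poolable: {st.pooled}")
sig = st.comparisons[st.comparisons.q_fdr < 0.05] if len(st.comparisons) else []
print(f"proteins associated with statin use (FDR): {len(sig)}; "
      f"LDL-confounded: {int(st.confound_flags.confounded.sum()) if len(st.confound_flags) else 0}; "
      f"clean: {len(st.clean_proteins)}")

hy = pp.hypertension_workflow(wide, c.cohort, med, screen)
n_group = int(hy.group.in_group.sum())
members = hy.group[hy.group.in_group]
print(f"\nhypertension group: {n_group} individuals "
      f"({members.regimen_class.value_counts().to_dict()})")
if len(hy.overlap):
    print("overlap of FDR-significant proteins across drug classes:")
    print(hy.overlap.to_string())
# diagonal = proteins affected by that class; off-diagonal = shared proteins
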