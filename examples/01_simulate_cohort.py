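"""Simulate a multi-dataset scRNA-seq cohort with planted disease signatures.

Builds the four-dataset study-shaped recipe (partially overlapping cell-type
repertoires, per-dataset batch effects, sample-level disease labels), draws
the cohort, and prints what was generated. The printed disease fractions are
per cell type and dataset — the quantity a transfer study reports alongside
performance, since a signature must survive such composition shifts.
"""

import sigtransfer as st

config = st.uc_study_config(seed=0)
cohort = st.generate_cohort(config)

print(f"{len(cohort.datasets)} datasets, {config.n_genes}-gene panel")
for ds in cohort.datasets:
    n_disease = int(ds.samples["disease_state"].sum())
    print(f"\n{ds.dataset_id}: {ds.n_cells} cells, "
          f"{len(ds.samples)} samples ({n_disease} disease)")
    for ct in ds.cell_types():
        frac = st.uc_fraction(ds, ct)
        n = int((ds.cell_type == ct).sum())
        print(f"  {ct:22s} {n:5d} cells, disease fraction {frac:.0%}")

sig = st.truth_signature(cohort, "Goblet Cell")
print(f"\nplanted Goblet Cell signature: {sig.genes} "
      f"(log2 fold changes {sig.log2_effects})")
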