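"""Search for candidate gene signatures on one (dataset, cell type) slice.

The evolutionary search explores 1-3-gene add/multiply structures, fits each
by maximum likelihood, and returns the ten best distinct structures. The
planted 2-gene signature should appear in the top candidates, surrounded by
three-gene variants that add little. 'Dominant features' are the genes that
recur across the shortlist — the stable core of the signal.
"""

import sigtransfer as st
from sigtransfer.cohort import recovery_cohort_config

cohort = st.generate_cohort(recovery_cohort_config(seed=2))
ds = st.normalize_log1p(cohort.datasets[0])
slice_ = st.slice_cell_type(ds, "Goblet Cell")

config = st.SearchConfig(population_size=64, generations=16, n_restarts_fit=2, seed=2)
candidates = st.search(slice_, config)

print(f"planted signature: {st.truth_signature(cohort, 'Goblet Cell').genes}")
print(f"\ntop {len(candidates)} structures (by training loss):")
for i, cand in enumerate(candidates, 1):
    print(f"{i:2d}. loss {cand.fit.loss:.4f}  PR AUC {cand.train_metrics.pr_auc:.3f}  "
          f"{cand.model.structure_key()}")

print(f"\ndominant features: {st.dominant_features(candidates)}")
print(f"best model: {candidates[0].model.expression()}")
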