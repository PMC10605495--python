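"""Median-conditioned response curve of a fitted signature.

The response curve shows the predicted disease probability as one signature
gene sweeps its observed range while the model's other genes are held at
their per-slice median — the standard way to read how a formula model uses a
gene. A monotone rise (or fall) along the grid is the model's directional
claim about that gene in disease.
"""

import sigtransfer as st
from sigtransfer.cohort import recovery_cohort_config
from sigtransfer.formula import Leaf, Node

cohort = st.generate_cohort(recovery_cohort_config(seed=1))
ds = st.normalize_log1p(cohort.datasets[0])
slice_ = st.slice_cell_type(ds, "Goblet Cell")
g1, g2 = st.truth_signature(cohort, "Goblet Cell").genes

model = st.FormulaModel(tree=Node("add", Leaf(g1), Leaf(g2)))
st.fit_parameters(model, slice_, n_restarts=5, seed=0, maxiter=300)

surface = st.response_surface(model, slice_, [g1], n_points=9)
print(f"model: {model.expression()}")
print(f"{g2} fixed at its median {surface.fixed_values[g2]:.3f}")
print(f"\n{g1:>8s}  P(disease)")
for x, p in zip(surface.grid[0], surface.probabilities):
    bar = "#" * int(40 * p)
    print(f"{x:8.3f}  {p:.3f} {bar}")
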