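"""How phylogeny-aware species weights combine q-scores across outgroups.

Vertebrate genome panels are phylogenetically biased (e.g. many primates);
naively multiplying evidence across outgroups lets oversampled clades
dominate.  The effective-number weights give every independent lineage one
unit of vote: duplicating a genome splits its weight instead of doubling it.
"""
import pandas as pd

from paralogon import combine_weighted, species_weights

panel = ["frog", "chicken", "human"]
sim = pd.DataFrame(
    [[1.0, 0.4, 0.4],
     [0.4, 1.0, 0.5],
     [0.4, 0.5, 1.0]],
    index=panel, columns=panel,
)
w = species_weights(sim)
print("weights:", {k: round(v, 3) for k, v in w.weights.items()})

q = {"frog": 0.02, "chicken": 0.10, "human": 0.08}
print("combined q:", round(combine_weighted(q, w), 5))

# add a second human-like genome: identical similarity row, identical q
panel2 = panel + ["human2"]
sim2 = pd.DataFrame(
    [[1.0, 0.4, 0.4, 0.4],
     [0.4, 1.0, 0.5, 0.5],
     [0.4, 0.5, 1.0, 1.0],
     [0.4, 0.5, 1.0, 1.0]],
    index=panel2, columns=panel2,
)
w2 = species_weights(sim2)
print("weights with a duplicated human genome:",
      {k: round(v, 3) for k, v in w2.weights.items()})
print("combined q unchanged:", round(combine_weighted({**q, "human2": q["human"]}, w2), 5))
print()
print("The duplicated genome halves the human weight; the combined q-score"
      " is invariant, so resampling a lineage can never buy significance.")
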