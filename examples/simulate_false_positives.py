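"""How robust is the exact test when sampling is biased?

The test assumes every set is a uniform draw from the background.  Here
100 "preferential" elements are w times more likely to be sampled; each
cell reports the fraction of 1000 replicates in which the 3-way overlap
of sets sized 200/300/400 is (spuriously) significant at alpha = 0.05.
"""

from exactsets import SimulationConfig, fpr_grid

base = SimulationConfig(n=1000, set_sizes=(200, 300, 400), n_pref=100, reps=1000, seed=1)
table = fpr_grid(weights=[1.0, 1.5, 2.0], populations=[1000, 10000], base=base)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

# Under unbiased sampling (w = 1) the false-positive rate stays at or
# below the nominal 5%.  Bias inflates it only when the preferential
# block is a sizable fraction of the population (n = 1000); at
# n = 10,000 the same bias is negligible.
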