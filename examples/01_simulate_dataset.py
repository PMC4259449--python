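"""Generate a synthetic single-cell DTC study and write it to disk.

The default configuration mirrors a small bone-marrow DTC study: 10
patients (4 NED, 6 ADV), 10 cells each, 40% erythroid progenitor-like
contaminants among the sorted cells, and a latent dormant/active split
within the ADV group.
"""

from collections import Counter

from dtcsig import SimConfig, simulate, write_dataset

cfg = SimConfig(seed=17)
matrix, records, gene_sets, truth = simulate(cfg)
paths = write_dataset("example_data", matrix, records, gene_sets, truth)

print(f"genes x cells: {matrix.values.shape}")
print(f"missing fraction: {matrix.values.isna().mean().mean():.3f}")
print("planted classes:", dict(Counter(truth.cell_class.values())))
for name, p in paths.items():
    print(f"  wrote {name}: {p}")

# planted classes shows how many cells are erythroid contaminants vs
# dormant/active DTC -- the labels the downstream analyses must recover
# without ever seeing them.
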