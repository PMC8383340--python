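"""Generate a synthetic two-batch dataset and inspect its structure.

The simulator draws negative-binomial counts for cells of a few latent
"types" and adds a per-batch shift in gene log-mean space, mimicking the
batch effects seen when the same tissue is profiled with two protocols.
"""

import numpy as np

from resmnn import SyntheticConfig, generate

cfg = SyntheticConfig(n_batches=2, cells_per_batch=[500, 400], n_genes=1000,
                      n_celltypes=4, seed=7)
data = generate(cfg)

def census(labels):
    values, counts = np.unique(labels, return_counts=True)
    return {str(v): int(c) for v, c in zip(values, counts)}


print(f"cells x genes:   {data.n_cells} x {data.n_genes}")
print(f"batches:         {census(data.batch)}")
print(f"cell types:      {census(data.cell_type)}")
print(f"median library:  {np.median(data.counts.sum(axis=1)):.0f} counts/cell")

# Each batch got its own additive shift in log-mean space, so the same cell
# type has systematically different expression across batches - that shift,
# not the type structure, is what the correction network must remove.
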