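"""Generate the study-conditions synthetic dataset.

Five 10x-style libraries (three control, two tumor-engrafted), seven
stromal populations at the published per-condition composition, 2% Ighg2b+
tumor cells spiked into the tumor libraries. Writes MTX triplets plus the
cell metadata under results/sim/ and prints the realized composition.
"""

import pandas as pd

from stromaniche import io, synthetic as syn

OUT = "results/sim"
SEED = 1

cfg = syn.default_config(n_genes=1000, n_cells_per_library=2000, seed=SEED)
ds = syn.simulate_dataset(cfg)
io.write_10x_dirs(ds.adata, OUT)

print(f"wrote {ds.adata.n_obs} cells x {ds.adata.n_vars} genes to {OUT}/")
comp = pd.crosstab(ds.true_labels, ds.adata.obs["condition"], normalize="columns")
print("\nrealized composition (proportion of cells per condition):")
print(comp.round(3).to_string())
print("\ntarget control composition:",
      dict(zip(syn.STROMAL_MARKERS, syn.table_composition("control").round(3))))
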