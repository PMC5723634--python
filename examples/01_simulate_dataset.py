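"""Simulate a two-sample UMI dataset with planted structure.

Generates discrete populations (basal-like and mature-luminal-like), a
bifurcating luminal continuum and every artifact class (low-quality cells,
high-mito cells, a doublet cluster, cross-sample barcodes), then prints the
planted composition — the ground truth later stages are scored against.
"""

from sctrails import synthetic

config = synthetic.default_config(seed=0)
counts, truth = synthetic.simulate_dataset(config)

print(f"simulated {counts.n_cells} cells x {counts.n_genes} genes "
      f"in samples {counts.samples}")
print("\nplanted cell states:")
print(truth.cells["population"].value_counts().to_string())
print("\nplanted artifacts: "
      f"{int(truth.cells['is_low_quality'].sum())} low-quality, "
      f"{int(truth.cells['is_high_mito'].sum())} high-mito, "
      f"{int(truth.cells['shared_barcode'].sum())} shared-barcode cells")
print("\nplanted gene programmes:")
print(truth.genes["trajectory_class"].value_counts().to_string())
# 'continuum' cells carry a pseudotime in [0,1] and a branch label; the
# doublet cells' expected profile is the average of the two parent clusters.
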