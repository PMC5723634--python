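"""Adaptive QC, size-factor normalisation and HVG selection.

Thresholds for genes detected and total UMIs sit three MADs below each
sample's median (with hard floors); cells at >= 5% mitochondrial UMIs or
with a barcode seen in more than one sample are also removed. Size factors
come from pooling-deconvolution, and highly variable genes are those whose
log-expression variance exceeds a fitted mean-variance trend by >= 0.5.
"""

from sctrails import preprocess, synthetic

counts, truth = synthetic.simulate_dataset(synthetic.default_config(seed=0))
passed, report = preprocess.apply_qc(counts)

print("per-sample adaptive thresholds:")
print(report.sample_thresholds.round(1).to_string())
print(f"\n{passed.n_cells}/{counts.n_cells} cells pass QC; removal reasons:")
failed = report.cells.loc[~report.cells["pass"], "reasons"]
print(failed.value_counts().to_string())

size_factors = preprocess.compute_size_factors(passed)
nm = preprocess.log_normalize(passed, size_factors)
stats = preprocess.fit_mean_variance_trend(nm)
hvgs = preprocess.select_hvgs(stats, n_cells=nm.n_cells)
print(f"\nsize factors: mean {size_factors.mean():.3f}, "
      f"range [{size_factors.min():.2f}, {size_factors.max():.2f}]")
print(f"{int(hvgs['is_hvg'].sum())} highly variable genes "
      f"(biological variance >= 0.5, BH-adjusted p <= 0.05)")
# The HVG set is the feature space used by clustering and the diffusion map.
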