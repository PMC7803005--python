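"""Effect of errors in the cell-type proportion matrix.

In practice C is itself estimated, so deconvolution must tolerate noise in
it. This sweep adds Uniform(0, max) noise to every proportion entry,
renormalizes each sample to the simplex, refits, and scores against the
unperturbed ground truth.
"""

from rodeo import SimConfig, noise_sweep

sw = noise_sweep(
    SimConfig(n_genes=2000, n_batch_genes=40, seed=3),
    "rodeo",
    max_noise_values=[0.05, 0.1, 0.2, 0.3, 0.5],
    n_replicates=5,
    base_seed=1,
)

print("median matched-csGEP correlation by max noise level:")
print(sw.per_celltype_median.round(3).to_string())
print("\nmedian per-gene correlation:")
print(sw.gene_corr_median.round(3).to_string())
print("\nThe dominant cell type (A, 50% of each sample) tolerates even "
      "heavy proportion noise; rare cell types lose accuracy quickly "
      "because their signal-to-noise ratio in the bulk mixture is low.")
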