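"""Estimate mRNA half-lives from a simulated actinomycin-D chase.

Simulates 300 genes in noiseless expectation mode, runs the FPKM ->
reference-normalization -> log-linear-regression pipeline, and compares the
estimated half-lives with the generative truth.
"""

import numpy as np

import decayatlas as da

truth = da.generate_gene_params(n_genes=300, seed=42)
dataset = da.simulate_dataset(truth, da.SimulationConfig(seed=42, mode="expectation"))

fpkm = da.compute_fpkm(dataset.exonic, dataset.gene_lengths)
halflives = da.estimate_half_lives(fpkm, dataset.manifest, "Rplp0", condition="control")

ok = halflives["status"] == "ok"
rel_err = (
    np.abs(halflives.loc[ok, "half_life_h"] - dataset.truth.loc[ok[ok].index, "half_life_h"])
    / dataset.truth.loc[ok[ok].index, "half_life_h"]
)
print(f"genes estimated ok:      {int(ok.sum())} / {len(halflives)}")
print(f"status counts:           {halflives['status'].value_counts().to_dict()}")
print(f"max relative error:      {rel_err.max():.2e}")
print(halflives.loc[ok].head()[["intercept", "slope", "half_life_h"]])

# Without sampling noise the log-linear fit inverts the generative model
# exactly, so the relative error is at machine precision; the stable
# reference gene itself shows no decay and is flagged over the 50 h cap.
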