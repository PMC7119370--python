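# decay-atlas

Quantitative analysis of mRNA metabolism from transcription-shutoff chase
RNA-seq, aimed at studies of deadenylation-driven decay (e.g. CCR4–NOT /
CNOT1 loss in mouse liver).  The package implements, as a tested reusable
library:

- **Half-life estimation** from an actinomycin-D chase.  After transcription
  shutoff each mRNA decays first-order, *m(t) = m₀ e^(−k t)*.  Because
  sequencing is compositional, per-sample FPKMs are normalized to a stable
  reference mRNA (Rplp0-like), averaged per timepoint over replicates, scaled
  to the 0 h value, and fitted by ordinary least squares of ln(level) on
  time; the half-life is *t½ = ln(0.5 / e^intercept) / slope*.  Estimates
  outside (0, 50] h are flagged unreliable.
- **RIP-seq enrichment scoring**: enrichment = pulldown FPKM / input FPKM per
  replicate experiment, aggregated by mean or median; genes with < 0.1 FPKM
  in both libraries are excluded; enrichment > 1.5 calls a gene "bound".
- **Pre-mRNA quantification** from intron-mapped reads (intron FPKM), a proxy
  for the transcription rate, with the intron quality filter
  (< 0.01 FPKM or < 30 bp intron eliminated).
- **Integration**: 2-fold expression classification, half-life ratio
  classification (knockout/control > 2.0 stabilized, < 0.5 destabilized),
  steady-state reconstruction (*level ≈ t½ × intron FPKM*, since steady state
  = synthesis/decay), Spearman/Pearson correlations, exact and asymptotic
  Wilcoxon tests, and three-way overlaps of stabilized × bound gene sets.
- **A synthetic transcriptome-kinetics generator** producing ground-truth
  kinetics and sequencing-like counts (chase, intron, RIP libraries; Poisson
  or negative-binomial noise; replicate design 4/3/3 control and 4/4/5
  knockout at 0/4/8 h), so every stage is testable end-to-end without any
  deposited data.

Intended users: computational biologists analysing decay kinetics or
benchmarking decay-rate estimators on controlled synthetic data.

## Worked example

```python
import numpy as np
import decayatlas as da

truth = da.generate_gene_params(n_genes=300, seed=42)
dataset = da.simulate_dataset(truth, da.SimulationConfig(seed=42, mode="expectation"))
fpkm = da.compute_fpkm(dataset.exonic, dataset.gene_lengths)
halflives = da.estimate_half_lives(fpkm, dataset.manifest, "Rplp0", condition="control")

ok = halflives["status"] == "ok"
rel_err = (np.abs(halflives.loc[ok, "half_life_h"]
                  - dataset.truth.loc[ok[ok].index, "half_life_h"])
           / dataset.truth.loc[ok[ok].index, "half_life_h"])
print(int(ok.sum()), len(halflives), float(rel_err.max()))
```

prints (see `examples/01_halflife_recovery.py`):

```
genes estimated ok:      300 / 301
status counts:           {'ok': 300, 'excluded_over_cap': 1}
max relative error:      3.57e-15
```

All 300 simulated genes are recovered at machine precision because the
noiseless pipeline inverts the generative model exactly; the 301st gene is
the stable reference itself, which shows no decay and is correctly flagged
as over the 50 h cap.  `examples/` holds one narrative script per
capability (half-life recovery, RIP enrichment, steady-state
reconstruction, full pipeline); each prints the numbers it computes and
what they mean.

The end-to-end pipeline is also available from the shell:

```sh
decay-atlas run --config run.yaml --outdir runs/demo
decay-atlas {simulate,quantify,halflife,rip} --help
```

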