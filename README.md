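# methylink

Multi-omic integration of myonuclear DNA methylation and gene expression
in skeletal muscle studies — and in any two-group design that produces
per-CpG bisulfite coverage files alongside differential-expression tables.

Muscle fibers are multinucleated; sorting myonuclei lets reduced
representation bisulfite sequencing (RRBS) measure CpG methylation in the
nuclei that actually transcribe the fiber's genes. The analytical question
this package answers is: *which expression changes are plausibly driven by
methylation changes near the gene?* It implements the full desk-side
workflow around that question:

1. **Differential methylation (`methylink.dm`)** — merge per-sample Bismark
   `.cov` files, apply the coverage filter (summed coverage strictly above
   10 with at least 1 read in every sample), test each CpG with a binomial
   logistic-regression likelihood-ratio test (or a pooled Fisher exact test
   for unreplicated designs), correct with Benjamini–Hochberg, and call DM
   sites at q < 0.05 and > 10 percentage-points pooled methylation
   difference. Sites are annotated to promoter/exon/intron/intergenic
   context and genes classified as hypo-only / hyper-only / mixed.
2. **Regulatory-potential integration (`methylink.integration`)** — score
   every gene by the distance-decayed influence of DM sites within 100 kb
   of its TSS,

   $$s_g = \sum_{i=1}^{k} e^{-(0.5 + 4\Delta_i)}, \qquad
     \Delta_i = \frac{|x_i - \mathrm{TSS}_g|}{100\,\mathrm{kb}},$$

   rank genes by potential and by differential-expression significance,
   and call **activated** (up-regulated) and **repressed** (down-regulated)
   targets where the product of normalised ranks falls below a cutoff
   (default 0.05). One-tailed Kolmogorov–Smirnov tests compare the
   potential ranks of up- and down-regulated genes against background, and
   per-gene empirical p-values come from uniformly re-placing the observed
   sites across all TSS neighbourhoods (default 100,000 permutations).
3. **Cell-type deconvolution (`methylink.deconvolution`)** — model bulk
   expression as a non-negative weighted sum of cell-type signature
   profiles, $\min_{w \ge 0} \lVert b - Sw \rVert_2$, and report simplex
   proportions per sample.
4. **QC outlier screen (`methylink.qc`)** — PCA of the promoter
   percent-methylation matrix with group centroid overlays, per-sample
   centroid distances, a permutation test for homogeneity of multivariate
   dispersion, and deterministic flagging of samples that sit extremely far
   from their group centroid or closer to another group's centroid.
   Flags are reported, never auto-applied.
5. **Synthetic data (`methylink.simulate`)** — generators for every input
   (genome, group-structured binomial methylation counts with planted DM
   sites, DE tables with planted methylation–expression coupling, Dirichlet
   cell mixtures, factorial QC cohorts, injected outliers) with the planted
   truth returned alongside, so every stage is verifiable without any
   download.

The analysis stages are scikit-learn-style estimators
(`DifferentialMethylation`, `RegulatoryPotentialIntegrator`,
`NNLSDeconvolver`, `PromoterOutlierQC`) with `fit`/`transform`,
`get_params`/`set_params` and trailing-underscore fitted attributes;
module-level functions wrap them for one-off use, and a `methylink` CLI
(`simulate | qc | dm-call | annotate | integrate | deconvolve | run`)
wraps the library for shell pipelines.

## Worked example

```python
from methylink import (
    DifferentialMethylation, RegulatoryPotentialIntegrator,
    SimulationConfig, simulate_genome, simulate_methylation, simulate_de,
)

cfg = SimulationConfig(seed=1)          # 2,000 genes, ~20,000 CpGs, 3 vs 3
catalog = simulate_genome(cfg)
samples, design, sites, truth = simulate_methylation(catalog, cfg)

dm = DifferentialMethylation().fit(samples, design)
print(len(dm.results_), "CpGs tested,", len(dm.dm_sites_), "DM sites")

de = simulate_de(catalog, truth, cfg)
integ = RegulatoryPotentialIntegrator().fit(dm.dm_sites_, de, catalog)
calls = integ.targets_["target_class"].value_counts()
print(calls.to_dict())
print("KS p (activation):", integ.function_test_.p_activate)
```

Output:

```
20042 CpGs tested, 1064 DM sites
{'non_target': 1827, 'repressed': 90, 'activated': 83}
KS p (activation): 2.5620147395734828e-46
```

Of the ~20,000 simulated CpGs, 1,064 pass the q < 0.05 and >10-point
filters (the generator planted 1,203, so site-level sensitivity here is
~84% with the false-discovery rate held near 5%). Integration then calls
83 activated and 90 repressed targets against the 100 + 100 planted
coupled genes — most planted couplings are recovered; the misses are
genes whose promoters carry few CpGs (see `docs/methods.md`) — and the
KS test confirms that up-regulated genes have systematically better
regulatory-potential ranks than background.

The same run from the shell:

```bash
methylink simulate --seed 1 --out sim/
methylink dm-call --cov sim/*.cov --design sim/design.tsv --out dm.tsv --bed dm.bed
methylink integrate --dm dm.tsv --genes sim/genes.bed12 --de sim/de.tsv \
    --n-perm 10000 --seed 1 --out targets.tsv
```

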