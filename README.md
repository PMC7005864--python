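# scbudget

Empirical-Bayes estimation and sequencing-budget design for UMI-based
single-cell RNA-seq.

## The problem

Every droplet scRNA-seq experiment faces the same allocation question: with a
fixed total number of reads `B`, should you sequence a few cells deeply or
many cells shallowly? `scbudget` treats the observed UMI counts as noisy
Poisson measurements of a latent per-cell expression level,

```
X_c  ~  P_X               (biological ground truth, relative expression)
Y_cg | X_cg  ~  Poisson(gamma_c * n_reads * X_cg)
```

with per-cell size factors `gamma_c` (mean 1) and mean depth `n_reads`
(UMIs/cell). Under this model the common *plug-in* practice — treating
`Y/s` as if it were `X` — systematically inflates variance-type quantities:
`E[var_plugin] = Var[X] + E[X]/s`. The package provides
*empirical-Bayes (EB)* estimators that remove the Poisson contribution
exactly:

* moments: falling factorials, `E[Y(Y-1)...(Y-k+1)/s^k | X] = X^k`;
* variance / CV / Fano / gamma overdispersion parameters via corrected moments;
* Pearson correlation with noise-free denominators (no attenuation);
* inactive probability `p0(kappa) = E[exp(-kappa X)]` via the exactly unbiased
  coefficients `a_y = (1 - kappa/s)^y`, including the pairwise version;
* the full marginal distribution `P_X` by nonparametric maximum-likelihood
  deconvolution (EM on a fixed grid).

On top of the estimators sits the design machinery: fixed-budget depth/cells
tradeoff sweeps against exact synthetic truth, optimal-depth extraction,
post hoc minimum-depth tables ("how deep must a gene be sequenced for a
reliable estimate with this many cells?"), and the `1/p*` rule: given the
relative expression `p*` of the weakest gene of interest, sequence at
`n_reads* = 1/p*` UMIs per cell with `n_cells* = B * p*` cells, so the
bottleneck gene averages one read per cell.

## Worked example

```python
import numpy as np
from scbudget import (GammaPrior, GeneratorSpec, sample_counts,
                      moments, gene_statistics, fit_gamma_mom,
                      optimal_design)

# simulate an overdispersed gene: X ~ Gamma(2, 0.5) (mean 1, CV 0.707),
# sequenced at 1 read per cell per gene in 100k cells
spec = GeneratorSpec.single(GammaPrior(2.0, 0.5), depth=1.0, seed=4)
counts, truth = sample_counts(spec, n_cells=100_000)
stats = gene_statistics(moments(counts, truth.size_factors(), k_max=2))
print(f"plug-in CV: {stats.cv_plugin[0]:.3f}   EB CV: {stats.cv_eb[0]:.3f}")
print(f"gamma shape (EB): {fit_gamma_mom(stats).shape[0]:.2f}")

# design: B-cell marker at relative expression 1/7000, one lane of 3e8 reads
design = optimal_design(p_star=1/7000, budget=3e8)
print(f"depth {design.n_reads_star:.0f} UMIs/cell, "
      f"{design.n_cells_star:.0f} cells")
```

Output:

```
plug-in CV: 1.224   EB CV: 0.709
gamma shape (EB): 1.99
depth 7000 UMIs/cell, 42857 cells
```

At a depth of one read per cell the plug-in CV nearly doubles the truth
(0.707) because Poisson noise masquerades as biological variability; the EB
estimate is on target, and the method-of-moments gamma fit recovers the true
shape 2.

The same functionality is available from a thin CLI
(`scbudget simulate|estimate|correlate|deconv|design|tradeoff|posthoc`);
each run writes a `manifest.json` echoing its resolved configuration.

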