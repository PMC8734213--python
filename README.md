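# scdali

Kernel-based tests and estimation for allelic imbalance in single cells.

Allele-specific read counts — reads assigned to the maternal or paternal
haplotype through phased heterozygous variants — expose *cis*-regulatory
genetic effects within a single sample: a variant that alters a regulatory
element shifts the balance between the two haplotypes at that locus.  In
single-cell data this imbalance can be *homogeneous* (shared by every cell)
or *heterogeneous* (specific to cell types, lineages or developmental
stages), and the heterogeneous kind is invisible to bulk or pseudo-bulk
analysis when opposing effects cancel.  This package implements the scDALI
family of tests for exactly this problem, for scATAC-seq, scRNA-seq and
related assays.

## Model and tests

For cells i = 1..n at one region, with maternal counts a_i out of d_i
haplotype-assignable reads:

    u ~ N(1·α + Xβ, σ²K),   μ_i = sigmoid(u_i),
    a_i | μ_i, d_i ~ BetaBinom(μ_i/θ, (1−μ_i)/θ)

K = EEᵀ is a cell-state kernel built from any low-dimensional representation
E of the total-count matrix (embedding, one-hot clusters, polynomial
pseudotime basis, or mixtures), α is pervasive imbalance, σ² scales
cell-state-specific imbalance and θ is extra-binomial overdispersion.
Three score tests avoid fitting the alternative model:

| test  | null hypothesis        | detects                          |
|-------|------------------------|----------------------------------|
| hom   | α = 0                  | pervasive imbalance (two-sided)  |
| het   | σ² = 0                 | cell-state-specific imbalance    |
| joint | α = 0 and σ² = 0       | either kind                      |

Variance-component statistics are referred to weighted-χ²₁ mixtures with
exactly computed (count-support-enumerated) information weights; small
samples get an exact-moment-corrected null.  Per-cell allelic rates for
significant regions are estimated by sparse variational Gaussian-process
regression on empirical rates, giving a rate field over the cell-state
manifold and the Qdiff10 effect size (90% minus 10% quantile of the field).
Haplotype-aware read counting from SAM/VCF/BED, benchmark simulators, a
lineage/pseudotime scan workflow and a compact VAE for cell-state and
pseudotime inference from binary accessibility are included.

## Worked example

```python
import numpy as np
from scdali import (NullModelSpec, fixtures, linear_factor,
                    standardize_factor, test_het, test_hom, test_joint)
from scdali.simulate import SimulationConfig, draw_counts
from scdali.rate_field import estimate_rates, qdiff10

# a synthetic study: 2000 cells on a clustered 8-D manifold, sparse totals
E, clusters, t = fixtures.make_cell_states(2000, seed=0)
d = fixtures.make_depths(2000, 1, target_mean_allelic=1.0, seed=1).ravel()

# plant purely cell-state-specific imbalance (no pervasive component)
cfg = SimulationConfig(rho=1.0, nu2=0.1, theta=2.0, n_cells=2000,
                       n_regions=1, seed=2, rho_is_het_fraction=True)
a = draw_counts(d, linear_factor(E), cfg)

factor = standardize_factor(linear_factor(E))
for res in (test_hom(a, d), test_het(a, d, factor), test_joint(a, d, factor)):
    print(f"{res.test:>6}: statistic = {res.statistic:9.2f}  p = {res.p_value:.3g}")

post = estimate_rates(a, d, factor, n_inducing=1000, seed=0)
es = qdiff10(post)
print(f"qdiff10 = {es.qdiff10:.3f}  mean rate = {es.mean_rate:.3f}")
```

Output:

```
   hom: statistic =      0.85  p = 0.356
   het: statistic =  10024.79  p = 2.96e-07
 joint: statistic =  10303.51  p = 2.92e-05
qdiff10 = 0.271  mean rate = 0.477
```

The pervasive test sees nothing (the imbalance averages out across cells),
the heterogeneity test flags the region strongly, the joint test detects it
as well, and the estimated rate field spreads by ~0.25 between the most
extreme cell populations — the signature of a cell-state-specific
regulatory effect that a bulk analysis would miss.

There is also a CLI (`scdali count | filter | test | estimate |
lineage-scan | time-scan | simulate | benchmark`) for file-based workflows;
every command writes a JSON run manifest alongside its outputs.

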