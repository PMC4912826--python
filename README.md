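# pigwas

GWAS toolkit for weighted, pre-corrected phenotypes in pedigreed livestock
populations, built around two complementary association models and a
post-MCMC **sliding-window QTL-region caller**:

1. **Weighted single-SNP linear mixed model (LM).** Per marker,
   `y_c = 1μ + x g + Z u + e` with polygenic effect `u ~ N(0, A σ²_u)`
   (`A` the pedigree-based additive relationship matrix) and
   heteroscedastic residual `e ~ N(0, D σ²_e)`, `D = diag(1/w_i)` where
   `w_i` is the reliability weight of the corrected phenotype `y_c,i`.
   Variance components are estimated once by REML on the null model and
   held fixed; each marker is tested by GLS with a two-sided t-test,
   with Bonferroni thresholds `-log10(α/N)` and the genomic-control
   inflation factor λ as diagnostics.
2. **Bayesian two-component mixture model (BM).** All SNP effects fitted
   simultaneously, `y_c = 1μ + Σ_j x_j g_j + Z u + e`, with
   `g_j ~ N(0, σ²_g0)` with probability π₀ and `g_j ~ N(0, 100 σ²_g0)`
   with probability 1 − π₀, and π₀ ~ Beta(100, 1). A single-site Gibbs
   sampler (numba-compiled) draws every parameter from its closed-form
   conditional; default chain bookkeeping is 52,000 cycles, 20,000
   burn-in, every 20th sample saved (1,600 samples).
3. **QTL-region detection.** Sliding windows of equal bp length (1.0,
   2.5, 5.0 Mb by default), one anchored at each marker. A window's
   **PP_int** is the fraction of saved MCMC cycles in which at least one
   SNP in the window falls in the large-effect component. Windows above
   a threshold (0.8) are chained into candidate peaks; the window with
   the highest PP_int per peak is the QTL region, reported with the
   posterior mean/SD of `var(X_region g_region)` and its share of the
   total additive genetic variance.

Because chip data of this kind is proprietary, the package ships a
first-class synthetic-data generator (`pigwas.simulate`): a
multi-generation random-mating pedigree, LD-structured 0/1/2 genotypes
with missingness and GenCall-style quality scores, planted large-effect
QTL among polygenic background, and weighted corrected phenotypes. Every
stage is tested end to end against this generator, including
planted-region recovery.

## Worked example

```python
import numpy as np
from pigwas import (
    SimConfig, simulate_dataset, MixedModelGWAS, BayesMixtureGWAS,
    QTLRegionScan, bonferroni_threshold,
)

cfg = SimConfig(
    n_founders=100, n_generations=3, offspring_per_mating=2,
    n_chromosomes=4, n_markers_per_chromosome=100,
    chromosome_length_bp=10_000_000,
    n_qtl=2, qtl_variance_fraction=0.5, qtl_chromosomes=(1, 2),
    sigma2_u=1.0, sigma2_e=1.0, missing_rate=0.0, seed=3,
)
ped, A, marker_map, geno, phen, truth = simulate_dataset(cfg)
y, w = phen["y_c"].to_numpy(), phen["weight"].to_numpy()

lm = MixedModelGWAS().fit(geno.values, y, A=A, weights=w, marker_map=marker_map)
bm = BayesMixtureGWAS(n_cycles=5200, burn_in=2000, thin=2, seed=7)
bm.fit(geno.values, y, pedigree=ped, weights=w)
rs = QTLRegionScan(window_lengths=(1_000_000,), threshold=0.8)
rs.fit(bm.samples_, marker_map, genotypes=geno.values)
print(rs.regions_[["chromosome", "start_bp", "end_bp", "pp_int",
                   "variance_proportion"]].to_string(index=False))
```

Output:

```
simulated 400 pigs x 400 markers; planted QTL at markers [60, 136]
LM scan: sigma2_u=2.07, sigma2_e=0.87, lambda=1.11, 2 markers above the 5% Bonferroni threshold (3.90)
BM chain: 1600 saved samples, posterior mean pi0=0.989
inclusion frequency at the planted QTL: [1.0, 1.0]
 chromosome  start_bp    end_bp  pp_int  variance_proportion
        1.0 5343160.0 6343160.0     1.0             0.232593
        2.0 2919386.0 3919386.0     1.0             0.279056
true QTL positions: [(1, 6269635), (2, 3918614)]
```

Both planted QTL sit inside the two reported 1 Mb regions; each region
explains roughly a quarter of the additive genetic variance, matching
the simulation design (two QTL per trait jointly explaining half of it,
the polygenic term the other half). The QTL-free chromosomes 3 and 4
produce no window above the 0.8 threshold.

There is also a CLI mirroring the library stages:

```bash
pigwas simulate --out-dir data --seed 1
pigwas qc --genotypes data/genotypes.tsv --map data/markers.map \
          --gencall data/gencall.tsv --out qc_report.tsv
pigwas run --config pipeline.yaml    # qc -> impute -> LM -> BM -> regions
```

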