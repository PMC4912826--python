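# Methods

## Data model and notation

The unit of analysis is a pedigreed population genotyped on a
medium-density SNP chip, with a *corrected phenotype* `y_c` per animal —
an observation pre-adjusted for non-genetic effects (herd-year-season,
parity and the like) — carrying a positive reliability weight `w`. The
weight enters every model through the residual: `var(e_i) = σ²_e / w_i`,
i.e. the residual covariance is `D σ²_e` with `D = diag(1/w_i)`. More
reliable records (larger `w`) get smaller residual variance.

Genotypes are coded 0/1/2 as the count of the second allele. The
pedigree induces the additive (numerator) relationship matrix `A`, so
the polygenic effect is `u ~ N(0, A σ²_u)`.

## Quality control

Markers are kept iff MAF > 0.01, call frequency > 0.9, mean GenCall
score > 0.60, Hardy-Weinberg P > 1e-7 and the map position is known; the
inequalities are strict. Animals with call rate < 0.8 are excluded
first, and marker statistics are recomputed on the kept animals (the
usual chip-QC order; the alternative order differs only marginally at
these thresholds). The HWE test is the 1-df chi-square goodness-of-fit
against expected counts `n p², 2n p q, n q²` with `p` estimated from the
sample; a monomorphic marker is assigned chi2 = 0, P = 1. An exact test
would differ at very small counts, but at chip-scale sample sizes and a
1e-7 cut-off the chi-square form is standard and analytically checkable.

Remaining sporadic missing genotypes are filled with the marker's
rounded mean genotype. This is deliberately naive — it preserves allele
frequency to O(k/n) per marker and never touches observed calls — and is
not a substitute for LD-aware imputation; at the low missingness the QC
step leaves through (<10%), downstream results are insensitive to it.

## Single-SNP weighted mixed model

Per marker: `y_c = 1μ + x g + u + e`. Variance components `(σ²_u, σ²_e)`
are estimated once by REML on the null model (no SNP) and held fixed
across markers — the standard two-stage shortcut, exact enough because a
single SNP barely perturbs the variance components, and ~m-fold faster
than per-marker REML.

REML itself is solved exactly rather than iteratively: standardising by
`sqrt(w)` turns the residual covariance into `σ²_e I`; one
eigendecomposition of `W^{1/2} A W^{1/2}` makes the profile restricted
likelihood a cheap 1-D function of the ratio `λ = σ²_u/σ²_e`, maximised
by a grid + bounded refinement over `log λ ∈ [-12, 12]`. This has no
convergence failure modes, is deterministic, and clamps cleanly to the
`σ²_u = 0` boundary. When the profile is flat — e.g. `A = I` makes `u`
and `e` exchangeable — the tie is broken toward `σ²_u = 0` (parsimony).

The per-marker test is GLS under `V = σ²_u A + σ²_e D` with a two-sided
t-test on `n − 2` degrees of freedom (mean + SNP). The standard error is
rescaled by the marker-specific weighted residual variance
(`weighted RSS / (n − 2)`), so in the `σ²_u = 0`, unit-weight special
case the scan reduces *exactly* to textbook simple regression — this is
the package's strongest correctness anchor, tested to 1e-8 — and the
statistic is invariant to rescaling `V` (e.g. doubling all weights while
halving `σ²_e`). `V` is factorised once (Cholesky) and reused across all
markers in blocks. Monomorphic markers are reported with undefined
effect and P = 1, flagged.

Significance uses Bonferroni thresholds `-log10(α/N)`; for the chip
panels of 37,060 and 36,058 markers these are 5.87/6.57 and 5.86/6.56 at
α = 0.05/0.01. The genomic-control inflation factor is
`λ = median(χ²₁ quantiles of 1 − p) / 0.4549` — near 1 for a calibrated
scan, above 1 under uncorrected stratification.

## Bayesian mixture model

All markers simultaneously: `y_c = 1μ + Σ_j x_j g_j + u + e` with

- `g_j ~ N(0, σ²_g0)` with probability π₀, `N(0, σ²_g1)` with
  probability π₁ = 1 − π₀, and `σ²_g1 = 100 σ²_g0` fixed;
- `π₀ ~ Beta(100, 1)` (prior mean ≈ 0.99: most markers have small
  effects);
- flat priors on `μ` and `σ²_g0`; flat priors on `σ²_u`, `σ²_e` giving
  scaled-inverse-chi-square conditionals;
- the same weighted residual structure `D = diag(1/w)` as the LM (both
  models analyse the same weighted records).

One Gibbs cycle updates: `μ` (normal conditional); each `(δ_j, g_j)`
pair jointly — the indicator is drawn with the effect **integrated out**
(the two-component marginal-likelihood odds times the π odds), then the
effect from its normal conditional given the chosen component. The
marginalised indicator update mixes far better than conditioning on the
current `g_j` and leaves the stationary distribution unchanged. The
polygenic values are updated single-site through the sparse `A⁻¹` built
directly from the pedigree by Henderson's rules (with inbreeding,
Mendelian-sampling variances from the tabular-method diagonal), so no
dense n×n solve occurs inside the chain. Variance draws:
`σ²_g0 ~ S/χ²(m−2)` with `S = Σ_{δ=0} g² + Σ_{δ=1} g²/100`, and
analogous draws for `σ²_u` (with `S = u'A⁻¹u`) and `σ²_e` (weighted
residual sum of squares). The flat prior on `σ²_g0` is made proper by a
large finite support bound (1e6 × var(y) by default; redraw, then clamp)
— it matters only for degenerate tiny-m inputs.

Genotype columns are centred inside the sampler. Centring changes
nothing identifiable (effects, indicators, window variances are
invariant) but decouples `μ` from the marker block and makes a
zero-variance column exactly likelihood-flat, so its inclusion frequency
equals the posterior mean of π₁ ≈ 1/101 — a useful sanity check.

The running residual is maintained by add-back/subtract updates and
compared against a from-scratch recomputation every 500 cycles; the
maximum drift is exposed (`residual_drift_`, tested < 1e-6). Chains are
bit-reproducible given a seed. Default bookkeeping follows the
chip-scale convention (52,000 cycles / 20,000 burn-in / thin 20 → 1,600
saved samples); all package tests use proportionally scaled-down chains,
which the planted-QTL studies show are long enough at desk-scale n and m.

A modelling caveat worth knowing: `σ²_g0` is identified by the mass of
(near-)null markers. With a single marker the small component simply
inflates to absorb any effect and the indicator stays at its prior, so
"detection" is only meaningful when many markers are fitted jointly.

## QTL-region detection

Windows of equal bp length are anchored **at every marker position**
(`[p, p + L)`, half-open, 1-based): the finest sliding resolution, and
consistent with reported region boundaries coinciding with marker
coordinates. Per window, `PP_int` = fraction of saved cycles in which at
least one member SNP is in the large-effect component — the posterior
probability that the window carries a large-effect locus. It is a union
event, hence monotone: enlarging a window can never decrease `PP_int`
(and its plateau over window length is the practical stopping rule for
window size).

Windows with `PP_int` above the threshold (0.8 by default; a direct
posterior probability, chosen by the investigator) are chained into
candidate peaks wherever they overlap or touch in bp; the
highest-`PP_int` window per peak (ties to the smaller start) is the QTL
region. Per saved cycle `t` the region's explained variance is the
population variance across individuals of `X_region g_region^(t)`; its
posterior mean and SD are reported, plus the mean per-cycle proportion
relative to the total additive genetic variance. The total is
`var(X g^(t) + u^(t))` by default — "additive genetic" includes the
polygenic term — with a `markers_only` alternative, since the choice of
denominator is a reporting convention rather than part of the model.
Cycles with zero total variance are skipped and counted. An empty region
report is a valid outcome (the "no significant region detected" path),
not an error.

Each window length (1.0 / 2.5 / 5.0 Mb by default) is analysed
independently; picking the narrowest informative region across lengths
is left to the analyst, as it is a reporting choice.

## Synthetic data generator

The generator emulates the *structure* of proprietary chip data, not any
particular population:

- **Pedigree**: founders plus `n_generations` of random mating (the
  previous generation randomly paired, `offspring_per_mating` each),
  giving realistic family covariance through `A`.
- **Founder haplotypes**: per chromosome, a first-order Markov chain in
  which marker `k` keeps its configured allele frequency *exactly* while
  its dependence on marker `k−1` is the Fréchet upper bound scaled by
  `1 − ld_decay`. `ld_decay = 0` copies alleles (maximal LD; identical
  adjacent markers when frequencies are equal), `1` gives independence,
  and for equal frequencies the adjacent-marker correlation is exactly
  `1 − ld_decay`. Allele frequencies are drawn from a uniform MAF band
  (default 0.05–0.5) with random allele orientation.
- **Meiosis**: each gamete picks a random starting haplotype per
  chromosome and switches at one uniformly placed crossover — the
  simplest mechanism that keeps multi-marker windows in LD with a
  planted locus across generations.
- **Phenotypes**: `y_c = μ + X_qtl b + u + e`. QTL markers are chosen
  round-robin over the allowed chromosomes with a minimum bp separation
  and MAF ≥ 0.1; effects alternate in sign and are rescaled post hoc so
  the planted QTL jointly explain exactly `qtl_variance_fraction` of the
  realised additive variance `var(X_qtl b) + σ²_u` (which is why that
  fraction requires `σ²_u > 0`). `u` is drawn from `N(0, A σ²_u)` via
  Cholesky; `e_i ~ N(0, σ²_e/w_i)` with weights uniform on
  `weight_range`. GenCall means are Beta(45, 5) draws (~0.9); only their
  mean is consumed by QC. Everything is reproducible from a single seed.

Defaults describe a scaled-down chip panel: 18 autosomes × 120 markers
on 10 Mb (≈12 markers/Mb, chip-like density), 5 QTL explaining 30% of
additive variance, `σ²_u = σ²_e = 1`, weights in (0.5, 2), 2%
missingness, `ld_decay = 0.5`.

What the generator does **not** emulate — and hence what passing tests
do not certify about real data: coalescent-realistic LD decay and allele
frequency spectra, assembly/map errors (a known cause of LM/BM
disagreement on real chromosomes), selection and non-random mating,
multi-breed structure, and the derivation of `y_c` and `w` from raw
repeated records (both are generated directly).

## Validation studies and problem sizes

The studies in `pigwas.validation` (run by the test suite and
`scripts/acceptance.py`) use sizes chosen to give stable Monte-Carlo
estimates in minutes on one CPU:

- **Null calibration**: n = 600 (150 founders, 3 generations), 10,000
  markers, no QTL, weak LD (`ld_decay = 0.8`); empirical type-I error at
  nominal 0.05 should be 0.05 ± 0.01 and λ on uniform p-values
  1.00 ± 0.02.
- **GLS/OLS anchor**: 200 × 500 panel, agreement to 1e-8 (observed
  ~1e-14).
- **Region recovery**: 20 replicates of n = 1,000, m = 2,000 on 4 × 50
  Mb chromosomes; 4 QTL on chromosomes 1–2 (two per chromosome, ≥2 Mb
  apart) jointly explaining 50% of additive variance (≈12.5% each ≈ 8%
  of phenotypic variance); chains 5,200/2,000/thin 2; 1 Mb windows at
  threshold 0.8. Expected: ≥80% of planted regions recovered, ≤5% of
  QTL-free chromosomes with any above-threshold window (observed: ~99%
  and 0% at the shipped seeds).
- **No-region pathway**: a purely polygenic trait (3 chromosomes, 450
  markers) must yield an empty region report.

## Numerical and degenerate-input choices

- Relationship matrices get a 1e-10 diagonal jitter before Cholesky;
  a failed factorisation raises with a pointer to pedigree ordering.
- Window coordinates: 1-based positions, half-open `[start, end)`;
  variance over individuals uses denominator n.
- Ties in region selection go to the smaller start coordinate.
- Monomorphic markers: P = 1 with a flag (LM); prior-level inclusion
  (BM); `(χ² = 0, P = 1)` convention in the HWE test.
- Constant phenotypes raise a variance-estimation error.
- Seeds are masked to 31 bits before reaching the numba RNG.

## Known limitations

- The Gibbs sampler requires phenotypes for the individuals it models;
  when QC drops genotyped animals the pipeline falls back to a dense
  inverse of the subset relationship matrix (fine at desk scale,
  quadratic in n).
- Single chain only; diagnostics are limited to scalar trace summaries
  and the residual-drift check.
- No dominance/epistasis, no multi-breed or multi-trait modelling, no
  LD-based imputation, no gene annotation of detected regions.
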