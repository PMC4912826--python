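"""Bayesian two-component mixture GWAS fitted by Gibbs sampling.

All SNP effects are fitted simultaneously:
``y_c = 1*mu + sum_j x_j g_j + Z u + e`` with the spike-and-slab-style
prior ``g_j ~ N(0, sigma2_g0)`` with probability ``pi0`` and
``g_j ~ N(0, sigma2_g1)``, ``sigma2_g1 = 100 * sigma2_g0``, with
probability ``pi1 = 1 - pi0``; ``pi0 ~ Beta(100, 1)`` (prior mean ~0.99
of markers in the small-effect component). ``mu`` and ``sigma2_g0``
carry flat priors, as do the polygenic and residual variances; record
weights enter the residual precision as ``w_i / sigma2_e``.

The default chain settings (52,000 cycles, 20,000 burn-in, thin 20,
hence 1,600 saved samples) are far longer than needed at desk scale;
scaled-down chains are used throughout the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from . import _gibbs
from .pedigree import Pedigree, a_inverse


class GibbsDivergenceError(RuntimeError):
    """A variance draw became non-finite during sampling."""


@dataclass
class GibbsConfig:
    """Chain bookkeeping: total cycles, burn-in, thinning interval, seed."""

    n_cycles: int = 52_000
    burn_in: int = 20_000
    thin: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_cycles:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_cycles")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_saved(self) -> int:
        """floor((n_cycles - burn_in) / thin) samples retained."""
        return (self.n_cycles - self.burn_in) // self.thin


@dataclass
class MixturePrior:
    """Two-normal mixture prior on SNP effects."""

    variance_ratio: float = 100.0
    pi_prior_a: float = 100.0
    pi_prior_b: float = 1.0

    def __post_init__(self) -> None:
        if self.variance_ratio <= 1.0:
            raise ValueError("variance_ratio must exceed 1")
        if self.pi_prior_a <= 0 or self.pi_prior_b <= 0:
            raise ValueError("Beta prior parameters must be positive")


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in Gibbs draws."""

    g: np.ndarray        # (T, m) SNP effects
    delta: np.ndarray    # (T, m) uint8 mixture indicators (1 = large effect)
    u: np.ndarray        # (T, n) polygenic values
    mu: np.ndarray       # (T,)
    sigma2_g0: np.ndarray
    pi0: np.ndarray
    sigma2_u: np.ndarray
    sigma2_e: np.ndarray

    @property
    def n_saved(self) -> int:
        return self.g.shape[0]

    @property
    def n_markers(self) -> int:
        return self.g.shape[1]


def run_gibbs(
    y,
    genotypes,
    pedigree: Pedigree | None = None,
    A: np.ndarray | None = None,
    weights=None,
    prior: MixturePrior | None = None,
    config: GibbsConfig | None = None,
    s2g0_max: float | None = None,
    prior_only: bool = False,
    check_every: int = 500,
) -> tuple[PosteriorSamples, float]:
    """Run the Gibbs chain; returns (samples, max residual drift).

    Genotypes are column-centred internally (effects, indicators and
    variance summaries are invariant to this); a zero-variance column is
    therefore exactly likelihood-flat and its inclusion frequency
    matches the prior. The residual is maintained by add-back/subtract
    updates and checked against a from-scratch recomputation every
    ``check_every`` cycles; the largest deviation seen is returned.
    """
    prior = prior or MixturePrior()
    config = config or GibbsConfig()
    y = np.asarray(y, dtype=float)
    X = np.asarray(genotypes, dtype=float)
    if np.isnan(X).any():
        raise ValueError("genotypes contain missing values; impute first")
    n, m = X.shape
    if len(y) != n:
        raise ValueError("phenotype length does not match genotypes")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")

    Xc = X - X.mean(axis=0)
    Xt = np.ascontiguousarray(Xc.T)
    c = (Xt * Xt * w).sum(axis=1)

    if pedigree is not None:
        if pedigree.n != n:
            raise ValueError("pedigree size does not match phenotypes")
        Ainv = a_inverse(pedigree)
        indptr = Ainv.indptr.astype(np.int64)
        indices = Ainv.indices.astype(np.int64)
        data = Ainv.data.astype(np.float64)
        has_poly = True
    elif A is not None:
        # dense fallback, e.g. when QC dropped animals and the subset of A
        # no longer corresponds to a standalone pedigree
        if A.shape != (n, n):
            raise ValueError("relationship matrix shape does not match phenotypes")
        Ainv = sparse.csr_matrix(np.linalg.inv(A + 1e-10 * np.eye(n)))
        indptr = Ainv.indptr.astype(np.int64)
        indices = Ainv.indices.astype(np.int64)
        data = Ainv.data.astype(np.float64)
        has_poly = True
    else:
        indptr = np.zeros(n + 1, dtype=np.int64)
        indices = np.zeros(0, dtype=np.int64)
        data = np.zeros(0, dtype=np.float64)
        has_poly = False

    if s2g0_max is None:
        vary = float(np.var(y)) if float(np.var(y)) > 0 else 1.0
        s2g0_max = 1e6 * vary

    T = config.n_saved
    g_out = np.zeros((T, m))
    delta_out = np.zeros((T, m), dtype=np.uint8)
    u_out = np.zeros((T, n))
    mu_out = np.zeros(T)
    s2g0_out = np.zeros(T)
    pi0_out = np.zeros(T)
    s2u_out = np.zeros(T)
    s2e_out = np.zeros(T)

    status, bad_cycle, drift = _gibbs.gibbs_kernel(
        Xt, y, w, c,
        indptr, indices, data, has_poly,
        float(prior.variance_ratio), float(prior.pi_prior_a), float(prior.pi_prior_b),
        int(config.n_cycles), int(config.burn_in), int(config.thin),
        int(config.seed) & 0x7FFFFFFF,
        float(s2g0_max),
        bool(prior_only),
        int(check_every),
        g_out, delta_out, u_out,
        mu_out, s2g0_out, pi0_out, s2u_out, s2e_out,
    )
    if status == _gibbs.STATUS_NONFINITE:
        raise GibbsDivergenceError(
            f"non-finite variance draw at cycle {bad_cycle}; "
            "check phenotype scaling and weights"
        )
    samples = PosteriorSamples(
        g=g_out, delta=delta_out, u=u_out, mu=mu_out,
        sigma2_g0=s2g0_out, pi0=pi0_out, sigma2_u=s2u_out, sigma2_e=s2e_out,
    )
    return samples, float(drift)


def posterior_summaries(samples: PosteriorSamples) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-marker and scalar-chain posterior summaries.

    Returns (marker table with posterior mean/SD effect and inclusion
    frequency, scalar table with mean/SD of mu, variances and pi0).
    """
    if samples.n_saved < 1:
        raise ValueError("need at least one saved cycle")
    marker = pd.DataFrame(
        {
            "effect_mean": samples.g.mean(axis=0),
            "effect_sd": samples.g.std(axis=0),
            "inclusion_frequency": samples.delta.mean(axis=0),
        }
    )
    scalars = {}
    for name in ("mu", "sigma2_g0", "pi0", "sigma2_u", "sigma2_e"):
        arr = getattr(samples, name)
        scalars[name] = {"mean": float(arr.mean()), "sd": float(arr.std())}
    return marker, pd.DataFrame(scalars).T


class BayesMixtureGWAS:
    """Scikit-learn-style estimator for the mixture-model GWAS.

    Parameters mirror :class:`GibbsConfig` and :class:`MixturePrior`.
    Fitted attributes: ``samples_`` (:class:`PosteriorSamples`),
    ``inclusion_`` (per-marker posterior inclusion frequency),
    ``effect_mean_``, ``scalar_summary_``, ``residual_drift_``.
    """

    def __init__(
        self,
        n_cycles: int = 52_000,
        burn_in: int = 20_000,
        thin: int = 20,
        variance_ratio: float = 100.0,
        pi_prior_a: float = 100.0,
        pi_prior_b: float = 1.0,
        seed: int = 0,
        s2g0_max: float | None = None,
        check_every: int = 500,
    ) -> None:
        self.n_cycles = n_cycles
        self.burn_in = burn_in
        self.thin = thin
        self.variance_ratio = variance_ratio
        self.pi_prior_a = pi_prior_a
        self.pi_prior_b = pi_prior_b
        self.seed = seed
        self.s2g0_max = s2g0_max
        self.check_every = check_every

    _param_names = (
        "n_cycles", "burn_in", "thin", "variance_ratio",
        "pi_prior_a", "pi_prior_b", "seed", "s2g0_max", "check_every",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def config(self) -> GibbsConfig:
        return GibbsConfig(self.n_cycles, self.burn_in, self.thin, self.seed)

    @property
    def prior(self) -> MixturePrior:
        return MixturePrior(self.variance_ratio, self.pi_prior_a, self.pi_prior_b)

    def fit(self, X, y, pedigree: Pedigree | None = None, A=None, weights=None):
        self.samples_, self.residual_drift_ = run_gibbs(
            y, X,
            pedigree=pedigree,
            A=A,
            weights=weights,
            prior=self.prior,
            config=self.config,
            s2g0_max=self.s2g0_max,
            check_every=self.check_every,
        )
        marker, scalars = posterior_summaries(self.samples_)
        self.inclusion_ = marker["inclusion_frequency"].to_numpy()
        self.effect_mean_ = marker["effect_mean"].to_numpy()
        self.marker_summary_ = marker
        self.scalar_summary_ = scalars
        return self
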