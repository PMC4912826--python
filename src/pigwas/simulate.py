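"""Synthetic pedigree, genotype and phenotype generation.

Emulates, at desk scale, the structure of a medium-density SNP-chip
breeding-population data set: a multi-generation pedigree inducing
polygenic covariance, LD-structured 0/1/2 genotypes over several
autosomes with missingness and per-marker GenCall-style quality scores,
a handful of planted large-effect QTL, and pre-corrected phenotypes
``y_c`` carrying positive reliability weights ``w`` (residual variance
``sigma2_e / w_i``).

Founder haplotypes follow a first-order Markov chain along each
chromosome: each marker keeps its configured allele frequency exactly,
while the dependence on the previous marker is the Frechet upper bound
scaled by ``1 - ld_decay`` (``ld_decay = 0`` gives maximal correlation,
``1`` gives independence). Descendant haplotypes are recombined parental
gametes with one uniformly placed crossover per chromosome per meiosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pedigree import Pedigree, relationship_matrix


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a scaled-down chip panel: 18 autosomes of 10 Mb
    carrying 120 markers each (~12 markers/Mb, chip-like density), a
    5-generation pedigree of ~50 animals per generation, moderate LD
    between adjacent markers, 5 large-effect QTL explaining 30% of the
    additive genetic variance, equal polygenic and residual variances,
    and record weights between 0.5 and 2.
    """

    n_founders: int = 50
    n_generations: int = 4
    offspring_per_mating: int = 2
    n_chromosomes: int = 18
    chromosome_length_bp: int = 10_000_000
    n_markers_per_chromosome: int = 120
    ld_decay: float = 0.5
    maf_spectrum: tuple[str, float, float] = ("uniform", 0.05, 0.5)
    n_qtl: int = 5
    qtl_variance_fraction: float = 0.3
    sigma2_u: float = 1.0
    sigma2_e: float = 1.0
    mu: float = 0.0
    weight_range: tuple[float, float] = (0.5, 2.0)
    missing_rate: float = 0.02
    trait_name: str = "trait"
    qtl_chromosomes: tuple[int, ...] | None = None
    qtl_min_distance_bp: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_founders": self.n_founders,
            "n_generations": self.n_generations + 1,  # 0 generations allowed
            "offspring_per_mating": self.offspring_per_mating,
            "n_chromosomes": self.n_chromosomes,
            "chromosome_length_bp": self.chromosome_length_bp,
            "n_markers_per_chromosome": self.n_markers_per_chromosome,
        }
        for name, v in counts.items():
            if int(v) < 1:
                raise ConfigError(f"{name} must be >= 1 (got {v})")
        if self.n_generations < 0:
            raise ConfigError("n_generations must be >= 0")
        for name, v in (("ld_decay", self.ld_decay), ("missing_rate", self.missing_rate)):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1] (got {v})")
        for name, v in (("sigma2_u", self.sigma2_u), ("sigma2_e", self.sigma2_e)):
            if v < 0:
                raise ConfigError(f"{name} must be >= 0 (got {v})")
        lo, hi = self.weight_range
        if not (lo > 0 and hi >= lo):
            raise ConfigError("weight_range bounds must be positive and ordered")
        if not 0.0 <= self.qtl_variance_fraction < 1.0:
            raise ConfigError("qtl_variance_fraction must lie in [0, 1)")
        if self.n_qtl < 0:
            raise ConfigError("n_qtl must be >= 0")
        kind, a, b = self.maf_spectrum
        if kind != "uniform" or not (0 < a <= b <= 0.5):
            raise ConfigError(
                "maf_spectrum must be ('uniform', low, high) with 0 < low <= high <= 0.5"
            )
        if self.n_markers_per_chromosome > self.chromosome_length_bp:
            raise ConfigError("more markers than base pairs on a chromosome")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GenotypeMatrix:
    """n x m matrix of 0/1/2 allele-2 counts; ``nan`` marks a missing call."""

    values: np.ndarray
    individual_ids: np.ndarray
    mean_gencall: np.ndarray  # per marker, in (0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=np.int64)
        self.mean_gencall = np.asarray(self.mean_gencall, dtype=float)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def call_frequency(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return 1.0 - np.isnan(self.values).mean(axis=0)

    @property
    def call_rate(self) -> np.ndarray:
        """Per-individual fraction of non-missing calls."""
        return 1.0 - np.isnan(self.values).mean(axis=1)


@dataclass
class TruthRecord:
    """Ground truth of a simulated data set, for recovery experiments."""

    qtl_marker_indices: np.ndarray
    qtl_effects: np.ndarray
    true_u: np.ndarray
    true_region_spans: list[tuple[int, int, int]]  # (chromosome, start, end)

    def to_dict(self) -> dict:
        return {
            "qtl_marker_indices": [int(i) for i in self.qtl_marker_indices],
            "qtl_effects": [float(x) for x in self.qtl_effects],
            "true_u": [float(x) for x in self.true_u],
            "true_region_spans": [
                [int(c), int(s), int(e)] for c, s, e in self.true_region_spans
            ],
        }


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Random-mating multi-generation pedigree.

    Founders (generation 0) have unknown parents. In each later
    generation the previous generation is randomly split into mating
    pairs, each producing ``offspring_per_mating`` offspring.
    """
    rng = np.random.default_rng(config.seed)
    ids = list(range(1, config.n_founders + 1))
    sires = [0] * config.n_founders
    dams = [0] * config.n_founders
    gens = [0] * config.n_founders
    prev = list(ids)
    next_id = config.n_founders + 1
    for g in range(1, config.n_generations + 1):
        if len(prev) < 2:
            raise ConfigError(
                f"generation {g - 1} has {len(prev)} individual(s); need >= 2 to mate"
            )
        perm = rng.permutation(prev)
        n_pairs = len(prev) // 2
        cur: list[int] = []
        for k in range(n_pairs):
            sire, dam = int(perm[2 * k]), int(perm[2 * k + 1])
            for _ in range(config.offspring_per_mating):
                ids.append(next_id)
                sires.append(sire)
                dams.append(dam)
                gens.append(g)
                cur.append(next_id)
                next_id += 1
        prev = cur
    return Pedigree(
        individual=np.array(ids),
        sire=np.array(sires),
        dam=np.array(dams),
        generation=np.array(gens),
    )


def _founder_haplotypes(
    rng: np.random.Generator, n_hap: int, freqs: np.ndarray, ld_decay: float
) -> np.ndarray:
    """Markov-chain founder haplotypes with exact per-marker frequencies."""
    k = len(freqs)
    h = np.empty((n_hap, k), dtype=np.int8)
    h[:, 0] = rng.random(n_hap) < freqs[0]
    c = 1.0 - ld_decay
    for j in range(1, k):
        p_prev, p = freqs[j - 1], freqs[j]
        lam = min(p / p_prev, (1.0 - p) / (1.0 - p_prev))
        p_given1 = p + c * lam * (1.0 - p_prev)
        p_given0 = p - c * lam * p_prev
        cond = np.where(h[:, j - 1] == 1, p_given1, p_given0)
        h[:, j] = rng.random(n_hap) < cond
    return h


def simulate_genotypes(
    config: SimConfig, pedigree: Pedigree
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Gene-drop genotypes through the pedigree.

    Returns the marker map (``marker_id, chromosome, position_bp,
    allele_1, allele_2``; positions strictly increasing within a
    chromosome) and the 0/1/2 genotype matrix with missing calls and
    simulated per-marker mean GenCall scores.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = pedigree.n
    sidx, didx = pedigree.parent_indices()
    mk = config.n_markers_per_chromosome
    m = config.n_chromosomes * mk

    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1), mk)
    positions = np.empty(m, dtype=np.int64)
    for c in range(config.n_chromosomes):
        pos = rng.choice(config.chromosome_length_bp, size=mk, replace=False) + 1
        positions[c * mk : (c + 1) * mk] = np.sort(pos)
    marker_map = pd.DataFrame(
        {
            "marker_id": [f"SNP{i + 1:06d}" for i in range(m)],
            "chromosome": chroms,
            "position_bp": positions,
            "allele_1": "A",
            "allele_2": "B",
        }
    )

    _, lo, hi = config.maf_spectrum
    maf = rng.uniform(lo, hi, size=m)
    flip = rng.random(m) < 0.5
    freqs = np.where(flip, 1.0 - maf, maf)  # frequency of allele_2
    freqs = np.clip(freqs, 1e-6, 1.0 - 1e-6)

    # Haplotypes stored as (2n, m); rows 2i, 2i+1 belong to individual i.
    hap = np.empty((2 * n, m), dtype=np.int8)
    founder_rows = np.flatnonzero((sidx < 0) & (didx < 0))
    n_founder_hap = 2 * len(founder_rows)
    for c in range(config.n_chromosomes):
        sl = slice(c * mk, (c + 1) * mk)
        fh = _founder_haplotypes(rng, n_founder_hap, freqs[sl], config.ld_decay)
        for k, i in enumerate(founder_rows):
            hap[2 * i, sl] = fh[2 * k]
            hap[2 * i + 1, sl] = fh[2 * k + 1]

    chrom_slices = [slice(c * mk, (c + 1) * mk) for c in range(config.n_chromosomes)]
    chrom_pos = [positions[sl] for sl in chrom_slices]

    def gamete(parent: int) -> np.ndarray:
        g = np.empty(m, dtype=np.int8)
        for sl, pos in zip(chrom_slices, chrom_pos):
            start = rng.integers(0, 2)
            xover = rng.integers(1, config.chromosome_length_bp + 1)
            use_second = (pos > xover).astype(np.int8) ^ start
            h0 = hap[2 * parent, sl]
            h1 = hap[2 * parent + 1, sl]
            g[sl] = np.where(use_second == 0, h0, h1)
        return g

    for i in range(n):
        if sidx[i] < 0 and didx[i] < 0:
            continue
        if sidx[i] < 0 or didx[i] < 0:
            raise ConfigError("simulated pedigrees must have both parents or none")
        hap[2 * i] = gamete(sidx[i])
        hap[2 * i + 1] = gamete(didx[i])

    values = (hap[0::2] + hap[1::2]).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = np.nan
    mean_gencall = rng.beta(45.0, 5.0, size=m)  # mean ~0.9, chip-like
    geno = GenotypeMatrix(
        values=values,
        individual_ids=pedigree.individual.copy(),
        mean_gencall=mean_gencall,
    )
    return marker_map, geno


def _select_qtl_markers(
    rng: np.random.Generator,
    marker_map: pd.DataFrame,
    values: np.ndarray,
    config: SimConfig,
) -> np.ndarray:
    """Pick QTL markers with decent frequency, spaced apart in bp.

    QTL are assigned round-robin over the allowed chromosomes (all
    chromosomes when ``qtl_chromosomes`` is None), so e.g. 4 QTL on
    chromosomes (1, 2) plant two per chromosome.
    """
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(values, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    chrom = marker_map["chromosome"].to_numpy()
    pos = marker_map["position_bp"].to_numpy()
    allowed = (
        list(config.qtl_chromosomes)
        if config.qtl_chromosomes is not None
        else sorted(np.unique(chrom).tolist())
    )
    chosen: list[int] = []
    for k in range(config.n_qtl):
        c = allowed[k % len(allowed)]
        eligible = np.flatnonzero((maf >= 0.1) & (chrom == c))
        eligible = [
            int(j)
            for j in rng.permutation(eligible)
            if all(
                chrom[j] != chrom[q]
                or abs(int(pos[j]) - int(pos[q])) >= config.qtl_min_distance_bp
                for q in chosen
            )
        ]
        if not eligible:
            raise ConfigError(
                f"could not place QTL {k + 1} on chromosome {c} at least "
                f"{config.qtl_min_distance_bp} bp from the others; relax the constraint"
            )
        chosen.append(eligible[0])
    return np.sort(np.array(chosen, dtype=np.int64))


def simulate_phenotypes(
    config: SimConfig,
    marker_map: pd.DataFrame,
    genotypes: GenotypeMatrix,
    A: np.ndarray,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Corrected phenotypes y_c with reliability weights, plus ground truth.

    ``y_c = mu + X_qtl b + u + e`` with ``u ~ N(0, A sigma2_u)`` and
    ``e_i ~ N(0, sigma2_e / w_i)``, ``w_i ~ Uniform(weight_range)``.
    QTL effects alternate in sign and are rescaled post hoc so the
    planted QTL jointly explain exactly ``qtl_variance_fraction`` of the
    realised additive genetic variance var(X_qtl b) + sigma2_u.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = genotypes.n_individuals
    if A.shape != (n, n):
        raise ValueError("relationship matrix does not match genotypes")

    genetic = np.zeros(n)
    qtl_idx = np.array([], dtype=np.int64)
    effects = np.array([])
    spans: list[tuple[int, int, int]] = []
    if config.n_qtl > 0 and config.qtl_variance_fraction > 0:
        if config.sigma2_u <= 0:
            raise ConfigError(
                "qtl_variance_fraction is a share of additive variance; "
                "it needs sigma2_u > 0 when n_qtl > 0"
            )
        qtl_idx = _select_qtl_markers(rng, marker_map, genotypes.values, config)
        Xq = genotypes.values[:, qtl_idx].copy()
        # QTL columns must be complete for an exact in-sample variance target
        col_mean = np.nanmean(Xq, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(Xq))
        Xq[nan_r, nan_c] = col_mean[nan_c]
        signs = np.array([1.0 if k % 2 == 0 else -1.0 for k in range(config.n_qtl)])
        raw = signs * rng.uniform(0.8, 1.2, size=config.n_qtl)
        gq = Xq @ raw
        cur = gq.var()
        f = config.qtl_variance_fraction
        target = config.sigma2_u * f / (1.0 - f)
        scale = np.sqrt(target / cur) if cur > 0 else 0.0
        effects = raw * scale
        genetic = Xq @ effects
        pos = marker_map["position_bp"].to_numpy()
        chrom = marker_map["chromosome"].to_numpy()
        spans = [(int(chrom[j]), int(pos[j]), int(pos[j]) + 1) for j in qtl_idx]

    if config.sigma2_u > 0:
        try:
            L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise np.linalg.LinAlgError(
                "relationship matrix is not positive semi-definite; "
                "check the pedigree ordering"
            ) from exc
        u = np.sqrt(config.sigma2_u) * (L @ rng.standard_normal(n))
    else:
        u = np.zeros(n)

    w = rng.uniform(config.weight_range[0], config.weight_range[1], size=n)
    e = rng.standard_normal(n) * np.sqrt(config.sigma2_e / w)
    y = config.mu + genetic + u + e
    phen = pd.DataFrame(
        {
            "individual": genotypes.individual_ids,
            "trait": config.trait_name,
            "y_c": y,
            "weight": w,
        }
    )
    truth = TruthRecord(
        qtl_marker_indices=qtl_idx,
        qtl_effects=effects,
        true_u=u,
        true_region_spans=spans,
    )
    return phen, truth


def simulate_dataset(config: SimConfig):
    """One-call generator: pedigree, A, marker map, genotypes, phenotypes, truth."""
    ped = simulate_pedigree(config)
    A = relationship_matrix(ped)
    marker_map, geno = simulate_genotypes(config, ped)
    phen, truth = simulate_phenotypes(config, marker_map, geno, A)
    return ped, A, marker_map, geno, phen, truth
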