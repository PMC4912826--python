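"""Synthetic-data generator: pedigree, LD genotypes, weighted phenotypes."""

import numpy as np
import pytest

from pigwas import (
    SimConfig,
    relationship_matrix,
    simulate_dataset,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)
from pigwas.simulate import ConfigError, _founder_haplotypes


def test_smallest_pedigree():
    ped = simulate_pedigree(
        SimConfig(n_founders=2, n_generations=1, offspring_per_mating=1)
    )
    assert ped.n == 3
    assert set((int(ped.sire[2]), int(ped.dam[2]))) == {1, 2}
    assert (ped.sire[:2] == 0).all() and (ped.dam[:2] == 0).all()


def test_zero_generations_founders_only():
    ped = simulate_pedigree(SimConfig(n_founders=7, n_generations=0))
    assert ped.n == 7
    assert (ped.sire == 0).all() and (ped.dam == 0).all()


def test_pedigree_deterministic_given_seed():
    cfg = SimConfig(n_founders=10, n_generations=2, seed=99)
    p1, p2 = simulate_pedigree(cfg), simulate_pedigree(cfg)
    assert np.array_equal(p1.individual, p2.individual)
    assert np.array_equal(p1.sire, p2.sire)
    assert np.array_equal(p1.dam, p2.dam)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_founders=0),
        dict(ld_decay=1.5),
        dict(missing_rate=-0.1),
        dict(weight_range=(0.0, 1.0)),
        dict(qtl_variance_fraction=1.0),
        dict(maf_spectrum=("uniform", 0.0, 0.6)),
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ConfigError):
        SimConfig(**kwargs)


def test_no_missingness_gives_full_call_frequency():
    cfg = SimConfig(n_founders=20, n_generations=1, n_chromosomes=2,
                    n_markers_per_chromosome=30, missing_rate=0.0, seed=1)
    ped = simulate_pedigree(cfg)
    _, geno = simulate_genotypes(cfg, ped)
    assert np.all(geno.call_frequency == 1.0)
    assert np.all(geno.call_rate == 1.0)


def test_maximal_ld_constant_frequency_gives_identical_adjacent_markers():
    rng = np.random.default_rng(0)
    freqs = np.full(50, 0.3)
    h = _founder_haplotypes(rng, 2, freqs, ld_decay=0.0)
    assert (h == h[:, [0]]).all()


def test_adjacent_marker_correlation_decreases_with_ld_decay():
    rng = np.random.default_rng(1)
    freqs = np.full(2, 0.4)
    cors = []
    for r in (0.1, 0.5, 0.9):
        h = _founder_haplotypes(np.random.default_rng(1), 2000, freqs, ld_decay=r)
        cors.append(np.corrcoef(h[:, 0], h[:, 1])[0, 1])
    assert cors[0] > cors[1] > cors[2]
    # theoretical correlation for equal frequencies is 1 - ld_decay
    assert cors[0] == pytest.approx(0.9, abs=0.05)
    assert cors[2] == pytest.approx(0.1, abs=0.05)


def test_founder_frequencies_match_configured_spectrum():
    cfg = SimConfig(n_founders=1500, n_generations=0, n_chromosomes=2,
                    n_markers_per_chromosome=150, missing_rate=0.0,
                    maf_spectrum=("uniform", 0.1, 0.5), ld_decay=0.5, seed=2)
    ped = simulate_pedigree(cfg)
    _, geno = simulate_genotypes(cfg, ped)
    freq = geno.values.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    # realised MAFs should span the configured band, not shrink to its middle
    assert maf.min() > 0.05
    assert np.quantile(maf, 0.1) < 0.20
    assert np.quantile(maf, 0.9) > 0.40
    assert abs(maf.mean() - 0.3) < 0.03


def test_genotypes_deterministic_and_biallelic():
    cfg = SimConfig(n_founders=15, n_generations=2, n_chromosomes=2,
                    n_markers_per_chromosome=25, seed=4)
    ped = simulate_pedigree(cfg)
    m1, g1 = simulate_genotypes(cfg, ped)
    m2, g2 = simulate_genotypes(cfg, ped)
    assert m1.equals(m2)
    assert np.array_equal(g1.values, g2.values, equal_nan=True)
    called = g1.values[~np.isnan(g1.values)]
    assert set(np.unique(called)) <= {0.0, 1.0, 2.0}
    pos = m1.groupby("chromosome")["position_bp"]
    assert (pos.apply(lambda s: s.is_monotonic_increasing)).all()


def test_degenerate_phenotypes_constant_mu():
    cfg = SimConfig(n_founders=10, n_generations=1, n_chromosomes=1,
                    n_markers_per_chromosome=10, n_qtl=0,
                    qtl_variance_fraction=0.0, sigma2_u=0.0, sigma2_e=0.0,
                    mu=3.5, missing_rate=0.0, seed=5)
    ped = simulate_pedigree(cfg)
    A = relationship_matrix(ped)
    mm, geno = simulate_genotypes(cfg, ped)
    phen, truth = simulate_phenotypes(cfg, mm, geno, A)
    assert np.allclose(phen["y_c"], 3.5)
    assert len(truth.qtl_marker_indices) == 0


def test_weights_scale_residual_variance():
    # var(e | w=1) / var(e | w=4) should be 4 over many replicates
    cfg = SimConfig(n_founders=10, n_generations=0, n_chromosomes=1,
                    n_markers_per_chromosome=5, n_qtl=0,
                    qtl_variance_fraction=0.0, sigma2_u=0.0, sigma2_e=1.0,
                    missing_rate=0.0)
    rng = np.random.default_rng(8)
    draws_w1, draws_w4 = [], []
    for w, sink in ((1.0, draws_w1), (4.0, draws_w4)):
        c = SimConfig(**{**cfg.to_dict(), "weight_range": (w, w), "seed": 0})
        ped = simulate_pedigree(c)
        A = relationship_matrix(ped)
        mm, geno = simulate_genotypes(c, ped)
        for rep in range(1200):
            c2 = SimConfig(**{**c.to_dict(), "seed": rep})
            phen, _ = simulate_phenotypes(c2, mm, geno, A)
            sink.extend(phen["y_c"].to_list())
    ratio = np.var(draws_w1) / np.var(draws_w4)
    assert ratio == pytest.approx(4.0, rel=0.15)


def test_polygenic_variance_matches_relationship_diagonal():
    cfg = SimConfig(n_founders=12, n_generations=2, n_chromosomes=1,
                    n_markers_per_chromosome=10, n_qtl=0,
                    qtl_variance_fraction=0.0, sigma2_u=2.0, sigma2_e=0.0,
                    weight_range=(1.0, 1.0), missing_rate=0.0)
    ped = simulate_pedigree(SimConfig(**{**cfg.to_dict(), "seed": 0}))
    A = relationship_matrix(ped)
    mm, geno = simulate_genotypes(SimConfig(**{**cfg.to_dict(), "seed": 0}), ped)
    us = []
    for rep in range(600):
        c2 = SimConfig(**{**cfg.to_dict(), "seed": rep})
        _, truth = simulate_phenotypes(c2, mm, geno, A)
        us.append(truth.true_u)
    emp = np.var(np.array(us), axis=0)
    expected = 2.0 * np.diag(A)
    assert np.allclose(emp, expected, rtol=0.25)


def test_planted_qtl_hit_exact_variance_fraction():
    cfg = SimConfig(n_founders=80, n_generations=2, n_chromosomes=3,
                    n_markers_per_chromosome=60, n_qtl=3,
                    qtl_variance_fraction=0.4, sigma2_u=1.5, sigma2_e=1.0,
                    missing_rate=0.0, qtl_min_distance_bp=1_000_000, seed=6)
    ped, A, mm, geno, phen, truth = simulate_dataset(cfg)
    Xq = geno.values[:, truth.qtl_marker_indices]
    var_qtl = (Xq @ truth.qtl_effects).var()
    frac = var_qtl / (var_qtl + cfg.sigma2_u)
    assert frac == pytest.approx(0.4, abs=1e-10)
    assert len(truth.true_region_spans) == 3
    chroms = {c for c, _, _ in truth.true_region_spans}
    assert chroms == {1, 2, 3}  # round-robin placement
    # signs alternate
    assert np.all(np.sign(truth.qtl_effects) == np.array([1, -1, 1]))


def test_dataset_bit_identical_for_same_seed():
    cfg = SimConfig(n_founders=12, n_generations=1, n_chromosomes=2,
                    n_markers_per_chromosome=20, seed=123)
    a = simulate_dataset(cfg)
    b = simulate_dataset(cfg)
    assert np.array_equal(a[3].values, b[3].values, equal_nan=True)
    assert np.array_equal(a[4]["y_c"], b[4]["y_c"])
    assert np.array_equal(a[5].true_u, b[5].true_u)
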