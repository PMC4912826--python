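"""Shared fixtures: small simulated data sets and a short planted-QTL
mixture-model fit reused across the mixture and region tests."""

import numpy as np
import pytest

from pigwas import BayesMixtureGWAS, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def planted_sim():
    """n=400, m=400 data set with one planted QTL on each of chromosomes 1-2."""
    cfg = SimConfig(
        n_founders=100,
        n_generations=3,
        offspring_per_mating=2,
        n_chromosomes=4,
        n_markers_per_chromosome=100,
        chromosome_length_bp=10_000_000,
        n_qtl=2,
        qtl_variance_fraction=0.5,
        qtl_chromosomes=(1, 2),
        sigma2_u=1.0,
        sigma2_e=1.0,
        missing_rate=0.0,
        seed=3,
    )
    ped, A, mm, geno, phen, truth = simulate_dataset(cfg)
    return {
        "config": cfg,
        "pedigree": ped,
        "A": A,
        "marker_map": mm,
        "genotypes": geno,
        "phenotypes": phen,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def planted_fit(planted_sim):
    """Short mixture-model chain (2600 cycles) on the planted data set."""
    d = planted_sim
    bm = BayesMixtureGWAS(n_cycles=2600, burn_in=1000, thin=2, seed=7)
    bm.fit(
        d["genotypes"].values,
        d["phenotypes"]["y_c"].to_numpy(),
        pedigree=d["pedigree"],
        weights=d["phenotypes"]["weight"].to_numpy(),
    )
    return bm


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
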