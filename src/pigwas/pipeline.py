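"""End-to-end analysis pipeline: QC -> imputation -> LM scan -> mixture
chain -> region scan, driven by a YAML/dict configuration.

Every output is a plain-text table re-readable by the package's own
readers; the run log records the seed, thresholds, a hash of the full
configuration and the counts at each stage, which is enough to
reproduce a run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .lmm import MixedModelGWAS
from .mixture import BayesMixtureGWAS, GibbsConfig
from .pedigree import relationship_matrix
from .qc import MarkerQC, impute_missing_naive
from .regions import QTLRegionScan

logger = logging.getLogger("pigwas")


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration (caught before any compute)."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and chain settings for one pipeline run."""

    genotype_path: str = ""
    map_path: str = ""
    gencall_path: str | None = None
    pedigree_path: str = ""
    phenotype_path: str = ""
    out_dir: str = "pigwas_run"
    # marker / animal QC (defaults: chip-QC thresholds, strict inequalities)
    maf_min: float = 0.01
    call_frequency_min: float = 0.9
    mean_gencall_min: float = 0.60
    hwe_p_min: float = 1e-7
    animal_call_rate_min: float = 0.8
    # LM scan
    alpha_levels: tuple[float, ...] = (0.05, 0.01)
    # mixture chain
    n_cycles: int = 52_000
    burn_in: int = 20_000
    thin: int = 20
    variance_ratio: float = 100.0
    pi_prior_a: float = 100.0
    pi_prior_b: float = 1.0
    # region scan
    window_lengths_bp: tuple[int, ...] = (1_000_000, 2_500_000, 5_000_000)
    pp_int_threshold: float = 0.8
    variance_denominator: str = "genomic_plus_polygenic"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.pp_int_threshold <= 1.0:
            raise PipelineConfigError(
                f"pp_int_threshold must lie in (0, 1], got {self.pp_int_threshold}"
            )
        for name in ("maf_min", "call_frequency_min", "mean_gencall_min",
                     "hwe_p_min", "animal_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PipelineConfigError(f"{name} must lie in [0, 1], got {v}")
        if any(not 0.0 < a < 1.0 for a in self.alpha_levels):
            raise PipelineConfigError("alpha levels must lie in (0, 1)")
        if any(L < 1 for L in self.window_lengths_bp):
            raise PipelineConfigError("window lengths must be positive")
        GibbsConfig(self.n_cycles, self.burn_in, self.thin, self.seed)
        for name in ("genotype_path", "map_path", "pedigree_path", "phenotype_path"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise PipelineConfigError(f"{name} does not exist: {p!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("alpha_levels", "window_lengths_bp"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["alpha_levels"] = list(self.alpha_levels)
        d["window_lengths_bp"] = list(self.window_lengths_bp)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [
        h for h in logger.handlers if not isinstance(h, logging.FileHandler)
    ]
    fh = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        logger.addHandler(logging.StreamHandler())


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Stage failures abort with the stage named in the exception; outputs
    written before the failure are left in place for inspection.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    logger.info("config digest %s seed %d", config.digest(), config.seed)
    config.to_yaml(out / "config_used.yaml")

    stage = "read inputs"
    try:
        marker_map, geno = pio.read_genotypes(
            config.genotype_path, config.map_path, config.gencall_path
        )
        pedigree = pio.read_pedigree(config.pedigree_path)
        phen = pio.read_phenotypes(config.phenotype_path)
        logger.info(
            "read %d individuals x %d markers, pedigree of %d, %d phenotype records",
            geno.n_individuals, geno.n_markers, pedigree.n, len(phen),
        )

        stage = "quality control"
        qc = MarkerQC(
            maf_min=config.maf_min,
            call_frequency_min=config.call_frequency_min,
            mean_gencall_min=config.mean_gencall_min,
            hwe_p_min=config.hwe_p_min,
            animal_call_rate_min=config.animal_call_rate_min,
        )
        geno_qc, map_qc = qc.fit_transform(geno, marker_map)
        qc.report().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        logger.info(
            "QC kept %d/%d animals and %d/%d markers",
            len(qc.kept_animals_), geno.n_individuals,
            len(qc.kept_markers_), geno.n_markers,
        )

        stage = "imputation"
        geno_imp = impute_missing_naive(geno_qc)

        stage = "align phenotypes and pedigree"
        phen_idx = phen.set_index("individual")
        missing_ids = set(geno_imp.individual_ids) - set(phen_idx.index)
        if missing_ids:
            raise ValueError(
                f"{len(missing_ids)} genotyped individuals lack phenotypes "
                f"(first: {sorted(missing_ids)[:3]})"
            )
        phen_aligned = phen_idx.loc[geno_imp.individual_ids]
        y = phen_aligned["y_c"].to_numpy(dtype=float)
        w = phen_aligned["weight"].to_numpy(dtype=float)
        A_full = relationship_matrix(pedigree)
        ped_pos = {int(v): i for i, v in enumerate(pedigree.individual)}
        rows = np.array([ped_pos[int(i)] for i in geno_imp.individual_ids])
        A = A_full[np.ix_(rows, rows)]
        full_pedigree_kept = len(rows) == pedigree.n and np.array_equal(
            rows, np.arange(pedigree.n)
        )

        stage = "linear mixed-model scan"
        lm = MixedModelGWAS(alpha_levels=config.alpha_levels)
        lm.fit(geno_imp.values, y, A=A, weights=w, marker_map=map_qc)
        lm.results_.to_csv(out / "association.tsv", sep="\t", index=False)
        logger.info(
            "LM scan: sigma2_u=%.4g sigma2_e=%.4g lambda=%.3f",
            lm.sigma2_u_, lm.sigma2_e_, lm.lambda_gc_,
        )

        stage = "Bayesian mixture chain"
        bm = BayesMixtureGWAS(
            n_cycles=config.n_cycles,
            burn_in=config.burn_in,
            thin=config.thin,
            variance_ratio=config.variance_ratio,
            pi_prior_a=config.pi_prior_a,
            pi_prior_b=config.pi_prior_b,
            seed=config.seed,
        )
        if full_pedigree_kept:
            bm.fit(geno_imp.values, y, pedigree=pedigree, weights=w)
        else:
            bm.fit(geno_imp.values, y, A=A, weights=w)
        scalars = pd.DataFrame(
            {
                "cycle": np.arange(bm.samples_.n_saved),
                "mu": bm.samples_.mu,
                "sigma2_g0": bm.samples_.sigma2_g0,
                "pi0": bm.samples_.pi0,
                "sigma2_u": bm.samples_.sigma2_u,
                "sigma2_e": bm.samples_.sigma2_e,
            }
        )
        scalars.to_csv(out / "chain_scalars.tsv", sep="\t", index=False)
        marker_post = map_qc.copy()
        marker_post["effect_mean"] = bm.effect_mean_
        marker_post["inclusion_frequency"] = bm.inclusion_
        marker_post.to_csv(out / "marker_posterior.tsv", sep="\t", index=False)
        np.save(out / "indicator_samples.npy", bm.samples_.delta)
        logger.info(
            "chain saved %d samples, residual drift %.2e",
            bm.samples_.n_saved, bm.residual_drift_,
        )

        stage = "region scan"
        rs = QTLRegionScan(
            window_lengths=config.window_lengths_bp,
            threshold=config.pp_int_threshold,
            denominator=config.variance_denominator,
        )
        rs.fit(bm.samples_, map_qc, genotypes=geno_imp.values)
        for L, win in rs.windows_.items():
            win.to_csv(out / f"pp_int_track_{L}bp.tsv", sep="\t", index=False)
        rs.regions_.to_csv(out / "regions.tsv", sep="\t", index=False)
        logger.info("detected %d QTL regions across window lengths", len(rs.regions_))
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
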