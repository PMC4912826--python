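"""Marker and animal quality control, plus naive mean imputation.

Default thresholds follow common chip-QC practice for this kind of
panel: a marker is kept iff MAF > 0.01, call frequency > 0.9, mean
GenCall > 0.60, Hardy-Weinberg chi-square P > 1e-7 and it has a known
map position (all inequalities strict); animals with call rate < 0.8
are excluded. Animals are filtered first, then marker statistics are
recomputed on the kept animals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeMatrix

MAF_MIN = 0.01
CALL_FREQUENCY_MIN = 0.9
MEAN_GENCALL_MIN = 0.60
HWE_P_MIN = 1e-7
ANIMAL_CALL_RATE_MIN = 0.8


def hwe_chi_square(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    Expected counts are n*p^2, 2n*p*q, n*q^2 with the allele frequency p
    estimated from the sample; the p-value is the upper tail. A
    monomorphic sample (p = 0 or 1) returns (0, 1) by convention.
    """
    n = n_AA + n_Aa + n_aa
    if n <= 0:
        raise ValueError("hwe_chi_square needs at least one genotyped individual")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p <= 0.0 or p >= 1.0:
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def compute_marker_stats(
    genotypes: GenotypeMatrix, marker_map: pd.DataFrame
) -> pd.DataFrame:
    """Per-marker QC statistics: MAF, call frequency, GenCall mean, HWE P.

    MAF is computed on non-missing calls only (genotype coded as the
    count of allele_2). A marker with zero non-missing calls gets
    undefined (NaN) maf/hwe_p and auto-fails the filter.
    """
    X = genotypes.values
    n, m = X.shape
    if len(marker_map) != m:
        raise ValueError("marker map length does not match genotype matrix")
    miss = np.isnan(X)
    n_called = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(X, axis=0) / (2.0 * np.maximum(n_called, 1))
    maf = np.minimum(freq, 1.0 - freq)
    maf[n_called == 0] = np.nan

    n_aa = ((X == 0) & ~miss).sum(axis=0)
    n_het = (X == 1).sum(axis=0)
    n_bb = (X == 2).sum(axis=0)
    hwe_p = np.full(m, np.nan)
    for j in range(m):
        if n_called[j] > 0:
            _, hwe_p[j] = hwe_chi_square(int(n_aa[j]), int(n_het[j]), int(n_bb[j]))

    has_position = (
        marker_map["position_bp"].notna() & (marker_map["position_bp"] >= 1)
    ).to_numpy()
    return pd.DataFrame(
        {
            "marker_id": marker_map["marker_id"].to_numpy(),
            "maf": maf,
            "call_frequency": genotypes.call_frequency,
            "mean_gencall": genotypes.mean_gencall,
            "hwe_p": hwe_p,
            "has_position": has_position,
        }
    )


def filter_markers(
    stats_df: pd.DataFrame,
    maf_min: float = MAF_MIN,
    call_frequency_min: float = CALL_FREQUENCY_MIN,
    mean_gencall_min: float = MEAN_GENCALL_MIN,
    hwe_p_min: float = HWE_P_MIN,
) -> np.ndarray:
    """Indices of markers passing all QC thresholds (strict inequalities)."""
    ok = (
        (stats_df["maf"].to_numpy() > maf_min)
        & (stats_df["call_frequency"].to_numpy() > call_frequency_min)
        & (stats_df["mean_gencall"].to_numpy() > mean_gencall_min)
        & (stats_df["hwe_p"].to_numpy() > hwe_p_min)
        & stats_df["has_position"].to_numpy()
    )
    ok &= ~np.isnan(stats_df["maf"].to_numpy())
    return np.flatnonzero(ok)


def filter_animals(
    genotypes: GenotypeMatrix, call_rate_min: float = ANIMAL_CALL_RATE_MIN
) -> np.ndarray:
    """Indices of individuals kept: call rate >= threshold (exclusion is strict <)."""
    return np.flatnonzero(genotypes.call_rate >= call_rate_min)


def impute_missing_naive(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing call with the marker's rounded mean genotype.

    Non-missing entries are never changed. Raises if a marker has no
    non-missing calls (filter such markers first).
    """
    X = genotypes.values.copy()
    miss = np.isnan(X)
    if not miss.any():
        return GenotypeMatrix(X, genotypes.individual_ids, genotypes.mean_gencall)
    all_missing = miss.all(axis=0)
    if all_missing.any():
        j = int(np.flatnonzero(all_missing)[0])
        raise ValueError(
            f"marker column {j} has no non-missing calls; run filter_markers first"
        )
    col_mean = np.nanmean(X, axis=0)
    fill = np.clip(np.rint(col_mean), 0, 2)
    r, c = np.nonzero(miss)
    X[r, c] = fill[c]
    return GenotypeMatrix(X, genotypes.individual_ids, genotypes.mean_gencall)


def qc_report(
    stats_df: pd.DataFrame,
    maf_min: float = MAF_MIN,
    call_frequency_min: float = CALL_FREQUENCY_MIN,
    mean_gencall_min: float = MEAN_GENCALL_MIN,
    hwe_p_min: float = HWE_P_MIN,
) -> pd.DataFrame:
    """Stats table with pass/fail and the first failing reason per marker."""
    out = stats_df.copy()
    maf = out["maf"].to_numpy()
    reasons = np.full(len(out), "", dtype=object)
    checks = [
        (np.isnan(maf), "no_calls"),
        (~(maf > maf_min), "maf"),
        (~(out["call_frequency"].to_numpy() > call_frequency_min), "call_frequency"),
        (~(out["mean_gencall"].to_numpy() > mean_gencall_min), "mean_gencall"),
        (~(out["hwe_p"].to_numpy() > hwe_p_min), "hwe"),
        (~out["has_position"].to_numpy(), "no_position"),
    ]
    for mask, label in checks:
        hit = mask & (reasons == "")
        reasons[hit] = label
    out["fail_reason"] = reasons
    out["pass"] = reasons == ""
    return out


class MarkerQC:
    """Transformer applying animal-then-marker QC to a genotype matrix.

    Scikit-learn style: ``fit`` computes which animals and markers pass,
    ``transform`` subsets a :class:`GenotypeMatrix` and marker map.
    Fitted attributes: ``kept_animals_``, ``kept_markers_``, ``stats_``.
    """

    def __init__(
        self,
        maf_min: float = MAF_MIN,
        call_frequency_min: float = CALL_FREQUENCY_MIN,
        mean_gencall_min: float = MEAN_GENCALL_MIN,
        hwe_p_min: float = HWE_P_MIN,
        animal_call_rate_min: float = ANIMAL_CALL_RATE_MIN,
    ) -> None:
        self.maf_min = maf_min
        self.call_frequency_min = call_frequency_min
        self.mean_gencall_min = mean_gencall_min
        self.hwe_p_min = hwe_p_min
        self.animal_call_rate_min = animal_call_rate_min

    def get_params(self, deep: bool = True) -> dict:
        return {
            "maf_min": self.maf_min,
            "call_frequency_min": self.call_frequency_min,
            "mean_gencall_min": self.mean_gencall_min,
            "hwe_p_min": self.hwe_p_min,
            "animal_call_rate_min": self.animal_call_rate_min,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, genotypes: GenotypeMatrix, marker_map: pd.DataFrame) -> "MarkerQC":
        self.kept_animals_ = filter_animals(genotypes, self.animal_call_rate_min)
        sub = GenotypeMatrix(
            genotypes.values[self.kept_animals_],
            genotypes.individual_ids[self.kept_animals_],
            genotypes.mean_gencall,
        )
        self.stats_ = compute_marker_stats(sub, marker_map)
        self.kept_markers_ = filter_markers(
            self.stats_,
            self.maf_min,
            self.call_frequency_min,
            self.mean_gencall_min,
            self.hwe_p_min,
        )
        return self

    def transform(
        self, genotypes: GenotypeMatrix, marker_map: pd.DataFrame
    ) -> tuple[GenotypeMatrix, pd.DataFrame]:
        geno = GenotypeMatrix(
            genotypes.values[np.ix_(self.kept_animals_, self.kept_markers_)],
            genotypes.individual_ids[self.kept_animals_],
            genotypes.mean_gencall[self.kept_markers_],
        )
        mm = marker_map.iloc[self.kept_markers_].reset_index(drop=True)
        return geno, mm

    def fit_transform(self, genotypes, marker_map):
        return self.fit(genotypes, marker_map).transform(genotypes, marker_map)

    def report(self) -> pd.DataFrame:
        return qc_report(
            self.stats_,
            self.maf_min,
            self.call_frequency_min,
            self.mean_gencall_min,
            self.hwe_p_min,
        )
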