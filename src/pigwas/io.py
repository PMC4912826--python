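"""Readers and writers for the package's plain-text data dialects.

Formats (all tab-separated, lossless round-trip with the writers):

* marker map: PLINK-style ``.map`` — chromosome, marker_id, genetic
  distance (written as 0), 1-based bp position; one marker per line,
  sorted by chromosome then position.
* genotypes: TSV with header ``individual_id`` followed by marker ids;
  one row per individual; entries 0/1/2 or ``NA`` for a missing call.
* GenCall metadata (optional sidecar): TSV marker_id, mean_gencall.
* pedigree: CSV individual,sire,dam,generation with 0 = unknown parent.
* phenotypes: TSV individual, trait, y_c, weight.
* truth: JSON dump of a :class:`~pigwas.simulate.TruthRecord`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .simulate import GenotypeMatrix, TruthRecord


class FormatError(ValueError):
    """Malformed input file; the message names the file and line."""


def write_map(marker_map: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chromosome": marker_map["chromosome"],
            "marker_id": marker_map["marker_id"],
            "cm": 0,
            "position_bp": marker_map["position_bp"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_map(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            try:
                chrom = int(parts[0])
                pos = int(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer chromosome/position") from exc
            rows.append((parts[1], chrom, pos))
    mm = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"])
    mm["allele_1"] = "A"
    mm["allele_2"] = "B"
    dup = mm["marker_id"].duplicated()
    if dup.any():
        raise FormatError(
            f"{path}: duplicate marker id {mm['marker_id'][dup].iloc[0]!r}"
        )
    chrom = mm["chromosome"].to_numpy()
    pos = mm["position_bp"].to_numpy()
    for j in range(1, len(mm)):
        if chrom[j] < chrom[j - 1] or (chrom[j] == chrom[j - 1] and pos[j] <= pos[j - 1]):
            raise FormatError(
                f"{path}: map not sorted by chromosome/position; first offender "
                f"{mm['marker_id'].iloc[j]!r}"
            )
    return mm


def write_genotypes(geno: GenotypeMatrix, marker_map: pd.DataFrame, path) -> None:
    df = pd.DataFrame(
        geno.values, columns=marker_map["marker_id"].to_list()
    )
    df.insert(0, "individual_id", geno.individual_ids)
    # integers where called, NA where missing
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.0f")


def write_gencall(geno: GenotypeMatrix, marker_map: pd.DataFrame, path) -> None:
    pd.DataFrame(
        {"marker_id": marker_map["marker_id"], "mean_gencall": geno.mean_gencall}
    ).to_csv(path, sep="\t", index=False)


def read_genotypes(
    genotype_path, map_path, gencall_path=None
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Read the .map + genotype-TSV pair (plus optional GenCall sidecar)."""
    marker_map = read_map(map_path)
    df = pd.read_csv(genotype_path, sep="\t", dtype={"individual_id": np.int64})
    if df.columns[0] != "individual_id":
        raise FormatError(f"{genotype_path}: first column must be 'individual_id'")
    marker_cols = list(df.columns[1:])
    if marker_cols != marker_map["marker_id"].to_list():
        raise FormatError(
            f"{genotype_path}: marker columns do not match {map_path}"
        )
    values = df[marker_cols].to_numpy(dtype=float)
    valid = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise FormatError(
            f"{genotype_path}: invalid genotype {values[i, j]!r} at data row "
            f"{i + 1}, marker {marker_cols[j]!r}"
        )
    if gencall_path is not None and Path(gencall_path).exists():
        gc = pd.read_csv(gencall_path, sep="\t")
        gc = gc.set_index("marker_id").reindex(marker_map["marker_id"])
        mean_gencall = gc["mean_gencall"].to_numpy(dtype=float)
    else:
        mean_gencall = np.ones(len(marker_map))
    geno = GenotypeMatrix(
        values=values,
        individual_ids=df["individual_id"].to_numpy(),
        mean_gencall=mean_gencall,
    )
    return marker_map, geno


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.to_frame().to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path)
    for col in ("individual", "sire", "dam"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return Pedigree.from_frame(df)


def write_phenotypes(phen: pd.DataFrame, path) -> None:
    phen.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("individual", "trait", "y_c", "weight"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if (df["weight"] <= 0).any():
        bad = df.index[df["weight"] <= 0][0]
        raise FormatError(f"{path}: non-positive weight at data row {bad + 1}")
    return df


def write_truth(truth: TruthRecord, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_truth(path) -> TruthRecord:
    with open(path) as fh:
        d = json.load(fh)
    return TruthRecord(
        qtl_marker_indices=np.array(d["qtl_marker_indices"], dtype=np.int64),
        qtl_effects=np.array(d["qtl_effects"], dtype=float),
        true_u=np.array(d["true_u"], dtype=float),
        true_region_spans=[tuple(x) for x in d["true_region_spans"]],
    )
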