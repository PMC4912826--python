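"""Pedigree container and additive (numerator) relationship matrices.

The additive relationship matrix ``A`` gives the expected covariance of
additive genetic values between relatives: ``u ~ N(0, A * sigma2_u)``.
It is built with the tabular method; its sparse inverse, needed by the
Gibbs sampler's polygenic updates, is built directly from the pedigree
with Henderson's rules (accounting for parental inbreeding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = 0  #: parent code for "unknown" in pedigree files


class PedigreeError(ValueError):
    """Structural problem in a pedigree (unordered, cyclic, bad parent ids)."""


@dataclass
class Pedigree:
    """An ordered pedigree: parents must appear before their offspring.

    Parameters
    ----------
    individual : array of int
        Individual ids (positive integers, unique).
    sire, dam : arrays of int
        Parent ids; ``0`` encodes an unknown parent.
    generation : array of int, optional
        Generation index per individual (0 = founders). Informational only.
    """

    individual: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray | None = None
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.individual = np.asarray(self.individual, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if self.generation is not None:
            self.generation = np.asarray(self.generation, dtype=np.int64)
        if len({len(self.individual), len(self.sire), len(self.dam)}) != 1:
            raise PedigreeError("individual/sire/dam arrays differ in length")
        if len(np.unique(self.individual)) != len(self.individual):
            raise PedigreeError("duplicate individual ids in pedigree")
        if np.any(self.individual == UNKNOWN):
            raise PedigreeError("individual id 0 is reserved for unknown")
        self._index = {int(v): i for i, v in enumerate(self.individual)}
        seen: set[int] = set()
        for ind, s, d in zip(self.individual, self.sire, self.dam):
            for p in (int(s), int(d)):
                if p == UNKNOWN:
                    continue
                if p == int(ind):
                    raise PedigreeError(f"individual {ind} is its own parent")
                if p not in self._index:
                    raise PedigreeError(f"parent {p} of {ind} not in pedigree")
                if p not in seen:
                    raise PedigreeError(
                        f"parent {p} listed after offspring {ind}; "
                        "pedigree must be ordered parents-before-offspring"
                    )
            seen.add(int(ind))

    def __len__(self) -> int:
        return len(self.individual)

    @property
    def n(self) -> int:
        return len(self.individual)

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """0-based positional indices of sire and dam; -1 for unknown."""
        sidx = np.array(
            [self._index[int(s)] if s != UNKNOWN else -1 for s in self.sire],
            dtype=np.int64,
        )
        didx = np.array(
            [self._index[int(d)] if d != UNKNOWN else -1 for d in self.dam],
            dtype=np.int64,
        )
        return sidx, didx

    def to_frame(self) -> pd.DataFrame:
        gen = (
            self.generation
            if self.generation is not None
            else np.zeros(self.n, dtype=np.int64)
        )
        return pd.DataFrame(
            {
                "individual": self.individual,
                "sire": self.sire,
                "dam": self.dam,
                "generation": gen,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        gen = df["generation"].to_numpy() if "generation" in df.columns else None
        return cls(
            individual=df["individual"].to_numpy(),
            sire=df["sire"].to_numpy(),
            dam=df["dam"].to_numpy(),
            generation=gen,
        )


def relationship_matrix(pedigree: Pedigree) -> np.ndarray:
    """Additive relationship matrix A by the tabular method.

    ``a_ii = 1 + 0.5 * a(sire_i, dam_i)``;
    ``a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))`` for j < i; unknown
    parents contribute 0. Rows must be ordered parents-before-offspring,
    which the :class:`Pedigree` constructor enforces.
    """
    n = pedigree.n
    sidx, didx = pedigree.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sidx[i], didx[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def inbreeding_coefficients(pedigree: Pedigree) -> np.ndarray:
    """F_i = a_ii - 1 from the tabular relationship matrix."""
    return np.diag(relationship_matrix(pedigree)) - 1.0


def a_inverse(pedigree: Pedigree) -> sparse.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding.

    The Mendelian-sampling variance of individual i is
    ``d_i = 0.5 - 0.25 (F_s + F_d)`` with both parents known,
    ``0.75 - 0.25 F_p`` with one parent p known, and 1 otherwise; each
    individual contributes ``alpha = 1/d_i`` to a small block of A^{-1}.
    """
    n = pedigree.n
    sidx, didx = pedigree.parent_indices()
    F = inbreeding_coefficients(pedigree)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        parents = [p for p in (sidx[i], didx[i]) if p >= 0]
        if len(parents) == 2:
            d = 0.5 - 0.25 * (F[parents[0]] + F[parents[1]])
        elif len(parents) == 1:
            d = 0.75 - 0.25 * F[parents[0]]
        else:
            d = 1.0
        alpha = 1.0 / d
        rows.append(i)
        cols.append(i)
        vals.append(alpha)
        for p in parents:
            rows.extend((i, p))
            cols.extend((p, i))
            vals.extend((-alpha / 2.0, -alpha / 2.0))
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(alpha / 4.0)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv
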