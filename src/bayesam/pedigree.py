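"""Pedigrees and the additive (numerator) relationship matrix.

The additive genetic effects in an animal model are correlated across
relatives: ``a | sigma2_a ~ N(0, A sigma2_a)`` where ``A`` is twice the
kinship matrix implied by the pedigree.  This module builds ``A`` with the
tabular (recursive) method, factors it (``A = L L'``), and provides the
triangular solves used everywhere ``A^{-1}`` is needed.  The Cholesky factor
``L`` is also how the samplers whiten the genetic effects (``a = L u``).
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

UNKNOWN_PARENT = 0


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id, missing parent)."""


@dataclass(frozen=True)
class Pedigree:
    """Animal/sire/dam records in topological order (parents before offspring).

    Ids are arbitrary positive integers; ``0`` marks an unknown parent
    (founder assumption).  Use :meth:`from_records` or :func:`load_pedigree`
    to construct — both sort topologically and validate.
    """

    animal: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    _index: dict = field(repr=False, hash=False, compare=False, default=None)

    @classmethod
    def from_records(
        cls, records: Iterable[Sequence[int]]
    ) -> "Pedigree":
        recs = [(int(a), int(s), int(d)) for a, s, d in records]
        if not recs:
            raise PedigreeError("empty pedigree")
        animals = [r[0] for r in recs]
        if len(set(animals)) != len(animals):
            dupes = sorted({a for a in animals if animals.count(a) > 1})
            raise PedigreeError(f"duplicate animal id(s): {dupes}")
        known = set(animals)
        by_id = {a: (s, d) for a, s, d in recs}
        for a, s, d in recs:
            for parent in (s, d):
                if parent != UNKNOWN_PARENT and parent not in known:
                    raise PedigreeError(
                        f"parent {parent} of animal {a} has no pedigree record"
                    )
            if a in (s, d):
                raise PedigreeError(f"animal {a} is its own parent")
        graph = {
            a: [p for p in by_id[a] if p != UNKNOWN_PARENT] for a in animals
        }
        try:
            order = list(graphlib.TopologicalSorter(graph).static_order())
        except graphlib.CycleError as err:
            raise PedigreeError(f"cyclic pedigree: {err.args[1]}") from err
        animal = np.array(order, dtype=np.int64)
        sire = np.array([by_id[a][0] for a in order], dtype=np.int64)
        dam = np.array([by_id[a][1] for a in order], dtype=np.int64)
        return cls(animal, sire, dam, {a: i for i, a in enumerate(order)})

    @property
    def q(self) -> int:
        """Number of animals."""
        return len(self.animal)

    @property
    def index(self) -> dict:
        """Mapping animal id -> row/column index in ``A``."""
        return self._index

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire/dam positions in topological order; -1 where unknown."""
        idx = self._index
        s = np.array(
            [idx[p] if p != UNKNOWN_PARENT else -1 for p in self.sire],
            dtype=np.int64,
        )
        d = np.array(
            [idx[p] if p != UNKNOWN_PARENT else -1 for p in self.dam],
            dtype=np.int64,
        )
        return s, d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.animal, "sire": self.sire, "dam": self.dam}
        )


def load_pedigree(path: str | Path) -> Pedigree:
    """Read an ``animal sire dam`` file (whitespace or comma separated).

    A header line is optional and detected by non-numeric tokens.  Unknown
    parents are coded ``0``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"[,\s]+", engine="python", header=None, dtype=str)
    if df.shape[1] < 3:
        raise PedigreeError(f"{path}: expected 3 columns (animal sire dam)")
    first = df.iloc[0]
    if not all(str(v).lstrip("-").isdigit() for v in first[:3]):
        df = df.iloc[1:]
    try:
        recs = df.iloc[:, :3].astype(np.int64).to_numpy()
    except ValueError as err:
        raise PedigreeError(f"{path}: non-integer pedigree entry ({err})") from err
    return Pedigree.from_records(recs)


def build_a(pedigree: Pedigree) -> np.ndarray:
    """Additive relationship matrix by the tabular method.

    Processing animals in topological order,
    ``a_ij = (a_{j,s(i)} + a_{j,d(i)}) / 2`` for j earlier than i and
    ``a_ii = 1 + a_{s(i),d(i)} / 2``; unknown-parent terms are zero.
    The diagonal equals ``1 + F_i`` with ``F_i`` the inbreeding coefficient.
    """
    s, d = pedigree.parent_indices()
    q = pedigree.q
    A = np.zeros((q, q))
    for i in range(q):
        si, di = s[i], d[i]
        if i:
            row = np.zeros(i)
            if si >= 0:
                row += 0.5 * A[si, :i]
            if di >= 0:
                row += 0.5 * A[di, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    return A


def inbreeding(A: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients F = diag(A) - 1."""
    return np.diag(A) - 1.0


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    """Cholesky failed; carries the order of the offending leading minor."""

    def __init__(self, minor: int):
        self.minor = minor
        super().__init__(
            f"matrix is not positive definite: leading minor of order "
            f"{minor} is not positive"
        )


def cholesky_factor(A: np.ndarray) -> np.ndarray:
    """Lower-triangular L with ``L L' = A`` (positive diagonal)."""
    try:
        return scipy.linalg.cholesky(A, lower=True)
    except scipy.linalg.LinAlgError as err:
        # scipy reports the failing leading minor in args[0] as "...minor k..."
        minor = next(
            (int(tok) for tok in str(err).replace("-", " ").split() if tok.isdigit()),
            -1,
        )
        raise NotPositiveDefiniteError(minor) from err


@dataclass(frozen=True)
class RelationshipFactor:
    """``A`` together with its Cholesky factor ``L`` (``A = L L'``)."""

    A: np.ndarray
    L: np.ndarray
    q: int

    @classmethod
    def from_pedigree(cls, pedigree: Pedigree) -> "RelationshipFactor":
        A = build_a(pedigree)
        return cls(A=A, L=cholesky_factor(A), q=pedigree.q)

    @classmethod
    def from_matrix(cls, A: np.ndarray) -> "RelationshipFactor":
        A = np.asarray(A, dtype=float)
        return cls(A=A, L=cholesky_factor(A), q=A.shape[0])

    def solve_a_inverse(self, v: np.ndarray) -> np.ndarray:
        """``A^{-1} v`` via two triangular solves with L (no explicit inverse)."""
        w = scipy.linalg.solve_triangular(self.L, v, lower=True)
        return scipy.linalg.solve_triangular(self.L, w, lower=True, trans="T")

    def a_inverse(self) -> np.ndarray:
        """Dense ``A^{-1}`` (used once by the Gibbs sampler's site updates)."""
        return self.solve_a_inverse(np.eye(self.q))

    def whiten(self, a: np.ndarray) -> np.ndarray:
        """u with a = L u."""
        return scipy.linalg.solve_triangular(self.L, a, lower=True)

    def unwhiten(self, u: np.ndarray) -> np.ndarray:
        """a = L u."""
        return self.L @ u
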