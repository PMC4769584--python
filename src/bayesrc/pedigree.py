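"""Pedigree handling and the numerator relationship matrix A.

A is built with the tabular method: ordering individuals so parents precede
offspring, A_ii = 1 + 0.5 * A_{sire,dam} and A_ij = 0.5 * (A_{j,sire(i)} +
A_{j,dam(i)}), with unknown parents contributing 0 (founders are treated as
unrelated and non-inbred). A scales the polygenic term of the mixed model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky

logger = logging.getLogger(__name__)


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Sire/dam records; ``None`` marks an unknown parent."""

    ids: list
    sire: list
    dam: list

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dup = {i for i in self.ids if self.ids.count(i) > 1}
            raise PedigreeError(f"duplicate pedigree id(s): {sorted(dup)}")
        known = set(self.ids)
        for p in list(self.sire) + list(self.dam):
            if p is not None and p not in known:
                raise PedigreeError(f"parent {p!r} has no pedigree record")

    def topological_order(self) -> list[int]:
        """Indices ordered parents-before-offspring; raises on a cycle."""
        idx = {v: i for i, v in enumerate(self.ids)}
        n = len(self.ids)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=int)
        for i in range(n):
            for p in (self.sire[i], self.dam[i]):
                if p is not None:
                    children[idx[p]].append(i)
                    indeg[i] += 1
        order: list[int] = []
        stack = sorted(np.flatnonzero(indeg == 0), key=lambda i: i)
        stack = list(stack)
        while stack:
            i = stack.pop(0)
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        if len(order) != n:
            cyclic = [self.ids[i] for i in range(n) if indeg[i] > 0]
            raise PedigreeError(f"pedigree cycle involving: {cyclic}")
        return order


@dataclass
class AMatrix:
    """Symmetric additive-relationship matrix with its id order."""

    ids: list
    values: np.ndarray
    _chol: np.ndarray | None = field(default=None, repr=False)

    def reorder(self, ids: list) -> "AMatrix":
        pos = {v: i for i, v in enumerate(self.ids)}
        try:
            index = [pos[i] for i in ids]
        except KeyError as exc:
            raise PedigreeError(f"id {exc.args[0]!r} not in A matrix") from exc
        return AMatrix(ids=list(ids), values=self.values[np.ix_(index, index)])

    def factor(self, jitter: float = 1e-8) -> np.ndarray:
        """Lower Cholesky factor, adding diagonal jitter if needed (logged)."""
        if self._chol is None:
            A = self.values
            try:
                L = cholesky(A, lower=True)
            except np.linalg.LinAlgError:
                logger.info("A not PD; adding diagonal jitter %g", jitter)
                L = cholesky(A + jitter * np.eye(A.shape[0]), lower=True)
            self._chol = L
        return self._chol

    def inverse(self, jitter: float = 1e-8) -> np.ndarray:
        L = self.factor(jitter)
        return cho_solve((L, True), np.eye(L.shape[0]))


def build_a_matrix(ped: Pedigree) -> AMatrix:
    """Numerator relationship matrix by the tabular method.

    Output rows follow the input id order (the internal computation uses a
    topological order, so input row order does not affect the result).
    """
    order = ped.topological_order()
    n = len(ped.ids)
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    idx = {v: i for i, v in enumerate(ped.ids)}

    A = np.zeros((n, n))
    for k in order:
        s = ped.sire[k]
        d = ped.dam[k]
        si = idx[s] if s is not None else None
        di = idx[d] if d is not None else None
        A[k, k] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
        for j in range(n):
            if rank[j] >= rank[k]:
                continue
            val = 0.0
            if si is not None:
                val += 0.5 * A[j, si]
            if di is not None:
                val += 0.5 * A[j, di]
            A[k, j] = A[j, k] = val
    return AMatrix(ids=list(ped.ids), values=A)


def read_pedigree(path: str) -> Pedigree:
    """TSV with columns id, sire, dam; '0' or empty marks an unknown parent."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("0")
    cols = list(df.columns[:3])
    as_none = lambda v: None if v in ("0", "", "NA") else v
    return Pedigree(
        ids=list(df[cols[0]]),
        sire=[as_none(v) for v in df[cols[1]]],
        dam=[as_none(v) for v in df[cols[2]]],
    )
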