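"""Numerator relationship matrix (A) construction from pedigree records.

The pedigree-based relationship matrix A carries the expected additive
genetic covariance between animals: the random breeding values are assumed
a ~ N(0, A * sigma2_a).  A is built by the tabular (recursive) method with
inbreeding, and its sparse inverse directly by Henderson's rules with
inbreeding-corrected Mendelian-sampling variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["Pedigree", "PedigreeError", "build_A", "build_A_inverse"]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, unknown id, duplicate)."""


def _is_unknown(parent) -> bool:
    if parent is None:
        return True
    if isinstance(parent, float) and np.isnan(parent):
        return True
    s = str(parent).strip()
    return s in ("", "0", "0.0", "NA", "nan", ".")


@dataclass
class Pedigree:
    """Pedigree as parallel arrays in topological order.

    ``sire[i]``/``dam[i]`` are integer positions into ``ids`` or -1 for an
    unknown parent.  Construct from raw records with :meth:`from_records`,
    which validates acyclicity and sorts parents before offspring.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._pos:
            self._pos = {a: i for i, a in enumerate(self.ids)}
        if len(self._pos) != len(self.ids):
            raise PedigreeError("duplicate animal ids in pedigree")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def founders(self) -> list:
        return [a for a, s, d in zip(self.ids, self.sire, self.dam) if s < 0 and d < 0]

    def index_of(self, ids: Sequence) -> np.ndarray:
        try:
            return np.array([self._pos[a] for a in ids], dtype=np.int64)
        except KeyError as exc:
            raise PedigreeError(f"id {exc.args[0]!r} not in pedigree") from exc

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build from an iterable of (animal, sire, dam) triplets.

        ``0``, empty string, None and NaN all denote an unknown parent.
        Parents that never appear as animals are added as founders.  Records
        may arrive in any order; a topological sort is applied and cycles
        (an animal that is its own ancestor) are rejected.
        """
        recs = [(a, None if _is_unknown(s) else s, None if _is_unknown(d) else d)
                for a, s, d in records]
        seen = set()
        for a, _, _ in recs:
            if a in seen:
                raise PedigreeError(f"duplicate animal id {a!r}")
            seen.add(a)
        # implicit founders: parents with no own record
        extra = []
        for _, s, d in recs:
            for p in (s, d):
                if p is not None and p not in seen:
                    seen.add(p)
                    extra.append((p, None, None))
        recs = extra + recs

        parent_of = {a: (s, d) for a, s, d in recs}
        order: list = []
        state: dict = {}  # 0 = visiting, 1 = done

        for root in parent_of:
            if root in state:
                continue
            stack = [(root, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    state[node] = 1
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    continue
                if state.get(node) == 0:
                    raise PedigreeError(f"pedigree cycle through id {node!r}")
                state[node] = 0
                stack.append((node, True))
                for p in parent_of[node]:
                    if p is not None and state.get(p) != 1:
                        if state.get(p) == 0:
                            raise PedigreeError(f"pedigree cycle through id {p!r}")
                        stack.append((p, False))

        pos = {a: i for i, a in enumerate(order)}
        sire = np.array([pos[parent_of[a][0]] if parent_of[a][0] is not None else -1
                         for a in order], dtype=np.int64)
        dam = np.array([pos[parent_of[a][1]] if parent_of[a][1] is not None else -1
                        for a in order], dtype=np.int64)
        return cls(ids=order, sire=sire, dam=dam, _pos=pos)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        cols = {c.lower(): c for c in df.columns}
        try:
            triplets = df[[cols["id"], cols["sire"], cols["dam"]]].itertuples(index=False)
        except KeyError as exc:
            raise PedigreeError(f"pedigree file missing column {exc.args[0]!r}") from exc
        return cls.from_records(triplets)

    def to_csv(self, path) -> None:
        out = pd.DataFrame({
            "id": self.ids,
            "sire": [self.ids[s] if s >= 0 else 0 for s in self.sire],
            "dam": [self.ids[d] if d >= 0 else 0 for d in self.dam],
        })
        out.to_csv(path, index=False)

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficient F per animal (topological order).

        Computed as the kinship of each animal's parents via a memoized
        recursion over ancestors (linear memory, unlike the tabular method).
        """
        n = self.n
        F = np.zeros(n)
        sire, dam = self.sire, self.dam
        memo: dict = {}

        def kin(x: int, y: int) -> float:
            if x < 0 or y < 0:
                return 0.0
            if x < y:
                x, y = y, x
            key = (x, y)
            v = memo.get(key)
            if v is not None:
                return v
            if x == y:
                v = 0.5 * (1.0 + F[x])
            else:
                v = 0.5 * (kin(sire[x], y) + kin(dam[x], y))
            memo[key] = v
            return v

        for i in range(n):
            s, d = int(sire[i]), int(dam[i])
            if s >= 0 and d >= 0:
                F[i] = kin(s, d)
        return F


def _tabular_A(ped: Pedigree) -> np.ndarray:
    """Dense A over the full pedigree by the tabular method.

    a_ii = 1 + a(sire,dam)/2 and a_ij = (a_{j,sire(i)} + a_{j,dam(i)})/2 for
    j < i in topological order.  O(n^2) memory, adequate for the pedigree
    sizes this package targets (thousands of animals).
    """
    n = ped.n
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        if i == 0:
            continue
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def build_A(ped: Pedigree, subset: Sequence | None = None) -> "RelationshipMatrix":
    """Numerator relationship matrix restricted to ``subset`` (default all).

    The full matrix is computed recursively over the whole pedigree (the
    relationship between two late-generation animals flows through their
    ancestors), then the requested block is returned.
    """
    from .preprocess import RelationshipMatrix

    A = _tabular_A(ped)
    if subset is None:
        ids = list(ped.ids)
    else:
        idx = ped.index_of(subset)
        A = A[np.ix_(idx, idx)]
        ids = list(subset)
    return RelationshipMatrix(ids=ids, matrix=A, kind="pedigree")


def build_A_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse A^-1 over the full pedigree by Henderson's rules.

    Mendelian-sampling variances are corrected for parental inbreeding:
    d_i = 1 - 0.25*(1+F_s) - 0.25*(1+F_d) with a known parent's term
    replacing 0.25*(1+F) by 0 when that parent is unknown.  The product
    with :func:`build_A` over the same ids is the identity.
    """
    F = ped.inbreeding()
    n = ped.n
    rows, cols, vals = [], [], []
    for i in range(n):
        si, di = ped.sire[i], ped.dam[i]
        d = 1.0
        parents = []
        if si >= 0:
            d -= 0.25 * (1.0 + F[si])
            parents.append(si)
        if di >= 0:
            d -= 0.25 * (1.0 + F[di])
            parents.append(di)
        w = 1.0 / d
        rows.append(i); cols.append(i); vals.append(w)
        for p in parents:
            rows += [i, p]; cols += [p, i]; vals += [-0.5 * w, -0.5 * w]
        for p in parents:
            for q in parents:
                rows.append(p); cols.append(q); vals.append(0.25 * w)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return Ainv
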