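"""OTU count preprocessing: rarefaction, prevalence filtering, the
standardized log-abundance design Z3, and the microbial relationship matrix.

Pipeline order (fixed): rarefy to a common depth, discarding samples with
fewer total reads -> drop OTU whose prevalence is not strictly above the
threshold -> add a +1 pseudocount -> relative abundances P -> column-wise
z-scores of log(P) -> M = Z3 Z3' / k.

The column standard deviation uses the sample (n-1) denominator, which gives
trace(M) = n - 1 exactly.  Because every sample has the same total after
rarefaction, standardizing log(count + 1) and standardizing log(P) produce
the identical Z3 (the per-sample total is a constant shift on the log scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OtuCountTable",
    "AbundanceDesign",
    "RelationshipMatrix",
    "PreprocessError",
    "rarefy",
    "prevalence_filter",
    "log_standardize",
    "build_microbial_relationship",
    "preprocess_counts",
    "relationship_inverse",
]


class PreprocessError(ValueError):
    pass


@dataclass
class OtuCountTable:
    """Integer count matrix, samples in rows, OTU in columns."""

    sample_ids: list
    otu_ids: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise PreprocessError("counts shape does not match id lists")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise PreprocessError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise PreprocessError("duplicate OTU ids")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise PreprocessError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise PreprocessError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otu(self) -> int:
        return len(self.otu_ids)

    def depths(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @classmethod
    def from_tsv(cls, path) -> "OtuCountTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(sample_ids=list(df.index.astype(str)),
                   otu_ids=list(df.columns.astype(str)),
                   counts=df.to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.counts, index=self.sample_ids,
                     columns=self.otu_ids).to_csv(path, sep="\t", index_label="sample")


@dataclass
class AbundanceDesign:
    """Standardized log-abundance matrix Z3 (n samples x k OTU).

    Columns are exactly centered and have unit sample standard deviation.
    """

    sample_ids: list
    otu_ids: list
    z3: np.ndarray

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def k(self) -> int:
        return len(self.otu_ids)

    def subset_samples(self, ids: Sequence) -> "AbundanceDesign":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return AbundanceDesign(list(ids), list(self.otu_ids), self.z3[idx])


@dataclass
class RelationshipMatrix:
    """Covariance structure among animals: pedigree (A) or microbial (M)."""

    ids: list
    matrix: np.ndarray
    kind: str = "microbial"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise PreprocessError("relationship matrix shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise PreprocessError("relationship matrix not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence) -> "RelationshipMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return RelationshipMatrix(list(ids), self.matrix[np.ix_(idx, idx)], self.kind)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path, kind: str = "microbial") -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=list(df.index.astype(str)), matrix=df.to_numpy(), kind=kind)


def rarefy(table: OtuCountTable, depth: int, seed: int) -> tuple[OtuCountTable, list]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are removed and returned in the
    discard list.  A sample at exactly ``depth`` is kept unchanged.  Each
    retained sample gets one independent multivariate-hypergeometric draw
    (equivalent to expanding the reads and subsampling) from a generator
    seeded by ``seed``.
    """
    if depth <= 0:
        raise PreprocessError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.depths()
    keep = totals >= depth
    discarded = [s for s, k in zip(table.sample_ids, keep) if not k]
    rows = []
    for i in np.flatnonzero(keep):
        c = table.counts[i]
        if totals[i] == depth:
            rows.append(c.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(c, depth))
    counts = np.array(rows, dtype=np.int64) if rows else np.zeros((0, table.n_otu), np.int64)
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    return OtuCountTable(kept_ids, list(table.otu_ids), counts), discarded


def prevalence_filter(table: OtuCountTable, min_nonzero_frac: float = 0.01) -> OtuCountTable:
    """Keep OTU present (count > 0) in strictly more than ``min_nonzero_frac``
    of the samples; the sample set is unchanged."""
    if not 0 <= min_nonzero_frac < 1:
        raise PreprocessError("min_nonzero_frac must be in [0, 1)")
    prev = (table.counts > 0).mean(axis=0)
    keep = prev > min_nonzero_frac
    if not keep.any():
        raise PreprocessError("no OTU pass the prevalence filter")
    return OtuCountTable(list(table.sample_ids),
                         [o for o, k in zip(table.otu_ids, keep) if k],
                         table.counts[:, keep])


def log_standardize(table: OtuCountTable) -> AbundanceDesign:
    """Pseudocount, relative abundance, and column z-scores of log P.

    P_ij = (c_ij + 1) / sum_j (c_ij + 1); each column of log P is centered
    and divided by its sample (n-1) standard deviation.  A zero-variance
    column is an error (the offending OTU is named, not dropped).
    """
    c = table.counts + 1
    P = c / c.sum(axis=1, keepdims=True)
    logp = np.log(P)
    mu = logp.mean(axis=0)
    sd = logp.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        names = [table.otu_ids[j] for j in bad[:5]]
        raise PreprocessError(
            f"zero log-abundance variance for OTU {names}"
            + ("..." if bad.size > 5 else ""))
    z3 = (logp - mu) / sd
    return AbundanceDesign(list(table.sample_ids), list(table.otu_ids), z3)


def build_microbial_relationship(design: AbundanceDesign) -> RelationshipMatrix:
    """M = Z3 Z3' / k.

    Symmetric PSD with zero row sums (columns of Z3 are centered) and
    trace n - 1 under the sample-sd convention.
    """
    if design.k < 2:
        raise PreprocessError("need at least 2 OTU to build M")
    M = design.z3 @ design.z3.T / design.k
    M = (M + M.T) / 2.0
    return RelationshipMatrix(list(design.sample_ids), M, kind="microbial")


def preprocess_counts(table: OtuCountTable, depth: int = 9000,
                      min_prevalence: float = 0.01, seed: int = 0):
    """Full pipeline: rarefy -> prevalence filter -> Z3 -> M.

    Returns (design, M, discarded_samples).
    """
    rare, discarded = rarefy(table, depth, seed)
    filt = prevalence_filter(rare, min_prevalence)
    design = log_standardize(filt)
    M = build_microbial_relationship(design)
    return design, M, discarded


def relationship_inverse(K: RelationshipMatrix | np.ndarray,
                         method: str = "ridge",
                         ridge_tol: float = 1e-8,
                         ridge: float = 1e-6) -> np.ndarray:
    """Inverse of a relationship matrix.

    M = Z3 Z3'/k is always singular (centering of the Z3 columns puts the
    all-ones vector in its null space), so a plain inverse does not exist.

    ``method="ridge"``: if the minimum eigenvalue falls below ``ridge_tol``
    times the mean diagonal, ``ridge`` times the mean diagonal is added to
    the diagonal before inverting.  Used inside the mixed-model equations,
    where the null direction must stay penalized to keep the system
    non-singular alongside an intercept.

    ``method="pinv"``: eigendecomposition pseudo-inverse (eigenvalues below
    ``ridge_tol`` x mean diagonal dropped).  Used for back-solving, where it
    makes the reconstruction Z3 @ OTU_hat = m_hat exact for m_hat in the
    column space of Z3.
    """
    A = K.matrix if isinstance(K, RelationshipMatrix) else np.asarray(K, float)
    mean_diag = float(np.mean(np.diag(A)))
    if method == "pinv":
        w, Q = np.linalg.eigh(A)
        keep = w > ridge_tol * mean_diag
        return (Q[:, keep] / w[keep]) @ Q[:, keep].T
    if method != "ridge":
        raise ValueError(f"unknown method {method!r}")
    w = np.linalg.eigvalsh(A)
    if w.min() < ridge_tol * mean_diag:
        A = A + ridge * mean_diag * np.eye(A.shape[0])
    return np.linalg.inv(A)
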