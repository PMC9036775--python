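"""Microbiome-wide association: single-OTU regression and BLUP back-solving.

Two routes to per-OTU effects on a trait:

* **single-OTU regression** — the animal model (fixed effects + breeding
  values) with one standardized OTU column added as a fixed covariate; the
  estimate and its standard error from the inverse coefficient matrix give
  a Z-score and a chi-square(1 df) p-value.

* **back-solving** — the aggregate microbial values m_hat from the full
  model are mapped back to per-OTU effects under the equal-variance
  assumption var(OTU_j) = sigma2_m / k:

      OTU_hat = (1/k) Z3' M^-1 m_hat,
      var(OTU_hat) = (1/k^2) Z3' M^-1 (M sigma2_m - C^mm sigma2_e) M^-1 Z3,

  with C^mm the microbial block of the inverted mixed-model equations
  (PEV(m_hat) = C^mm sigma2_e).

Multiple testing uses the effective number of independent tests from the
eigenvalues of the OTU correlation matrix: m_eff is the smallest number of
top eigenvalues whose sum reaches a target fraction (default 99.5%) of the
total, and the family-wise thresholds are -log10(alpha / m_eff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .mixed_models import FitError, ModelSpec, build_mme
from .preprocess import AbundanceDesign, RelationshipMatrix, relationship_inverse

__all__ = ["MwasResult", "SignificanceThresholds", "single_otu_regression",
           "mwas_single_regression", "backsolve_effects", "backsolve_variances",
           "backsolve_pvalues", "mwas_backsolve", "gao_effective_tests"]


@dataclass
class SignificanceThresholds:
    m_eff: int
    threshold_5: float
    threshold_10: float
    variance_captured: float
    eigenvalues: np.ndarray

    @classmethod
    def from_m_eff(cls, m_eff: int, capture: float = 0.995,
                   eigenvalues: Optional[np.ndarray] = None):
        return cls(m_eff=int(m_eff),
                   threshold_5=float(-np.log10(0.05 / m_eff)),
                   threshold_10=float(-np.log10(0.10 / m_eff)),
                   variance_captured=capture,
                   eigenvalues=eigenvalues if eigenvalues is not None
                   else np.array([]))


def _result_frame(otu_ids, effects, ses, method, aliased=None) -> pd.DataFrame:
    effects = np.asarray(effects, float)
    ses = np.asarray(ses, float)
    ok = ses > 0
    z = np.zeros_like(effects)
    z[ok] = effects[ok] / ses[ok]
    p = np.ones_like(effects)
    p[ok] = stats.chi2.sf(z[ok] ** 2, df=1)
    df = pd.DataFrame({
        "otu_id": list(otu_ids),
        "effect": effects,
        "se": ses,
        "z_score": z,
        "p_value": p,
        "neg_log10_p": -np.log10(np.maximum(p, np.finfo(float).tiny)),
        "method": method,
    })
    df["flag"] = ""
    if aliased is not None and len(aliased):
        df.loc[df.index[aliased], "flag"] = "aliased"
        df.loc[df.index[aliased], "p_value"] = 1.0
        df.loc[df.index[aliased], "neg_log10_p"] = 0.0
    df.loc[~ok & (df["flag"] == ""), "flag"] = "zero_variance"
    return df


class MwasResult(pd.DataFrame):
    """Per-OTU effect/SE/Z/p table (a plain DataFrame subclass)."""

    @property
    def _constructor(self):
        return MwasResult


def single_otu_regression(trait: str, otu_index: int, phenotypes: pd.DataFrame,
                          A: RelationshipMatrix, design: AbundanceDesign,
                          variances: dict, fixed_effects: Sequence[str] = ()
                          ) -> pd.Series:
    """One OTU tested as a fixed covariate in the animal model."""
    res = mwas_single_regression(trait, phenotypes, A, design, variances,
                                 fixed_effects=fixed_effects,
                                 otu_indices=[otu_index])
    return res.iloc[0]


def mwas_single_regression(trait: str, phenotypes: pd.DataFrame,
                           A: RelationshipMatrix, design: AbundanceDesign,
                           variances: dict, fixed_effects: Sequence[str] = (),
                           otu_indices: Optional[Sequence[int]] = None,
                           refit_variances: bool = False,
                           max_em_iter: int = 50) -> MwasResult:
    """Single-OTU regression scan: y = Xb + beta * z3_j + Z1 a + e.

    The base animal-model system (without the covariate) is factorized once
    and each OTU enters through a rank-one Schur complement, so a scan costs
    one O(n^2) solve per OTU.  Variance components are plug-in values (e.g.
    posterior means of the genetic model); ``refit_variances`` re-estimates
    sigma2_a/sigma2_e per OTU by EM-REML instead.
    """
    spec = ModelSpec(traits=[trait], include_genetic=True,
                     include_microbiome=False, fixed_effects=fixed_effects)
    mme = build_mme(spec, phenotypes, A, None, variances)
    data = mme.data
    y = data["y"]
    ids = data["pheno"]["id"]
    dpos = {s: i for i, s in enumerate(design.sample_ids)}
    try:
        rows = np.array([dpos[i] for i in ids])
    except KeyError as exc:
        raise FitError(f"animal {exc.args[0]!r} has no abundance data") from exc
    Zobs = design.z3[rows, :]  # n_obs x k, standardized columns

    if otu_indices is None:
        otu_indices = range(design.k)
    otu_indices = list(otu_indices)

    fac = linalg.cho_factor(mme.C)
    theta0 = linalg.cho_solve(fac, mme.rhs)
    W_t = np.vstack([mme.X.T, _z1_dense(data, mme).T])  # (p + n_ped) x n_obs

    effects, ses, aliased = [], [], []
    for j in otu_indices:
        zj = Zobs[:, j]
        if refit_variances:
            eff, se, alias = _single_otu_reml(mme, zj, y, variances, max_em_iter)
        else:
            v = W_t @ zj
            w = linalg.cho_solve(fac, v)
            s = zj @ zj - v @ w
            scale = zj @ zj
            if s <= 1e-10 * max(scale, 1.0):
                eff, se, alias = 0.0, 0.0, True
            else:
                eff = (zj @ y - v @ theta0) / s
                se = np.sqrt(variances["sigma2_e"] / s)
                alias = False
        effects.append(eff)
        ses.append(se)
        if alias:
            aliased.append(len(effects) - 1)
    otu_ids = [design.otu_ids[j] for j in otu_indices]
    return MwasResult(_result_frame(otu_ids, effects, ses, "single_regression",
                                    aliased=np.array(aliased, dtype=int)))


def _z1_dense(data, mme) -> np.ndarray:
    n_obs = len(data["pheno"])
    n_ped = data["A"].n
    Z1 = np.zeros((n_obs, n_ped))
    Z1[np.arange(n_obs), data["z1"]] = 1.0
    return Z1


def _single_otu_reml(mme, zj, y, variances, max_iter):
    """EM-REML re-estimation of (sigma2_a, sigma2_e) with the OTU covariate
    in the model; returns the covariate estimate at convergence."""
    data = mme.data
    X = np.column_stack([mme.X, zj])
    Z1 = _z1_dense(data, mme)
    n_ped = data["A"].n
    Ainv = np.linalg.inv(data["A"].matrix + 1e-10 * np.eye(n_ped))
    n_obs, p = X.shape
    sig2a = float(variances["sigma2_a"])
    sig2e = float(variances["sigma2_e"])
    W = np.hstack([X, Z1])
    WtW = W.T @ W
    Wty = W.T @ y
    for _ in range(max_iter):
        C = WtW.copy()
        C[p:, p:] += Ainv * (sig2e / sig2a)
        try:
            fac = linalg.cho_factor(C)
        except linalg.LinAlgError:
            return 0.0, 0.0, True
        theta = linalg.cho_solve(fac, Wty)
        Cinv = linalg.cho_solve(fac, np.eye(C.shape[0]))
        a = theta[p:]
        new_a = (a @ Ainv @ a + np.trace(Ainv @ Cinv[p:, p:]) * sig2e) / n_ped
        e = y - W @ theta
        new_e = (e @ y) / (n_obs - p)
        if abs(new_a - sig2a) < 1e-8 and abs(new_e - sig2e) < 1e-8:
            sig2a, sig2e = new_a, new_e
            break
        sig2a, sig2e = max(new_a, 1e-12), max(new_e, 1e-12)
    C = WtW.copy()
    C[p:, p:] += Ainv * (sig2e / sig2a)
    fac = linalg.cho_factor(C)
    theta = linalg.cho_solve(fac, Wty)
    Cinv = linalg.cho_solve(fac, np.eye(C.shape[0]))
    eff = theta[p - 1]
    se = np.sqrt(Cinv[p - 1, p - 1] * sig2e)
    return float(eff), float(se), False


# ---------------------------------------------------------------------------
# back-solving


def backsolve_effects(m_hat, design: AbundanceDesign,
                      M: RelationshipMatrix) -> np.ndarray:
    """OTU_hat = (1/k) Z3' M^-1 m_hat.

    When m_hat lies in the column space of Z3 (which it does, because
    M = Z3 Z3'/k), reconstructing Z3 @ OTU_hat recovers m_hat.
    """
    m_hat = np.asarray(m_hat, float)
    if m_hat.shape[0] != design.n:
        raise FitError("m_hat length does not match the abundance design")
    Minv = relationship_inverse(M, method="pinv")
    return design.z3.T @ (Minv @ m_hat) / design.k


def backsolve_variances(design: AbundanceDesign, M: RelationshipMatrix,
                        C_mm: np.ndarray, sigma2_m: float, sigma2_e: float
                        ) -> np.ndarray:
    """Diagonal of var(OTU_hat) = (1/k^2) Z3' M^-1 (M s2m - C^mm s2e) M^-1 Z3.

    C_mm must be the microbial block of the inverted MME coefficient matrix
    computed at the same (sigma2_m, sigma2_e).  Marginally negative entries
    (within numerical tolerance) are clipped to zero with a warning.
    """
    C_mm = np.asarray(C_mm, float)
    if C_mm.shape != (design.n, design.n):
        raise FitError("C_mm must be the n x n microbial block")
    Minv = relationship_inverse(M, method="pinv")
    mid = M.matrix * sigma2_m - C_mm * sigma2_e
    B = Minv @ design.z3  # n x k
    var = np.einsum("ij,ij->j", B, mid @ B) / design.k ** 2
    neg = var < 0
    if neg.any():
        if var.min() < -1e-8 * max(abs(var).max(), 1.0):
            raise FitError(f"negative back-solved variance {var.min():.3e}; "
                           "inconsistent variance inputs for C_mm")
        warnings.warn(f"{int(neg.sum())} marginally negative back-solved "
                      "variances clipped to 0")
        var = np.clip(var, 0.0, None)
    return var


def backsolve_pvalues(effects, variances, otu_ids=None) -> MwasResult:
    """Z = effect / sqrt(var), p from the chi-square(1) upper tail at Z^2."""
    effects = np.asarray(effects, float)
    variances = np.asarray(variances, float)
    if effects.shape != variances.shape:
        raise FitError("effects and variances must have matching lengths")
    if (variances < 0).any():
        raise FitError("negative variance passed to backsolve_pvalues")
    if otu_ids is None:
        otu_ids = [f"OTU{j}" for j in range(len(effects))]
    return MwasResult(_result_frame(otu_ids, effects, np.sqrt(variances),
                                    "backsolve"))


def mwas_backsolve(trait: str, phenotypes: pd.DataFrame,
                   A: Optional[RelationshipMatrix], M: RelationshipMatrix,
                   design: AbundanceDesign, variances: dict,
                   fixed_effects: Sequence[str] = ()) -> MwasResult:
    """Full back-solving pipeline from phenotypes to per-OTU p-values.

    Solves the full model's MME at the supplied variance components (the
    genetic term is included when ``A`` is given and sigma2_a > 0), extracts
    m_hat and C^mm, and back-solves effects, variances and p-values.
    """
    from .mixed_models import blup_solve
    include_genetic = A is not None and variances.get("sigma2_a", 0) > 0
    spec = ModelSpec(traits=[trait], include_genetic=include_genetic,
                     include_microbiome=True, fixed_effects=fixed_effects)
    sol = blup_solve(spec, phenotypes, A, M, variances, compute_cmm=True)
    m_hat = sol.m.reindex(design.sample_ids).to_numpy(float)
    effects = backsolve_effects(m_hat, design, M)
    var = backsolve_variances(design, M, sol.cmm, variances["sigma2_m"],
                              variances["sigma2_e"])
    return backsolve_pvalues(effects, var, otu_ids=design.otu_ids)


def gao_effective_tests(design: AbundanceDesign, capture: float = 0.995
                        ) -> SignificanceThresholds:
    """Effective number of independent tests from OTU correlation eigenvalues.

    Eigendecomposes the k x k correlation matrix of the standardized columns
    (computed through the smaller Gram side when k > n), takes the smallest
    m_eff with cumulative eigenvalue mass >= capture * k, and converts it to
    family-wise -log10 thresholds at 5% and 10%.  m_eff is invariant to
    whether the Gram matrix is scaled by n or n-1.
    """
    if design.k < 2:
        raise FitError("need at least 2 OTU")
    if not 0 < capture < 1:
        raise FitError("capture must be in (0, 1)")
    Z = design.z3
    n, k = Z.shape
    if not np.all(np.isfinite(Z)):
        raise FitError("non-finite values in the abundance design "
                       "(zero-variance OTU column?)")
    denom = n - 1
    if k <= n:
        gram = Z.T @ Z / denom
    else:
        gram = Z @ Z.T / denom
    ev = np.linalg.eigvalsh(gram)[::-1]
    ev = np.clip(ev, 0, None)
    total = float(ev.sum())  # == trace of the correlation matrix == k
    cum = np.cumsum(ev)
    m_eff = int(np.searchsorted(cum, capture * total) + 1)
    m_eff = min(m_eff, k)
    full = np.zeros(k)
    full[:len(ev)] = ev
    return SignificanceThresholds.from_m_eff(m_eff, capture=capture,
                                             eigenvalues=full)
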