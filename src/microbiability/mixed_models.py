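"""Animal mixed models with genetic and microbial random effects.

Four nested univariate models for a trait y:

    (1) y = Xb + e
    (2) y = Xb + Z2 m + e
    (3) y = Xb + Z1 a + e
    (4) y = Xb + Z1 a + Z2 m + e

with a ~ N(0, A sigma2_a) over the pedigree, m ~ N(0, M sigma2_m) over the
animals with microbiome data, and e ~ N(0, I sigma2_e).  Variance
components come from a blocked Gibbs sampler (scaled inverse chi-square /
inverse-Wishart full conditionals); BLUP solutions at fixed variances come
from Henderson's mixed model equations.  Bivariate versions of Models
(2)-(4) replace the scalar variances by 2x2 (co)variance matrices G0, R_m,
R_e with Kronecker covariance structure.

Location parameters are sampled exactly from their joint full conditionals.
The sampler hoists one-off factorizations out of the chain: a = L Q alpha
with L = chol(A) and Q the eigenbasis of L' Z1'Z1 L, and m expressed in the
rank-retaining eigenbasis of M rotated to diagonalize the data term.  In
these coordinates every conditional precision is diagonal (univariate) or
2x2-block-diagonal (bivariate), so one iteration costs a few matrix-vector
products.  The quadratic forms a'A^-1 a and m'M^+ m needed by the variance
updates reduce to alpha'alpha and beta'beta in the same coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .preprocess import RelationshipMatrix, relationship_inverse

__all__ = ["ModelSpec", "GibbsConfig", "PosteriorSummary", "MmeSystem",
           "BlupSolution", "build_mme", "gibbs_fit", "compute_dic",
           "blup_solve", "adjusted_phenotype_correlations", "FitError"]


class FitError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Which random terms a model includes, and its fixed-effect factors.

    Model numbers: (1) neither random term, (2) microbiome only,
    (3) genetic only, (4) both.
    """

    traits: Sequence[str]
    include_genetic: bool
    include_microbiome: bool
    fixed_effects: Sequence[str] = ()
    intercept: bool = True

    def __post_init__(self):
        self.traits = list(self.traits)
        if len(self.traits) not in (1, 2):
            raise ValueError("one or two traits required")
        self.fixed_effects = list(self.fixed_effects)

    @classmethod
    def from_model_number(cls, number: int, traits, fixed_effects=()):
        mapping = {1: (False, False), 2: (False, True),
                   3: (True, False), 4: (True, True)}
        if number not in mapping:
            raise ValueError("model number must be 1-4")
        g, m = mapping[number]
        t = [traits] if isinstance(traits, str) else list(traits)
        return cls(traits=t, include_genetic=g, include_microbiome=m,
                   fixed_effects=fixed_effects)

    @property
    def model_number(self) -> int:
        return {(False, False): 1, (False, True): 2,
                (True, False): 3, (True, True): 4}[
                    (self.include_genetic, self.include_microbiome)]

    @property
    def bivariate(self) -> bool:
        return len(self.traits) == 2


@dataclass
class GibbsConfig:
    """Chain settings.  Defaults are desk-scale (20,000 iterations, 4,000
    burn-in, thin 10); a study-scale run uses 100,000 / 15,000 / 10."""

    n_iter: int = 20000
    burn_in: int = 4000
    thin: int = 10
    seed: int = 0
    prior_df: float = -2.0     # scaled inverse chi-square prior df (flat)
    prior_scale: float = 0.0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior means/SDs, DIC, solutions and diagnostics from one fit."""

    means: dict
    sds: dict
    dic: float
    pd_eff: float
    n_retained: int
    chains: pd.DataFrame
    solutions: dict
    diagnostics: dict
    flags: dict = field(default_factory=dict)

    def __getattr__(self, name):
        means = object.__getattribute__(self, "means")
        if name in means:
            return means[name]
        raise AttributeError(name)

    def sd(self, name: str) -> float:
        return self.sds[name]


# ---------------------------------------------------------------------------
# data assembly


def _design_fixed(pheno: pd.DataFrame, spec: ModelSpec):
    """Full-rank fixed-effect design: intercept + drop-first dummies.

    Aliased columns (rank deficiencies, e.g. confounded factors) are dropped
    with a warning naming them.
    """
    cols, names = [], []
    n = len(pheno)
    if spec.intercept:
        cols.append(np.ones(n))
        names.append("intercept")
    for f in spec.fixed_effects:
        if f not in pheno.columns:
            raise FitError(f"fixed effect column {f!r} missing from phenotypes")
        d = pd.get_dummies(pheno[f].astype(str), prefix=f, drop_first=spec.intercept)
        for c in d.columns:
            cols.append(d[c].to_numpy(float))
            names.append(c)
    if not cols:
        return np.zeros((n, 0)), []
    X = np.column_stack(cols)
    # rank check via pivoted QR
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0
    keep_piv = piv[diag > tol]
    if len(keep_piv) < X.shape[1]:
        dropped = [names[j] for j in piv[diag <= tol]]
        warnings.warn(f"aliased fixed-effect columns dropped: {dropped}")
        keep_piv = np.sort(keep_piv)
        X = X[:, keep_piv]
        names = [names[j] for j in keep_piv]
    return X, names


def _assemble(spec: ModelSpec, phenotypes: pd.DataFrame,
              A: Optional[RelationshipMatrix], M: Optional[RelationshipMatrix]):
    if "id" not in phenotypes.columns:
        raise FitError("phenotype table needs an 'id' column")
    for t in spec.traits:
        if t not in phenotypes.columns:
            raise FitError(f"trait column {t!r} missing from phenotypes")
    vals = phenotypes[spec.traits].to_numpy(float)
    mask = np.isfinite(vals).all(axis=1)
    pheno = phenotypes.loc[mask].reset_index(drop=True)
    if len(pheno) == 0:
        raise FitError("no records with observed trait values")
    y = pheno[spec.traits].to_numpy(float)
    X, xnames = _design_fixed(pheno, spec)
    out = {"pheno": pheno, "y": y[:, 0] if not spec.bivariate else y,
           "X": X, "xnames": xnames, "ids": list(pheno["id"])}
    if spec.include_genetic:
        if A is None:
            raise FitError("model includes genetic term but A not supplied")
        pos = {a: i for i, a in enumerate(A.ids)}
        try:
            out["z1"] = np.array([pos[i] for i in pheno["id"]])
        except KeyError as exc:
            raise FitError(f"animal {exc.args[0]!r} not in A") from exc
        out["A"] = A
    if spec.include_microbiome:
        if M is None:
            raise FitError("model includes microbial term but M not supplied")
        pos = {a: i for i, a in enumerate(M.ids)}
        try:
            out["z2"] = np.array([pos[i] for i in pheno["id"]])
        except KeyError as exc:
            raise FitError(f"animal {exc.args[0]!r} not in M") from exc
        out["M"] = M
    return out


def _genetic_basis(A: RelationshipMatrix, z1: np.ndarray):
    """T = L Q with L = chol(A), Q eigenbasis of L' Z1'Z1 L.

    Then a = T alpha has prior alpha ~ N(0, sigma2_a I), a'A^-1 a =
    alpha'alpha, and the data Gram matrix (Z1 T)'(Z1 T) is diag(w).
    """
    n_ped = A.n
    La = linalg.cholesky(A.matrix + 1e-10 * np.eye(n_ped), lower=True)
    d = np.bincount(z1, minlength=n_ped).astype(float)
    S = La.T @ (La * d[:, None])
    w, Q = linalg.eigh((S + S.T) / 2)
    w = np.clip(w, 0, None)
    T = La @ Q
    G = T[z1, :]
    return T, G, w


def _microbial_basis(M: RelationshipMatrix, z2: np.ndarray):
    """Rank-retaining basis of M rotated against the observation pattern.

    m = T beta with prior beta ~ N(0, sigma2_m I_r), r = rank(M),
    m'M^+ m = beta'beta, and (Z2 T)'(Z2 T) = diag(v).
    """
    s, Qm = linalg.eigh(M.matrix)
    keep = s > 1e-10 * max(s.max(), 1.0)
    r = int(keep.sum())
    if r == 0:
        raise FitError("microbial relationship matrix has rank 0")
    B = Qm[:, keep] * np.sqrt(s[keep])
    Bobs = B[z2, :]
    S2 = Bobs.T @ Bobs
    v, R = linalg.eigh((S2 + S2.T) / 2)
    v = np.clip(v, 0, None)
    T = B @ R
    G = Bobs @ R
    return T, G, v


def _scaled_inv_chi2(rng, ss: float, df: float) -> float:
    if df <= 0:
        raise FitError(f"variance full conditional has df {df} <= 0; "
                       "increase prior_df or sample size")
    return ss / rng.chisquare(df)


def _inv_wishart_2x2(rng, S: np.ndarray, df: float) -> np.ndarray:
    """One draw from IW(df, S) for 2x2 S via the Bartlett decomposition."""
    if df <= 1:
        raise FitError(f"inverse-Wishart df {df} <= p - 1")
    Sinv = np.linalg.inv(S)
    Lv = np.linalg.cholesky(Sinv)
    Ab = np.zeros((2, 2))
    Ab[0, 0] = np.sqrt(rng.chisquare(df))
    Ab[1, 1] = np.sqrt(rng.chisquare(df - 1))
    Ab[1, 0] = rng.standard_normal()
    W = Lv @ Ab
    X = W @ W.T
    return np.linalg.inv(X)


def _split_rhat(x: np.ndarray) -> float:
    """Potential scale reduction from the two halves of a single chain."""
    n = len(x) // 2
    if n < 2:
        return np.nan
    a, b = x[:n], x[n:2 * n]
    W = (a.var(ddof=1) + b.var(ddof=1)) / 2
    B = n * np.var([a.mean(), b.mean()], ddof=1)
    if W <= 0:
        return np.nan
    return float(np.sqrt((n - 1) / n + B / (n * W)))


def _ess(x: np.ndarray) -> float:
    """Effective sample size via initial-positive-sequence autocorrelation."""
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * xc.var())
    s = 0.0
    for t in range(1, n):
        if acf[t] < 0:
            break
        s += acf[t]
    return float(n / (1 + 2 * s))


def compute_dic(deviance_samples: np.ndarray, deviance_at_mean: float
                ) -> tuple[float, float]:
    """DIC = Dbar + pD with pD = Dbar - D(posterior means).

    ``deviance_samples`` holds the conditional (location-given) deviance at
    each retained draw; ``deviance_at_mean`` is the deviance evaluated at
    posterior-mean locations and residual variance.
    """
    d = np.asarray(deviance_samples, float)
    if d.size == 0:
        raise FitError("empty chain")
    dbar = float(d.mean())
    p_d = dbar - float(deviance_at_mean)
    return dbar + p_d, p_d


# ---------------------------------------------------------------------------
# univariate Gibbs


def _gibbs_univariate(spec, data, config: GibbsConfig) -> PosteriorSummary:
    rng = np.random.default_rng(config.seed)
    y = data["y"]
    X = data["X"]
    n_obs, p = X.shape
    nu0, s0 = config.prior_df, config.prior_scale

    use_a, use_m = spec.include_genetic, spec.include_microbiome
    if p:
        XtX = X.T @ X
        Lx = linalg.cholesky(XtX + 1e-12 * np.trace(XtX) / p * np.eye(p), lower=True)
    if use_a:
        Ta, Ga, wa = _genetic_basis(data["A"], data["z1"])
        n_ped = Ta.shape[1]
    if use_m:
        Tm, Gm, vm = _microbial_basis(data["M"], data["z2"])
        r_m = Tm.shape[1]

    vy = max(np.var(y), 1e-12)
    sig2e = vy / 2
    sig2a = vy / 4 if use_a else 0.0
    sig2m = vy / 4 if use_m else 0.0
    b = np.zeros(p)
    alpha = np.zeros(n_ped) if use_a else None
    beta = np.zeros(r_m) if use_m else None
    fa = np.zeros(n_obs)
    fm = np.zeros(n_obs)
    xb = np.zeros(n_obs)

    rec = {k: [] for k in ("sigma2_a", "sigma2_m", "sigma2_e", "h2", "m2",
                           "deviance")}
    n_keep = 0
    b_sum = np.zeros(p)
    alpha_sum = np.zeros(n_ped) if use_a else None
    beta_sum = np.zeros(r_m) if use_m else None
    fit_sum = np.zeros(n_obs)

    for it in range(config.n_iter):
        if p:
            resid = y - fa - fm
            mean_b = linalg.cho_solve((Lx, True), X.T @ resid)
            b = mean_b + linalg.solve_triangular(
                Lx.T, rng.standard_normal(p)) * np.sqrt(sig2e)
            xb = X @ b
        if use_a:
            u = Ga.T @ (y - xb - fm)
            d = wa + sig2e / sig2a
            alpha = u / d + rng.standard_normal(n_ped) * np.sqrt(sig2e / d)
            fa = Ga @ alpha
        if use_m:
            u = Gm.T @ (y - xb - fa)
            d = vm + sig2e / sig2m
            beta = u / d + rng.standard_normal(r_m) * np.sqrt(sig2e / d)
            fm = Gm @ beta
        e = y - xb - fa - fm
        sig2e = _scaled_inv_chi2(rng, e @ e + nu0 * s0, n_obs + nu0)
        if use_a:
            sig2a = _scaled_inv_chi2(rng, alpha @ alpha + nu0 * s0, n_ped + nu0)
        if use_m:
            sig2m = _scaled_inv_chi2(rng, beta @ beta + nu0 * s0, r_m + nu0)
        if not np.isfinite(sig2e) or (use_a and not np.isfinite(sig2a)) \
                or (use_m and not np.isfinite(sig2m)):
            raise FitError(f"divergent chain at iteration {it}: "
                           f"sigma2=({sig2a}, {sig2m}, {sig2e})")

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            tot = sig2e + (sig2a if use_a else 0) + (sig2m if use_m else 0)
            rec["sigma2_a"].append(sig2a)
            rec["sigma2_m"].append(sig2m)
            rec["sigma2_e"].append(sig2e)
            rec["h2"].append(sig2a / tot if use_a else 0.0)
            rec["m2"].append(sig2m / tot if use_m else 0.0)
            fit = xb + fa + fm
            rec["deviance"].append(n_obs * np.log(2 * np.pi * sig2e)
                                   + (e @ e) / sig2e)
            n_keep += 1
            b_sum += b
            if use_a:
                alpha_sum += alpha
            if use_m:
                beta_sum += beta
            fit_sum += fit

    chains = pd.DataFrame(rec)
    means = {k: float(chains[k].mean()) for k in
             ("sigma2_a", "sigma2_m", "sigma2_e", "h2", "m2")}
    means["sigma2_p"] = means["sigma2_e"] + means["sigma2_a"] + means["sigma2_m"]
    sds = {k: float(chains[k].std(ddof=1)) if n_keep > 1 else 0.0
           for k in ("sigma2_a", "sigma2_m", "sigma2_e", "h2", "m2")}

    fit_bar = fit_sum / n_keep
    sig2e_bar = means["sigma2_e"]
    dev_at_mean = n_obs * np.log(2 * np.pi * sig2e_bar) \
        + float(((y - fit_bar) ** 2).sum()) / sig2e_bar
    dic, p_eff = compute_dic(chains["deviance"].to_numpy(), dev_at_mean)

    solutions = {"b": pd.Series(b_sum / n_keep, index=data["xnames"])}
    if use_a:
        a_hat = Ta @ (alpha_sum / n_keep)
        solutions["a"] = pd.Series(a_hat, index=data["A"].ids)
    if use_m:
        m_hat = Tm @ (beta_sum / n_keep)
        solutions["m"] = pd.Series(m_hat, index=data["M"].ids)

    watch = [k for k, on in (("sigma2_e", True), ("sigma2_a", use_a),
                             ("sigma2_m", use_m)) if on]
    diagnostics = {"rhat": {k: _split_rhat(chains[k].to_numpy()) for k in watch},
                   "ess": {k: _ess(chains[k].to_numpy()) for k in watch}}
    for k, v in diagnostics["rhat"].items():
        if np.isfinite(v) and v > 1.1:
            warnings.warn(f"split-chain R-hat for {k} is {v:.3f} (> 1.1); "
                          "run a longer chain")

    return PosteriorSummary(means=means, sds=sds, dic=float(dic),
                            pd_eff=float(p_eff), n_retained=n_keep,
                            chains=chains, solutions=solutions,
                            diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# bivariate Gibbs


def _sample_block_bivariate(rng, U: np.ndarray, w: np.ndarray,
                            Rinv_e: np.ndarray, Pr_inv: np.ndarray):
    """Sample all 2-vectors alpha_i from N(P_i^-1 u_i, P_i^-1) with
    P_i = w_i * Rinv_e + Pr_inv, vectorized over i."""
    p11 = w * Rinv_e[0, 0] + Pr_inv[0, 0]
    p12 = w * Rinv_e[0, 1] + Pr_inv[0, 1]
    p22 = w * Rinv_e[1, 1] + Pr_inv[1, 1]
    det = p11 * p22 - p12 ** 2
    s11, s12, s22 = p22 / det, -p12 / det, p11 / det
    mean1 = s11 * U[:, 0] + s12 * U[:, 1]
    mean2 = s12 * U[:, 0] + s22 * U[:, 1]
    l11 = np.sqrt(s11)
    l21 = s12 / l11
    l22 = np.sqrt(np.maximum(s22 - l21 ** 2, 1e-300))
    z = rng.standard_normal((len(w), 2))
    out = np.empty_like(U)
    out[:, 0] = mean1 + l11 * z[:, 0]
    out[:, 1] = mean2 + l21 * z[:, 0] + l22 * z[:, 1]
    return out


def _gibbs_bivariate(spec, data, config: GibbsConfig) -> PosteriorSummary:
    rng = np.random.default_rng(config.seed)
    Y = data["y"]
    X = data["X"]
    n_obs, p = X.shape
    nu0 = -3.0 if config.prior_df == -2.0 else config.prior_df  # flat IW default

    use_a, use_m = spec.include_genetic, spec.include_microbiome
    if not (use_a or use_m):
        raise FitError("bivariate fits are supported for Models (2)-(4)")
    if p:
        XtX = X.T @ X
        Lx = linalg.cholesky(XtX + 1e-12 * np.trace(XtX) / p * np.eye(p), lower=True)
    if use_a:
        Ta, Ga, wa = _genetic_basis(data["A"], data["z1"])
        n_ped = Ta.shape[1]
        Amat = np.zeros((n_ped, 2))
    if use_m:
        Tm, Gm, vm = _microbial_basis(data["M"], data["z2"])
        r_m = Tm.shape[1]
        Bmat = np.zeros((r_m, 2))

    vy = np.maximum(Y.var(axis=0), 1e-12)
    Re = np.diag(vy / 2)
    G0 = np.diag(vy / 4) if use_a else None
    Rm = np.diag(vy / 4) if use_m else None
    B = np.zeros((p, 2))
    FA = np.zeros((n_obs, 2))
    FM = np.zeros((n_obs, 2))
    XB = np.zeros((n_obs, 2))

    keys = ["sigma2_a1", "sigma2_a2", "sigma_a12", "r_a",
            "sigma2_m1", "sigma2_m2", "sigma_m12", "r_m",
            "sigma2_e1", "sigma2_e2", "sigma_e12", "r_e",
            "h2_1", "h2_2", "m2_1", "m2_2", "deviance"]
    rec = {k: [] for k in keys}
    n_keep = 0
    fit_sum = np.zeros((n_obs, 2))
    sol_sums = {"b": np.zeros((p, 2))}
    if use_a:
        sol_sums["alpha"] = np.zeros((n_ped, 2))
    if use_m:
        sol_sums["beta"] = np.zeros((r_m, 2))

    def corr(V):
        d = np.sqrt(V[0, 0] * V[1, 1])
        return V[0, 1] / d if d > 0 else np.nan

    for it in range(config.n_iter):
        Rei = np.linalg.inv(Re)
        if p:
            Resid = Y - FA - FM
            Bhat = linalg.cho_solve((Lx, True), X.T @ Resid)
            Z = rng.standard_normal((p, 2))
            Lre = np.linalg.cholesky(Re)
            B = Bhat + linalg.solve_triangular(Lx.T, Z) @ Lre.T
            XB = X @ B
        if use_a:
            U = Ga.T @ ((Y - XB - FM) @ Rei)
            Amat = _sample_block_bivariate(rng, U, wa, Rei, np.linalg.inv(G0))
            FA = Ga @ Amat
        if use_m:
            U = Gm.T @ ((Y - XB - FA) @ Rei)
            Bmat = _sample_block_bivariate(rng, U, vm, Rei, np.linalg.inv(Rm))
            FM = Gm @ Bmat
        E = Y - XB - FA - FM
        Re = _inv_wishart_2x2(rng, E.T @ E, n_obs + nu0)
        if use_a:
            G0 = _inv_wishart_2x2(rng, Amat.T @ Amat, n_ped + nu0)
        if use_m:
            Rm = _inv_wishart_2x2(rng, Bmat.T @ Bmat, r_m + nu0)
        if not np.all(np.isfinite(Re)):
            raise FitError(f"divergent chain at iteration {it}")

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            g = G0 if use_a else np.zeros((2, 2))
            mm = Rm if use_m else np.zeros((2, 2))
            tot = np.diag(g) + np.diag(mm) + np.diag(Re)
            rec["sigma2_a1"].append(g[0, 0]); rec["sigma2_a2"].append(g[1, 1])
            rec["sigma_a12"].append(g[0, 1])
            rec["r_a"].append(corr(g) if use_a else np.nan)
            rec["sigma2_m1"].append(mm[0, 0]); rec["sigma2_m2"].append(mm[1, 1])
            rec["sigma_m12"].append(mm[0, 1])
            rec["r_m"].append(corr(mm) if use_m else np.nan)
            rec["sigma2_e1"].append(Re[0, 0]); rec["sigma2_e2"].append(Re[1, 1])
            rec["sigma_e12"].append(Re[0, 1]); rec["r_e"].append(corr(Re))
            rec["h2_1"].append(g[0, 0] / tot[0]); rec["h2_2"].append(g[1, 1] / tot[1])
            rec["m2_1"].append(mm[0, 0] / tot[0]); rec["m2_2"].append(mm[1, 1] / tot[1])
            sign, logdet = np.linalg.slogdet(Re)
            Rei_now = np.linalg.inv(Re)
            rec["deviance"].append(n_obs * (2 * np.log(2 * np.pi) + logdet)
                                   + float(np.trace(Rei_now @ (E.T @ E))))
            n_keep += 1
            fit_sum += XB + FA + FM
            sol_sums["b"] += B
            if use_a:
                sol_sums["alpha"] += Amat
            if use_m:
                sol_sums["beta"] += Bmat

    chains = pd.DataFrame(rec)
    param_keys = [k for k in keys if k != "deviance"]
    means = {k: float(np.nanmean(chains[k])) for k in param_keys}
    sds = {k: float(np.nanstd(chains[k], ddof=1)) if n_keep > 1 else 0.0
           for k in param_keys}

    # DIC at posterior means
    fit_bar = fit_sum / n_keep
    Re_bar = np.array([[means["sigma2_e1"], means["sigma_e12"]],
                       [means["sigma_e12"], means["sigma2_e2"]]])
    Eb = Y - fit_bar
    sign, logdet = np.linalg.slogdet(Re_bar)
    dev_at_mean = n_obs * (2 * np.log(2 * np.pi) + logdet) \
        + float(np.trace(np.linalg.inv(Re_bar) @ (Eb.T @ Eb)))
    dic, p_eff = compute_dic(chains["deviance"].to_numpy(), dev_at_mean)

    solutions = {"b": pd.DataFrame(sol_sums["b"] / n_keep, index=data["xnames"],
                                   columns=spec.traits)}
    if use_a:
        solutions["a"] = pd.DataFrame(Ta @ (sol_sums["alpha"] / n_keep),
                                      index=data["A"].ids, columns=spec.traits)
    if use_m:
        solutions["m"] = pd.DataFrame(Tm @ (sol_sums["beta"] / n_keep),
                                      index=data["M"].ids, columns=spec.traits)

    flags = {}
    for rkey, on in (("r_a", use_a), ("r_m", use_m), ("r_e", True)):
        if on and (not np.isfinite(means[rkey]) or abs(means[rkey]) > 0.98):
            flags[rkey] = "NE"

    watch = ["sigma2_e1", "sigma2_e2"] + (["sigma2_a1"] if use_a else []) \
        + (["sigma2_m1"] if use_m else [])
    diagnostics = {"rhat": {k: _split_rhat(chains[k].to_numpy()) for k in watch},
                   "ess": {k: _ess(chains[k].to_numpy()) for k in watch}}

    return PosteriorSummary(means=means, sds=sds, dic=float(dic),
                            pd_eff=float(p_eff), n_retained=n_keep,
                            chains=chains, solutions=solutions,
                            diagnostics=diagnostics, flags=flags)


def gibbs_fit(spec: ModelSpec, phenotypes: pd.DataFrame,
              A: Optional[RelationshipMatrix] = None,
              M: Optional[RelationshipMatrix] = None,
              config: Optional[GibbsConfig] = None) -> PosteriorSummary:
    """Fit a model by blocked Gibbs sampling.

    Univariate for one trait; for two traits the bivariate sampler with
    inverse-Wishart conditionals on the 2x2 component matrices is used
    (complete records on both traits are required).
    """
    config = config or GibbsConfig()
    data = _assemble(spec, phenotypes, A, M)
    if spec.bivariate:
        n_all = len(phenotypes)
        if len(data["pheno"]) < n_all:
            warnings.warn(f"bivariate fit uses the {len(data['pheno'])} of "
                          f"{n_all} records complete on both traits")
        return _gibbs_bivariate(spec, data, config)
    return _gibbs_univariate(spec, data, config)


# ---------------------------------------------------------------------------
# Henderson mixed model equations (fixed variances)


@dataclass
class MmeSystem:
    C: np.ndarray
    rhs: np.ndarray
    xnames: list
    slices: dict
    ids_a: list
    ids_m: list
    X: np.ndarray
    variances: dict
    data: dict


@dataclass
class BlupSolution:
    b: pd.Series
    a: Optional[pd.Series]
    m: Optional[pd.Series]
    cmm: Optional[np.ndarray]
    cbb: Optional[np.ndarray]
    variances: dict
    xnames: list


def build_mme(spec: ModelSpec, phenotypes: pd.DataFrame,
              A: Optional[RelationshipMatrix], M: Optional[RelationshipMatrix],
              variances: dict) -> MmeSystem:
    """Henderson's mixed model equations at fixed variance components.

    ``variances`` holds sigma2_e plus sigma2_a / sigma2_m for the included
    random terms.  The coefficient matrix is
    [X'X, X'Z; Z'X, Z'Z + K^-1 lambda] with lambda = sigma2_e / sigma2_term.
    """
    if spec.bivariate:
        raise FitError("build_mme is univariate; bivariate fits use gibbs_fit")
    data = _assemble(spec, phenotypes, A, M)
    y, X = data["y"], data["X"]
    n_obs, p = X.shape
    sig2e = float(variances["sigma2_e"])
    if sig2e <= 0:
        raise FitError("sigma2_e must be positive")

    blocks = [X]
    ids_a, ids_m = [], []
    if spec.include_genetic:
        if variances.get("sigma2_a", 0) <= 0:
            raise FitError("sigma2_a must be positive for Model (3)/(4)")
        n_ped = data["A"].n
        Z1 = np.zeros((n_obs, n_ped))
        Z1[np.arange(n_obs), data["z1"]] = 1.0
        blocks.append(Z1)
        ids_a = list(data["A"].ids)
    if spec.include_microbiome:
        if variances.get("sigma2_m", 0) <= 0:
            raise FitError("sigma2_m must be positive for Model (2)/(4)")
        n_mic = data["M"].n
        Z2 = np.zeros((n_obs, n_mic))
        Z2[np.arange(n_obs), data["z2"]] = 1.0
        blocks.append(Z2)
        ids_m = list(data["M"].ids)

    W = np.hstack(blocks)
    C = W.T @ W
    rhs = W.T @ y
    slices = {"b": slice(0, p)}
    off = p
    if spec.include_genetic:
        n_ped = data["A"].n
        lam_a = sig2e / float(variances["sigma2_a"])
        Ainv = np.linalg.inv(data["A"].matrix + 1e-10 * np.eye(n_ped))
        C[off:off + n_ped, off:off + n_ped] += Ainv * lam_a
        slices["a"] = slice(off, off + n_ped)
        off += n_ped
    if spec.include_microbiome:
        n_mic = data["M"].n
        lam_m = sig2e / float(variances["sigma2_m"])
        Minv = relationship_inverse(data["M"])
        C[off:off + n_mic, off:off + n_mic] += Minv * lam_m
        slices["m"] = slice(off, off + n_mic)
        off += n_mic

    return MmeSystem(C=C, rhs=rhs, xnames=data["xnames"], slices=slices,
                     ids_a=ids_a, ids_m=ids_m, X=X, variances=dict(variances),
                     data=data)


def blup_solve(spec: ModelSpec, phenotypes: pd.DataFrame,
               A: Optional[RelationshipMatrix], M: Optional[RelationshipMatrix],
               variances: dict, compute_cmm: bool = False) -> BlupSolution:
    """Exact MME solve at fixed variances.

    With ``compute_cmm`` the microbial block of the inverse coefficient
    matrix is returned (prediction error variances: PEV(m_hat) =
    C^mm sigma2_e).
    """
    mme = build_mme(spec, phenotypes, A, M, variances)
    try:
        fac = linalg.cho_factor(mme.C)
    except linalg.LinAlgError as exc:
        raise FitError("singular mixed-model equations; check for aliased "
                       "fixed effects or zero variance components") from exc
    theta = linalg.cho_solve(fac, mme.rhs)
    sl = mme.slices
    b = pd.Series(theta[sl["b"]], index=mme.xnames)
    a = pd.Series(theta[sl["a"]], index=mme.ids_a) if "a" in sl else None
    m = pd.Series(theta[sl["m"]], index=mme.ids_m) if "m" in sl else None
    cmm = cbb = None
    if compute_cmm:
        Cinv = linalg.cho_solve(fac, np.eye(mme.C.shape[0]))
        cbb = Cinv[sl["b"], sl["b"]]
        if "m" in sl:
            cmm = Cinv[sl["m"], sl["m"]]
    return BlupSolution(b=b, a=a, m=m, cmm=cmm, cbb=cbb,
                        variances=dict(mme.variances), xnames=mme.xnames)


def adjusted_phenotype_correlations(solution, phenotypes: pd.DataFrame,
                                    spec: ModelSpec) -> dict:
    """Correlations of fixed-effect-adjusted phenotypes y* = y - X b_hat
    with the random-term solutions of the fitted model.

    Returns r(y*, m_hat) for Model (2), r(y*, a_hat) for Model (3), and all
    of r(y*, a_hat), r(y*, m_hat), r(y*, a_hat + m_hat) for Model (4).
    ``solution`` may be a BlupSolution or a PosteriorSummary (posterior-mean
    solutions).
    """
    data = _assemble(spec, phenotypes, None if not spec.include_genetic else
                     _dummy_rel(solution, "a"), None if not spec.include_microbiome
                     else _dummy_rel(solution, "m"))
    y, X = data["y"], data["X"]
    sols = solution.solutions if isinstance(solution, PosteriorSummary) else {
        "b": solution.b, "a": solution.a, "m": solution.m}
    b = sols["b"].reindex(data["xnames"]).to_numpy(float)
    ystar = y - X @ b
    out = {}
    parts = []
    if spec.include_genetic:
        a = sols["a"].loc[data["pheno"]["id"]].to_numpy(float)
        out["r_ystar_a"] = float(np.corrcoef(ystar, a)[0, 1])
        parts.append(a)
    if spec.include_microbiome:
        m = sols["m"].loc[data["pheno"]["id"]].to_numpy(float)
        out["r_ystar_m"] = float(np.corrcoef(ystar, m)[0, 1])
        parts.append(m)
    if len(parts) == 2:
        out["r_ystar_am"] = float(np.corrcoef(ystar, parts[0] + parts[1])[0, 1])
    return out


def _dummy_rel(solution, which: str) -> RelationshipMatrix:
    """Identity placeholder carrying the solution's id set, used only to
    align phenotype rows with solution entries."""
    sols = solution.solutions if isinstance(solution, PosteriorSummary) else {
        "a": solution.a, "m": solution.m}
    ids = list(sols[which].index)
    return RelationshipMatrix(ids=ids, matrix=np.eye(len(ids)),
                              kind="pedigree" if which == "a" else "microbial")
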