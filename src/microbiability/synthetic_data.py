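"""Synthetic pedigrees, OTU count tables and phenotypes with known truth.

The generator mirrors the generative structure assumed by the mixed models:
phenotypes are fixed effects plus pedigree-correlated breeding values plus a
microbiome contribution m = Z3 u plus residuals,

    y = Xb + a + Z3 u + e,   a ~ N(0, A sigma2_a),  u_j ~ N(0, sigma2_m / k),

so that var(m) = sigma2_m * M with M = Z3 Z3'/k built by the preprocessing
pipeline from the simulated counts.  Counts themselves follow a zero-inflated
log-normal/multinomial model: each OTU has a community-level log propensity,
each sample perturbs it and structurally silences a fraction of OTU, and the
sequencer draws a multinomial at a sample-specific depth.  Two founder
subpopulations ("lines") run through the pedigree and both are present in
every contemporary group.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeError
from .preprocess import (AbundanceDesign, OtuCountTable, log_standardize,
                         prevalence_filter, rarefy)

__all__ = ["SimConfig", "SimTruth", "SimData", "simulate_pedigree",
           "simulate_breeding_values", "simulate_otu_counts",
           "simulate_phenotypes", "simulate_bivariate_phenotypes",
           "simulate_dataset"]


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters for one simulated dataset.

    Defaults emulate the scale of a two-line divergent-selection experiment:
    ~550 phenotyped animals in the last generation plus two ancestor
    generations, an OTU table rarefied to depth 9000, and feed-conversion-
    ratio-like variance components on the trait scale.
    """

    n_founders: int = 60
    n_generations: int = 2
    litter_size: int = 8
    n_phenotyped: int = 565
    n_otu: int = 1000
    depth_mean: float = 12000.0
    depth_sd: float = 1500.0
    zero_inflation: float = 0.5
    sigma2_a: float = 0.022
    sigma2_m: float = 0.014
    sigma2_e: float = 0.032
    n_planted: int = 0
    planted_effect: float = 0.0
    fixed_levels: dict = field(default_factory=lambda: {"pen_size": 5, "herd": 2, "sex": 3})
    n_cg: int = 14
    rarefaction_depth: int = 9000
    min_prevalence: float = 0.01
    otu_spread: float = 2.0      # sd of community-level log propensities
    dispersion: float = 1.0      # sd of per-sample log-propensity noise
    n_factors: int = 30          # latent community axes shared by OTU
    factor_sd: float = 2.0       # total sd of the factor part of log propensity
    seed: int = 42

    def __post_init__(self):
        if min(self.sigma2_a, self.sigma2_m, self.sigma2_e) < 0:
            raise ConfigError("variances must be non-negative")
        if self.n_cg < 2:
            raise ConfigError("need at least 2 contemporary groups")
        if not 0 <= self.zero_inflation < 1:
            raise ConfigError("zero_inflation must be in [0, 1)")
        if self.n_founders < 2:
            raise ConfigError("need at least 2 founders")
        if self.n_generations >= 1 and self.litter_size < 1:
            raise ConfigError("litter_size must be >= 1")

    def rng_for(self, stage: str) -> np.random.Generator:
        """Independent, reproducible stream per pipeline stage."""
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode()) % (2**31)])
        return np.random.default_rng(ss)


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated phenotype table."""

    breeding_values: pd.Series        # per pedigree animal
    microbial_values: pd.Series       # per phenotyped animal, m = Z3 u
    otu_effects: np.ndarray           # u, per retained OTU
    fixed_effects: dict               # factor -> level values
    realized_h2: float
    realized_m2: float
    sigma2_a: float
    sigma2_m: float
    sigma2_e: float

    @property
    def target_h2(self) -> float:
        tot = self.sigma2_a + self.sigma2_m + self.sigma2_e
        return self.sigma2_a / tot if tot > 0 else 0.0

    @property
    def target_m2(self) -> float:
        tot = self.sigma2_a + self.sigma2_m + self.sigma2_e
        return self.sigma2_m / tot if tot > 0 else 0.0


@dataclass
class SimData:
    """Bundle returned by :func:`simulate_dataset`."""

    config: SimConfig
    pedigree: Pedigree
    counts: OtuCountTable
    phenotypes: pd.DataFrame
    truth: SimTruth
    design: AbundanceDesign
    discarded_samples: list


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Multi-generation two-line pedigree with the last generation sized to
    hold the phenotyped animals.

    Founders are split into two lines (a single line if there are fewer than
    four founders); each generation mates random sires and dams within line,
    litters of ``litter_size``; the two lines' offspring are interleaved in
    birth order so contemporary-group blocks span both lines.  The returned
    pedigree carries a ``meta`` DataFrame (id, generation, line, sex).
    """
    rng = config.rng_for("pedigree")
    two_lines = config.n_founders >= 4
    records, meta = [], []

    def add(animal, sire, dam, gen, line, sex):
        records.append((animal, sire, dam))
        meta.append({"id": animal, "generation": gen, "line": line, "sex": sex})

    lines = (0, 1) if two_lines else (0,)
    founders = {ln: [] for ln in lines}
    for i in range(config.n_founders):
        ln = lines[i % len(lines)]
        aid = f"F{i:04d}"
        founders[ln].append((aid, "M" if (i // len(lines)) % 2 == 0 else "F"))
        add(aid, 0, 0, 0, ln, founders[ln][-1][1])

    prev = founders
    mid_target = max(config.n_founders, config.n_phenotyped // 2)
    for gen in range(1, config.n_generations + 1):
        target = config.n_phenotyped if gen == config.n_generations else mid_target
        per_line_kids = {ln: [] for ln in lines}
        for ln in lines:
            tgt = target // len(lines) + (target % len(lines) if ln == lines[0] else 0)
            males = [a for a, s in prev[ln] if s == "M"]
            females = [a for a, s in prev[ln] if s == "F"]
            if not males or not females:
                raise ConfigError(f"line {ln} generation {gen - 1} lacks a sex; "
                                  "cannot produce offspring")
            n_matings = int(np.ceil(tgt / config.litter_size))
            sires = rng.choice(males, size=n_matings, replace=True)
            if len(females) >= n_matings:
                dams = rng.choice(females, size=n_matings, replace=False)
            else:
                dams = rng.choice(females, size=n_matings, replace=True)
            born = 0
            for j in range(n_matings):
                for _ in range(min(config.litter_size, tgt - born)):
                    sex = "M" if born % 2 == 0 else "F"
                    aid = f"G{gen}L{ln}_{born:05d}"
                    per_line_kids[ln].append((aid, sex))
                    add(aid, sires[j], dams[j], gen, ln, sex)
                    born += 1
        prev = per_line_kids

    ped = Pedigree.from_records(records)
    meta_df = pd.DataFrame(meta)
    # interleave lines in birth order for the final generation
    last = meta_df[meta_df.generation == config.n_generations]
    if two_lines:
        l0 = last[last.line == 0]["id"].tolist()
        l1 = last[last.line == 1]["id"].tolist()
        inter = [x for pair in zip(l0, l1) for x in pair]
        tail = l0[len(l1):] + l1[len(l0):]
        final_order = inter + tail
    else:
        final_order = last["id"].tolist()
    ped.meta = meta_df
    ped.final_generation = final_order
    return ped


def simulate_breeding_values(ped: Pedigree, sigma2_a: float,
                             seed: int | np.random.Generator) -> np.ndarray:
    """Breeding values by Mendelian sampling, aligned with ``ped.ids``.

    Founders draw N(0, sigma2_a); an offspring is the mean of its known
    parents plus a segregation deviation whose variance accounts for
    parental inbreeding: sigma2_a * (0.5 - 0.25*(F_s + F_d)) with both
    parents known, sigma2_a * (0.75 - 0.25*F_p) with one.
    """
    if sigma2_a < 0:
        raise ConfigError("sigma2_a must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sigma2_a == 0:
        return np.zeros(ped.n)
    F = ped.inbreeding()
    a = np.zeros(ped.n)
    z = rng.standard_normal(ped.n)
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            a[i] = z[i] * np.sqrt(sigma2_a)
        elif s >= 0 and d >= 0:
            v = sigma2_a * (0.5 - 0.25 * (F[s] + F[d]))
            a[i] = 0.5 * (a[s] + a[d]) + z[i] * np.sqrt(v)
        else:
            p = s if s >= 0 else d
            v = sigma2_a * (0.75 - 0.25 * F[p])
            a[i] = 0.5 * a[p] + z[i] * np.sqrt(v)
    return a


def simulate_otu_counts(config: SimConfig, sample_ids: Optional[list] = None,
                        rng: Optional[np.random.Generator] = None) -> OtuCountTable:
    """Zero-inflated log-normal/multinomial OTU counts.

    Community log propensities b_j ~ N(0, otu_spread^2) are shared across
    samples.  Between-sample variation has two parts: ``n_factors`` latent
    community axes with OTU loadings (gut communities co-vary along a few
    dominant gradients, which is what gives the microbial relationship
    matrix its informative eigenstructure) and iid N(0, dispersion^2) noise.
    Each OTU is structurally zeroed per sample with probability
    ``zero_inflation`` and counts are multinomial at a depth sampled from
    N(depth_mean, depth_sd) (floored at 1).
    """
    if config.n_otu < 2:
        raise ConfigError("need at least 2 OTU")
    rng = rng or config.rng_for("otu_counts")
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(config.n_phenotyped)]
    n, k = len(sample_ids), config.n_otu
    base = rng.normal(0.0, config.otu_spread, size=k)
    logits = base[None, :] + rng.normal(0.0, config.dispersion, size=(n, k))
    if config.n_factors > 0 and config.factor_sd > 0:
        q = config.n_factors
        loadings = rng.normal(0.0, config.factor_sd / np.sqrt(q), size=(k, q))
        factors = rng.standard_normal((n, q))
        logits = logits + factors @ loadings.T
    present = rng.random((n, k)) >= config.zero_inflation
    # guarantee at least one live OTU per sample
    dead = ~present.any(axis=1)
    if dead.any():
        present[dead, rng.integers(0, k, size=int(dead.sum()))] = True
    w = np.where(present, np.exp(logits - logits.max(axis=1, keepdims=True)), 0.0)
    p = w / w.sum(axis=1, keepdims=True)
    depths = np.maximum(1, np.round(rng.normal(config.depth_mean, config.depth_sd,
                                               size=n))).astype(np.int64)
    counts = np.vstack([rng.multinomial(depths[i], p[i]) for i in range(n)])
    return OtuCountTable(list(sample_ids), [f"OTU{j:05d}" for j in range(k)], counts)


def _assign_factors(ids: list, order: dict, config: SimConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Fixed-effect factor levels; CG by birth-order blocks of the final
    generation so each CG is a cohort containing both lines."""
    n = len(ids)
    cols = {"id": ids}
    for name, levels in config.fixed_levels.items():
        cols[name] = rng.integers(0, levels, size=n)
    pos = np.array([order.get(a, 0) for a in ids], dtype=float)
    ranks = np.argsort(np.argsort(pos))
    cols["cg"] = (ranks * config.n_cg // n).astype(int)
    df = pd.DataFrame(cols)
    for c in df.columns:
        if c != "id":
            df[c] = df[c].map(lambda v, c=c: f"{c}{v}")
    return df


def simulate_phenotypes(ped: Pedigree, counts: OtuCountTable, config: SimConfig
                        ) -> tuple[pd.DataFrame, SimTruth]:
    """Assemble y = Xb + a + Z3 u + e for the animals retained by the
    rarefaction/filter pipeline.

    Z3 comes from the same preprocessing the estimation side uses, so the
    simulated microbial values have covariance sigma2_m * M exactly.  OTU
    effects are iid N(0, sigma2_m/k) except for ``n_planted`` entries set to
    +/- ``planted_effect`` on the standardized scale.  Realized h2/m2 are
    variance ratios of the fixed-effect-free part a + m + e.
    """
    missing = [s for s in counts.sample_ids if s not in ped._pos]
    if missing:
        raise ConfigError(f"samples not in pedigree: {missing[:5]}")
    rng = config.rng_for("phenotypes")
    rare, _ = rarefy(counts, config.rarefaction_depth,
                     seed=int(config.rng_for("rarefy").integers(2**31)))
    filt = prevalence_filter(rare, config.min_prevalence)
    design = log_standardize(filt)
    ids = design.sample_ids
    n, k = design.n, design.k

    a_full = simulate_breeding_values(ped, config.sigma2_a, config.rng_for("bv"))
    a = a_full[ped.index_of(ids)]

    u = rng.normal(0.0, np.sqrt(config.sigma2_m / k), size=k)
    if config.n_planted > 0:
        if config.planted_effect == 0:
            raise ConfigError("n_planted > 0 requires a non-zero planted_effect")
        idx = rng.choice(k, size=config.n_planted, replace=False)
        u[idx] = np.where(np.arange(config.n_planted) % 2 == 0,
                          config.planted_effect, -config.planted_effect)
    m = design.z3 @ u
    e = rng.normal(0.0, np.sqrt(config.sigma2_e), size=n)

    order = {a_: i for i, a_ in enumerate(getattr(ped, "final_generation", ids))}
    factors = _assign_factors(ids, order, config, rng)
    b_levels = {name: {f"{name}{v}": rng.normal() for v in range(levels)}
                for name, levels in config.fixed_levels.items()}
    b_levels["cg"] = {f"cg{v}": rng.normal() for v in range(config.n_cg)}
    xb = np.zeros(n)
    for name, mapping in b_levels.items():
        xb += factors[name].map(mapping).to_numpy()

    y = xb + a + m + e
    pheno = factors.copy()
    pheno.insert(1, "trait", y)

    core = a + m + e
    truth = SimTruth(
        breeding_values=pd.Series(a_full, index=ped.ids),
        microbial_values=pd.Series(m, index=ids),
        otu_effects=u,
        fixed_effects=b_levels,
        realized_h2=float(np.var(a) / np.var(core)),
        realized_m2=float(np.var(m) / np.var(core)),
        sigma2_a=config.sigma2_a, sigma2_m=config.sigma2_m,
        sigma2_e=config.sigma2_e,
    )
    return pheno, truth


def simulate_bivariate_phenotypes(ped: Pedigree, counts: OtuCountTable,
                                  config: SimConfig, G0, Rm, Re
                                  ) -> tuple[pd.DataFrame, dict]:
    """Two traits sharing pedigree and microbiome.

    G0, Rm, Re are 2x2 (co)variance matrices for breeding values, microbial
    values and residuals; per-OTU effect pairs are iid N(0, Rm/k), so the
    microbial values of the two traits have cross-covariance Rm ⊗ M.
    """
    G0, Rm, Re = (np.asarray(x, float) for x in (G0, Rm, Re))
    for name, V in (("G0", G0), ("Rm", Rm), ("Re", Re)):
        if V.shape != (2, 2) or not np.allclose(V, V.T):
            raise ConfigError(f"{name} must be symmetric 2x2")
        if np.linalg.eigvalsh(V).min() < -1e-10:
            raise ConfigError(f"{name} must be positive semi-definite")
    rng = config.rng_for("phenotypes2")
    rare, _ = rarefy(counts, config.rarefaction_depth,
                     seed=int(config.rng_for("rarefy").integers(2**31)))
    filt = prevalence_filter(rare, config.min_prevalence)
    design = log_standardize(filt)
    ids = design.sample_ids
    n, k = design.n, design.k

    # bivariate Mendelian sampling: scale a unit-variance pair of correlated
    # pedigree draws by chol(G0)
    La = np.linalg.cholesky(G0 + 1e-12 * np.eye(2))
    z1 = simulate_breeding_values(ped, 1.0, config.rng_for("bv1"))
    z2 = simulate_breeding_values(ped, 1.0, config.rng_for("bv2"))
    A2 = np.column_stack([z1, z2]) @ La.T
    a = A2[ped.index_of(ids)]

    U = rng.standard_normal((k, 2)) @ np.linalg.cholesky(Rm / k + 1e-15 * np.eye(2)).T
    m = design.z3 @ U
    E = rng.standard_normal((n, 2)) @ np.linalg.cholesky(Re + 1e-15 * np.eye(2)).T

    order = {a_: i for i, a_ in enumerate(getattr(ped, "final_generation", ids))}
    factors = _assign_factors(ids, order, config, rng)
    b_levels = {name: {f"{name}{v}": rng.normal(size=2) for v in range(levels)}
                for name, levels in config.fixed_levels.items()}
    b_levels["cg"] = {f"cg{v}": rng.normal(size=2) for v in range(config.n_cg)}
    xb = np.zeros((n, 2))
    for name, mapping in b_levels.items():
        xb += np.vstack(factors[name].map(mapping).to_numpy())

    Y = xb + a + m + E
    pheno = factors.copy()
    pheno.insert(1, "trait1", Y[:, 0])
    pheno.insert(2, "trait2", Y[:, 1])
    truth = {"G0": G0, "Rm": Rm, "Re": Re, "otu_effects": U,
             "microbial_values": pd.DataFrame(m, index=ids),
             "breeding_values": pd.DataFrame(a, index=ids)}
    return pheno, truth


def simulate_dataset(config: SimConfig) -> SimData:
    """Pedigree, counts, phenotypes and truth from one configuration."""
    ped = simulate_pedigree(config)
    sample_ids = (ped.final_generation[:config.n_phenotyped]
                  if config.n_generations >= 1 else list(ped.ids)[:config.n_phenotyped])
    counts = simulate_otu_counts(config, sample_ids=sample_ids)
    pheno, truth = simulate_phenotypes(ped, counts, config)
    rare, discarded = rarefy(counts, config.rarefaction_depth,
                             seed=int(config.rng_for("rarefy").integers(2**31)))
    design = log_standardize(prevalence_filter(rare, config.min_prevalence))
    return SimData(config=config, pedigree=ped, counts=counts, phenotypes=pheno,
                   truth=truth, design=design, discarded_samples=discarded)


def config_to_yaml_dict(config: SimConfig) -> dict:
    d = asdict(config)
    return d
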