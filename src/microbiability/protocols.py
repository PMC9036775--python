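"""End-to-end evaluation protocols: simulate at known variance components,
fit by Gibbs sampling, and summarize recovery across seeds.

These drive both the acceptance script and the heavier integration tests.
Problem sizes default to the desk-scale study emulation (~550 phenotyped
animals, 1000 OTU, 20,000-iteration chains).
"""

from __future__ import annotations

import numpy as np

from .mixed_models import GibbsConfig, ModelSpec, gibbs_fit
from .pedigree import build_A
from .preprocess import build_microbial_relationship, preprocess_counts
from .synthetic_data import (SimConfig, simulate_bivariate_phenotypes,
                             simulate_dataset, simulate_otu_counts,
                             simulate_pedigree)

FIXED_EFFECTS = ["pen_size", "herd", "sex", "cg"]

DESK_CHAIN = dict(n_iter=20000, burn_in=4000, thin=10)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def recovery_protocol(sigma2_a: float, sigma2_m: float, sigma2_e: float,
                      n_seeds: int = 5, seed: int = 1,
                      n_phenotyped: int = 565, n_otu: int = 1000,
                      chain: dict = DESK_CHAIN) -> dict:
    """Simulate/fit the full model ``n_seeds`` times at fixed truths.

    Returns seed-averaged posterior means and posterior SDs of h2 and m2,
    the implied simulation targets, and the realized sample size.
    """
    seeds = _spawn_seeds(seed, n_seeds)
    h2s, m2s, h2_sds, m2_sds, ns = [], [], [], [], []
    for i, s in enumerate(seeds):
        cfg = SimConfig(seed=s, sigma2_a=sigma2_a, sigma2_m=sigma2_m,
                        sigma2_e=sigma2_e, n_phenotyped=n_phenotyped,
                        n_otu=n_otu)
        data = simulate_dataset(cfg)
        A = build_A(data.pedigree)
        M = build_microbial_relationship(data.design)
        spec = ModelSpec.from_model_number(4, "trait",
                                           fixed_effects=FIXED_EFFECTS)
        fit = gibbs_fit(spec, data.phenotypes, A, M,
                        GibbsConfig(seed=s % 100000, **chain))
        h2s.append(fit.means["h2"])
        m2s.append(fit.means["m2"])
        h2_sds.append(fit.sds["h2"])
        m2_sds.append(fit.sds["m2"])
        ns.append(data.design.n)
    tot = sigma2_a + sigma2_m + sigma2_e
    return {
        "h2_mean": float(np.mean(h2s)), "m2_mean": float(np.mean(m2s)),
        "h2_sd": float(np.mean(h2_sds)), "m2_sd": float(np.mean(m2_sds)),
        "h2_per_seed": h2s, "m2_per_seed": m2s,
        "target_h2": sigma2_a / tot, "target_m2": sigma2_m / tot,
        "n": int(np.mean(ns)), "n_seeds": n_seeds,
    }


def components_from_ratios(sigma2_p: float, h2: float, m2: float) -> dict:
    """Variance components on the trait scale from a phenotypic variance and
    the heritability/microbiability ratios."""
    s2a, s2m = h2 * sigma2_p, m2 * sigma2_p
    return {"sigma2_a": s2a, "sigma2_m": s2m,
            "sigma2_e": sigma2_p - s2a - s2m}


def bivariate_recovery_protocol(G0, Rm, Re, n_seeds: int = 5, seed: int = 1,
                                n_phenotyped: int = 515, n_otu: int = 1000,
                                chain: dict = DESK_CHAIN) -> dict:
    """Two-trait simulate/fit protocol; reports the microbial and genetic
    correlations averaged over seeds."""
    G0, Rm, Re = (np.asarray(x, float) for x in (G0, Rm, Re))
    seeds = _spawn_seeds(seed + 7, n_seeds)
    r_ms, r_as, r_m_sds, ns = [], [], [], []
    for s in seeds:
        cfg = SimConfig(seed=s, n_phenotyped=n_phenotyped, n_otu=n_otu)
        ped = simulate_pedigree(cfg)
        counts = simulate_otu_counts(
            cfg, sample_ids=ped.final_generation[:cfg.n_phenotyped])
        pheno, _ = simulate_bivariate_phenotypes(ped, counts, cfg, G0, Rm, Re)
        design, M, _ = preprocess_counts(
            counts, depth=cfg.rarefaction_depth,
            min_prevalence=cfg.min_prevalence,
            seed=int(cfg.rng_for("rarefy").integers(2 ** 31)))
        A = build_A(ped)
        spec = ModelSpec(traits=["trait1", "trait2"], include_genetic=True,
                         include_microbiome=True, fixed_effects=FIXED_EFFECTS)
        fit = gibbs_fit(spec, pheno, A, M, GibbsConfig(seed=s % 100000, **chain))
        r_ms.append(fit.means["r_m"])
        r_as.append(fit.means["r_a"])
        r_m_sds.append(fit.sds["r_m"])
        ns.append(design.n)
    def corr(V):
        return V[0, 1] / np.sqrt(V[0, 0] * V[1, 1])
    return {
        "r_m_mean": float(np.mean(r_ms)), "r_a_mean": float(np.mean(r_as)),
        "r_m_sd": float(np.mean(r_m_sds)),
        "r_m_per_seed": r_ms,
        "target_r_m": float(corr(Rm)), "target_r_a": float(corr(G0)),
        "n": int(np.mean(ns)), "n_seeds": n_seeds,
    }


def dic_ordering_protocol(n_seeds: int = 5, seed: int = 1,
                          n_phenotyped: int = 300, n_otu: int = 200,
                          chain: dict = dict(n_iter=5000, burn_in=1500,
                                             thin=5)) -> dict:
    """Fit the four nested models on signal-bearing simulations and count
    how often adding the microbial term improves (lowers) the DIC."""
    seeds = _spawn_seeds(seed + 13, n_seeds)
    wins_21, wins_43, dics = 0, 0, []
    for s in seeds:
        cfg = SimConfig(seed=s, sigma2_a=0.3, sigma2_m=0.3, sigma2_e=0.4,
                        n_phenotyped=n_phenotyped, n_otu=n_otu,
                        n_founders=40, n_cg=8)
        data = simulate_dataset(cfg)
        A = build_A(data.pedigree)
        M = build_microbial_relationship(data.design)
        row = {}
        for num in (1, 2, 3, 4):
            spec = ModelSpec.from_model_number(num, "trait",
                                               fixed_effects=FIXED_EFFECTS)
            fit = gibbs_fit(spec, data.phenotypes,
                            A if spec.include_genetic else None,
                            M if spec.include_microbiome else None,
                            GibbsConfig(seed=s % 100000, **chain))
            row[num] = fit.dic
        dics.append(row)
        wins_21 += row[2] < row[1]
        wins_43 += row[4] < row[3]
    return {"wins_2_vs_1": wins_21, "wins_4_vs_3": wins_43,
            "n_seeds": n_seeds, "dics": dics}
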