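import numpy as np
import pandas as pd
import pytest

from microbiability import (ModelSpec, Pedigree, SimConfig, build_A,
                            build_microbial_relationship, simulate_dataset)

FIXED = ["pen_size", "herd", "sex", "cg"]


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared by read-only tests."""
    cfg = SimConfig(n_phenotyped=250, n_otu=200, n_founders=30, seed=101,
                    sigma2_a=0.4, sigma2_m=0.3, sigma2_e=0.3, n_cg=6)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit_inputs(small_sim):
    A = build_A(small_sim.pedigree)
    M = build_microbial_relationship(small_sim.design)
    return small_sim, A, M


@pytest.fixture
def trio_pedigree():
    """Sire, dam, one offspring; parents unrelated."""
    return Pedigree.from_records([("s", 0, 0), ("d", 0, 0), ("o", "s", "d")])


def model_spec(number, trait="trait", fixed=FIXED):
    return ModelSpec.from_model_number(number, trait, fixed_effects=fixed)


@pytest.fixture
def random_pedigree():
    """~60-animal random 3-generation pedigree with some inbreeding."""
    rng = np.random.default_rng(7)
    records = [(f"f{i}", 0, 0) for i in range(10)]
    prev = [f"f{i}" for i in range(10)]
    for g in range(3):
        cur = []
        for j in range(18):
            s, d = rng.choice(prev, 2, replace=False)
            a = f"g{g}_{j}"
            records.append((a, s, d))
            cur.append(a)
        prev = cur + list(rng.choice(prev, 4, replace=False))
    return Pedigree.from_records(records)
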