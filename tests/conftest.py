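import numpy as np
import pytest

import bayesam as bs


@pytest.fixture(scope="session")
def tiny_sim():
    """Small simulated dataset (~44 animals) shared by fast model tests."""
    cfg = bs.SimConfig(
        n_base_males=4,
        n_base_females=8,
        n_generations=2,
        dams_per_sire=4,
        offspring_per_dam=4,
        h2_true=0.4,
        seed=42,
    )
    sim = bs.simulate(cfg)
    data = bs.build_design(sim.phenotypes, sim.pedigree)
    return sim, data


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_pedigree(n_animals: int, rng: np.random.Generator) -> bs.Pedigree:
    """Random valid pedigree: each non-founder gets two earlier parents."""
    n_founders = max(2, n_animals // 4)
    records = [(i + 1, 0, 0) for i in range(n_founders)]
    for i in range(n_founders, n_animals):
        s, d = rng.choice(i, size=2, replace=False) + 1
        records.append((i + 1, int(s), int(d)))
    return bs.Pedigree.from_records(records)
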