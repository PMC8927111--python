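import numpy as np
import pytest

from kinstats import Individual, Pedigree, SimConfig, TraitSpec, simulate_cohort


@pytest.fixture
def trio():
    return Pedigree(
        [
            Individual("dad", sex="male"),
            Individual("mom", sex="female"),
            Individual("kid", "dad", "mom"),
        ]
    )


@pytest.fixture
def textbook_pedigree():
    """Founders, full sibs, half sibs, grandchild, inbred offspring."""
    return Pedigree(
        [
            Individual("f1", sex="male"),
            Individual("m1", sex="female"),
            Individual("m2", sex="female"),
            Individual("s1", "f1", "m1"),
            Individual("s2", "f1", "m1", sex="female"),
            Individual("h1", "f1", "m2"),
            Individual("gc", "s1", "m2"),  # grandchild of f1/m1 via s1
            Individual("inb", "s1", "s2"),  # full-sib mating
        ]
    )


@pytest.fixture(scope="session")
def toy_cohort():
    """10 nuclear families (~40 individuals) with fixed simulated data."""
    cfg = SimConfig(
        n_families=10,
        structure="nuclear",
        k_children=2,
        traits=[TraitSpec("y")],
        G=[[0.6]],
        R=[[0.4]],
        beta_age=[0.01],
        beta_sex=[0.3],
        seed=20240915,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
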