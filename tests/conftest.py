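import numpy as np
import pytest

from inbreedage import Pedigree, simulate_genomes, simulate_pedigree
from inbreedage.simulate import SimConfig, TraitConfig


@pytest.fixture
def trio_ped():
    return Pedigree.from_records([("A", None, None), ("B", None, None),
                                  ("C", "A", "B")])


@pytest.fixture
def fullsib_ped():
    """Founders A,B; full sibs C,D; E their offspring (F=0.25)."""
    return Pedigree.from_records([
        ("A", None, None, "M", 0), ("B", None, None, "F", 0),
        ("C", "A", "B", "M", 1), ("D", "A", "B", "F", 1),
        ("E", "C", "D", "M", 2)])


@pytest.fixture
def repeated_sib_ped():
    """Three generations of full-sib matings: F = 0.25, 0.25, 0.375."""
    return Pedigree.from_records([
        ("A", None, None), ("B", None, None),
        ("C", "A", "B"), ("D", "A", "B"),
        ("E", "C", "D"), ("F", "C", "D"),
        ("G", "E", "F")])


def random_general_pedigree(seed, n=60, founder_prob=0.2, missing_prob=0.1):
    """Non-generational pedigree with optional unknown parents (general path)."""
    rng = np.random.default_rng(seed)
    records = []
    males, females = [], []
    for i in range(n):
        aid = f"X{i:03d}"
        sex = "M" if rng.random() < 0.5 else "F"
        if i < 4 or rng.random() < founder_prob or not males or not females:
            records.append((aid, None, None, sex, None))
        else:
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
            if rng.random() < missing_prob:
                sire = None
            elif rng.random() < missing_prob:
                dam = None
            records.append((aid, sire, dam, sex, None))
        (males if sex == "M" else females).append(aid)
    return Pedigree.from_records(records)


@pytest.fixture(scope="session")
def herd_cfg():
    """Small consanguineous herd with genomes, shared across tests."""
    return SimConfig(
        n_founders=40, n_generations=7, n_matings=25, offspring_per_mating=2,
        n_sires=8, avoidance_depth=0, consanguinity_rate=0.3,
        consang_weights={1: 0.4, 2: 0.3, 4: 0.3},
        n_chromosomes=4, chrom_length_mb=100.0, marker_spacing_kb=80.0,
        trait=TraitConfig(t_star=3), seed=99)


@pytest.fixture(scope="session")
def herd(herd_cfg):
    ped = simulate_pedigree(herd_cfg)
    geno, tracks = simulate_genomes(ped, herd_cfg)
    return ped, geno, tracks
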