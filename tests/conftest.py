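import numpy as np
import pytest

import pedigreml as pg
from pedigreml.pedigree import Pedigree, PedigreeEntry


@pytest.fixture
def trio_ped():
    return Pedigree([PedigreeEntry("S"), PedigreeEntry("D"),
                     PedigreeEntry("O", "S", "D")])


@pytest.fixture
def family_ped():
    """Founders S, D; full sibs O1, O2; I inbred offspring of the sibs."""
    return Pedigree([
        PedigreeEntry("S"), PedigreeEntry("D"),
        PedigreeEntry("O1", "S", "D"), PedigreeEntry("O2", "S", "D"),
        PedigreeEntry("I", "O1", "O2"),
    ])


def random_pedigree(n, rng, *, n_founders=None, allow_unknown=True):
    """Random acyclic pedigree: each non-founder draws earlier parents."""
    n_founders = n_founders or max(4, n // 5)
    entries = [PedigreeEntry(f"P{i}") for i in range(n_founders)]
    ids = [e.individual for e in entries]
    for i in range(n_founders, n):
        sire = ids[rng.integers(len(ids))]
        dam = ids[rng.integers(len(ids))]
        while dam == sire:
            dam = ids[rng.integers(len(ids))]
        if allow_unknown and rng.random() < 0.15:
            sire = pg.UNKNOWN
        if allow_unknown and rng.random() < 0.15:
            dam = pg.UNKNOWN
        entries.append(PedigreeEntry(f"P{i}", sire, dam))
        ids.append(f"P{i}")
    return Pedigree(entries)


@pytest.fixture(scope="session")
def small_dataset():
    """One moderate simulated dataset shared across fitting tests."""
    cfg = pg.SimulationConfig(seed=11, n_per_cohort=150, n_cohorts=2,
                              survival_rate=0.4)
    ds = pg.simulate_dataset(cfg)
    rec = ds.records
    for t in pg.TRAITS:
        rec = pg.scale_sessions(rec, t)
    A = pg.additive_relationship(ds.pedigree)
    return ds, rec, A
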