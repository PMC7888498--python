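"""Shared fixtures: small pedigrees, a random-pedigree generator, and the
session-scoped parameter-recovery runs reused by several slow tests."""

import numpy as np
import pytest

from ltam import PedigreeRecord, HerdSimulator, ThresholdAnimalModel, TraitSpec


def random_pedigree(rng, n, p_known=0.7):
    """Random valid pedigree of n animals: each animal may draw parents
    among earlier animals (so it is acyclic by construction)."""
    records = []
    for i in range(n):
        sire = dam = None
        if i >= 2:
            if rng.random() < p_known:
                sire = f"A{rng.integers(i)}"
            if rng.random() < p_known:
                dam = f"A{rng.integers(i)}"
            if sire is not None and sire == dam:
                dam = None
        records.append(PedigreeRecord(f"A{i}", sire, dam))
    return records


@pytest.fixture
def trio_records():
    return [
        PedigreeRecord("A"),
        PedigreeRecord("B"),
        PedigreeRecord("C", sire="A", dam="B"),
    ]


@pytest.fixture
def fullsib_mating_records():
    """Founders A,B; full sibs C,D; E from the C x D mating (F_E = 0.25)."""
    return [
        PedigreeRecord("A"),
        PedigreeRecord("B"),
        PedigreeRecord("C", sire="A", dam="B"),
        PedigreeRecord("D", sire="A", dam="B"),
        PedigreeRecord("E", sire="C", dam="D"),
    ]


@pytest.fixture(scope="session")
def small_herd():
    """A small simulated herd shared by read-only tests."""
    sim = HerdSimulator(n_founder_sires=20, n_founder_dams=120,
                        daughters_per_dam=2)
    return sim.simulate(seed=7)


@pytest.fixture(scope="session")
def recovery_runs():
    """Three-seed parameter recovery at the study's desk-scale conditions:
    3,000 sows, true h2 = 0.30 (litter traits) and 0.25 (liability),
    genetic correlation 0.6, liability-linked culling; joint four-trait
    chains of 20,000 cycles (5,000 burn-in, thinning 10)."""
    out = []
    for seed in (101, 102, 103):
        herd = HerdSimulator().simulate(seed=seed)
        table, _ = herd.analysis_table()
        joint = ThresholdAnimalModel(
            n_cycles=20_000, burn_in=5_000, thin=10, seed=seed,
        ).fit(table, pedigree=herd.pedigree_records)
        s = joint.summary_
        out.append({
            "seed": seed,
            "herd": herd,
            "h2": {t: s.loc[f"h2_{t}", "mean"]
                   for t in ("nba1", "nba2", "nba3", "stay14")},
            "rg": {c: s.loc[c, "mean"]
                   for c in s.index if c.startswith("rg_")},
            "store": joint.store_,
        })
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
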