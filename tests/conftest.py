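"""Shared fixtures: hand-built pedigrees and a cached small simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fgrs.io_registry import FEMALE, MALE, HOUSEHOLD_COLUMNS, PEDIGREE_COLUMNS, Pedigree
from fgrs import synthetic_data as synth
from fgrs import fgrs_core


def make_pedigree(rows, households=None):
    """rows: (person_id, father_id, mother_id, sex, birth, end)."""
    df = pd.DataFrame(rows, columns=PEDIGREE_COLUMNS)
    hh = pd.DataFrame(households, columns=HOUSEHOLD_COLUMNS) if households else None
    return Pedigree(df, hh)


@pytest.fixture
def trio():
    return make_pedigree(
        [
            ("dad", None, None, MALE, 1950, 2017),
            ("mom", None, None, FEMALE, 1952, 2017),
            ("kid", "dad", "mom", FEMALE, 1980, 2017),
        ]
    )


@pytest.fixture
def extended_pedigree():
    """Three generations: grandparents, two full sibs + their cousins, a half-sib."""
    rows = [
        ("gpa", None, None, MALE, 1920, 1995),
        ("gma", None, None, FEMALE, 1922, 2000),
        ("dad", "gpa", "gma", MALE, 1950, 2017),
        ("unc", "gpa", "gma", MALE, 1952, 2017),
        ("mom", None, None, FEMALE, 1951, 2017),
        ("aunt_w", None, None, FEMALE, 1953, 2017),
        ("kid", "dad", "mom", FEMALE, 1980, 2017),
        ("sib", "dad", "mom", MALE, 1982, 2017),
        ("cuz", "unc", "aunt_w", FEMALE, 1981, 2017),
        ("stepmom", None, None, FEMALE, 1955, 2017),
        ("halfsib", "dad", "stepmom", MALE, 1990, 2017),
    ]
    households = [
        ("dad", "h1", 1980, 2000),
        ("mom", "h1", 1980, 2000),
        ("kid", "h1", 1980, 1998),
        ("sib", "h1", 1982, 2000),
        ("halfsib", "h2", 1990, 2008),
        ("stepmom", "h2", 1990, 2008),
    ]
    return make_pedigree(rows, households)


@pytest.fixture
def double_first_cousins():
    """Two brothers married two sisters: their children share both grandparent couples."""
    rows = [
        ("gf1", None, None, MALE, 1900, 1980),
        ("gm1", None, None, FEMALE, 1902, 1985),
        ("gf2", None, None, MALE, 1901, 1981),
        ("gm2", None, None, FEMALE, 1903, 1986),
        ("bro1", "gf1", "gm1", MALE, 1930, 2010),
        ("bro2", "gf1", "gm1", MALE, 1932, 2011),
        ("sis1", "gf2", "gm2", FEMALE, 1931, 2012),
        ("sis2", "gf2", "gm2", FEMALE, 1933, 2013),
        ("dc1", "bro1", "sis1", FEMALE, 1960, 2017),
        ("dc2", "bro2", "sis2", MALE, 1962, 2017),
    ]
    return make_pedigree(rows)


def random_pedigree(rng: np.random.Generator, max_members: int = 60) -> Pedigree:
    """A random multi-generation pedigree for oracle comparisons."""
    n_fam = int(rng.integers(1, 3))
    cfg = synth.SimConfig(
        n_families=n_fam,
        generations=int(rng.integers(3, 5)),
        mean_offspring=float(rng.uniform(1.5, 2.2)),
        disorders=[synth.default_disorders()[0]],
    )
    res = synth.simulate(cfg, seed=int(rng.integers(2**31 - 1)))
    ped = res.pedigree
    if len(ped) > max_members:
        keep = ped.persons["person_id"].iloc[:max_members]
        # keep a parentally-closed prefix: builder order puts parents first
        sub = ped.persons[ped.persons["person_id"].isin(set(keep))].copy()
        known = set(sub["person_id"])
        for col in ("father_id", "mother_id"):
            sub[col] = sub[col].map(lambda v: v if v in known else None)
        ped = Pedigree(sub.reset_index(drop=True))
    return ped


@pytest.fixture(scope="session")
def small_sim():
    """One-disorder simulation shared by read-only tests (h2=0.5, 80 families)."""
    cfg = synth.single_disorder_config(h2=0.5, n_families=80)
    return synth.simulate(cfg, seed=20240)


@pytest.fixture(scope="session")
def small_matrix(small_sim):
    res = small_sim
    return fgrs_core.compute_fgrs_matrix(
        res.pedigree, res.events, res.config.disorder_configs(), res.proband_ids
    )
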