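"""Simulated registry data with known genetic architecture.

The generator emulates the data structure the family genetic risk score
assumes: multi-generation kindreds giving each proband relatives of first
through fifth degree, a multivariate liability-threshold phenotype model
with configurable heritabilities and cross-disorder genetic correlations, a
shared-household environmental component, sex-specific prevalences, age-at-
first-registration distributions, and register-coverage left truncation (a
disorder is only registrable from its register's start year, so older
cohorts carry false-negative relatives).

The pedigree of one family is a proband-centred kindred: a binary tree of
lineal ancestor couples down from ``generations - 1`` levels above the
proband generation, with collateral branches (siblings of every lineal
ancestor, married to new founders) carried down to the proband generation.
With the default four generations a proband therefore has parents, siblings,
grandparents, great-grandparents, aunts/uncles, first cousins, grand-aunts/
-uncles, parents' first cousins, and second cousins — degrees one to five —
plus half-sibs from remarriage.  Mating is random with unrelated founders,
so pedigrees are outbred.

Liabilities follow the additive model L = A + C + E per disorder, with
Var(A) = h2, Var(C) = c2, Var(E) = 1 - h2 - c2.  A child's additive value is
the parental midpoint plus a segregation deviation with covariance
Sigma_A / 2; all cross-disorder structure is carried by the genetic
correlation matrix.  The household component is the mean of the effects of
the households a person was reared in or reared children in (normalized to
unit variance), so cohabiting parent-offspring pairs, and reared-together
siblings, share environment while reared-apart pairs do not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_registry import (
    FEMALE,
    MALE,
    HOUSEHOLD_COLUMNS,
    PEDIGREE_COLUMNS,
    DisorderConfig,
    Pedigree,
)
from . import kinship

DISORDER_CLASSES = {
    "FM": "fsd", "IBS": "fsd", "CFS": "fsd",
    "MD": "internalizing", "AD": "internalizing",
    "RA": "autoimmune", "IBD": "autoimmune", "GRA": "autoimmune",
    "HASH": "autoimmune", "PoRh": "autoimmune",
    "BP": "pain", "MIG": "pain",
    "SD": "sleep",
}


@dataclass(frozen=True)
class DisorderSimSpec:
    """Generative parameters of one disorder."""

    name: str
    disorder_class: str
    prevalence_female: float
    prevalence_male: float
    h2: float
    c2: float
    onset: dict = field(default_factory=lambda: {"dist": "weibull", "shape": 3.0, "scale": 50.0})
    register_start_year: int = 1997

    def __post_init__(self):
        for p in (self.prevalence_female, self.prevalence_male):
            if not 0.0 < p < 1.0:
                raise ValueError(f"{self.name}: prevalence {p} outside (0,1)")
        if not (0.0 <= self.h2 <= 1.0 and 0.0 <= self.c2 <= 1.0 and self.h2 + self.c2 <= 1.0):
            raise ValueError(f"{self.name}: need h2, c2 >= 0 and h2 + c2 <= 1")

    def prevalence(self, sex: str) -> float:
        return self.prevalence_female if sex == FEMALE else self.prevalence_male

    def to_disorder_config(self) -> DisorderConfig:
        return DisorderConfig(
            name=self.name,
            register_start_year=self.register_start_year,
            disorder_class=self.disorder_class,
        )


@dataclass
class SimConfig:
    """Study-condition parameters of the simulated registry."""

    n_families: int = 200
    generations: int = 4
    mean_offspring: float = 2.1
    max_offspring: int = 6
    p_father_absent: float = 0.08
    p_half_sib_paternal: float = 0.08
    p_half_sib_maternal: float = 0.06
    half_sib_mean_children: float = 1.5
    proband_anchor_years: tuple[int, int] = (1955, 1990)
    follow_up_end: int = 2017
    life_expectancy: float = 82.0
    life_sd: float = 10.0
    relative_missingness: float = 0.0
    disorders: list[DisorderSimSpec] = field(default_factory=lambda: default_disorders())
    genetic_correlations: pd.DataFrame | None = None

    def __post_init__(self):
        names = [d.name for d in self.disorders]
        if len(set(names)) != len(names):
            raise ValueError("duplicate disorder names")
        if self.genetic_correlations is None:
            self.genetic_correlations = pd.DataFrame(
                np.eye(len(names)), index=names, columns=names
            )
        rg = self.genetic_correlations.loc[names, names]
        arr = rg.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise ValueError("genetic correlation matrix must be symmetric")
        if not np.allclose(np.diag(arr), 1.0, atol=1e-10):
            raise ValueError("genetic correlation matrix must have unit diagonal")
        eig = np.linalg.eigvalsh(arr)
        if eig.min() < -1e-8:
            raise ValueError(
                f"genetic correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eig.min():.3g})"
            )
        self.genetic_correlations = pd.DataFrame(arr, index=names, columns=names)

    @property
    def disorder_names(self) -> list[str]:
        return [d.name for d in self.disorders]

    def disorder_configs(self) -> dict[str, DisorderConfig]:
        return {d.name: d.to_disorder_config() for d in self.disorders}


def default_disorders() -> list[DisorderSimSpec]:
    """The 13-disorder panel: 3 functional somatic + 10 comparison disorders.

    Registered (not lifetime) prevalences, female/male, chosen as realistic
    register proportions; heritabilities in the range reported for these
    disorder families; onset distributions as Weibull over age.
    """
    def w(shape, scale):
        return {"dist": "weibull", "shape": shape, "scale": scale}

    specs = [
        # name, class, prev_f, prev_m, h2, c2, onset, register start
        ("FM", 0.012, 0.002, 0.50, 0.05, w(4.0, 50.0), 1997),
        ("IBS", 0.045, 0.020, 0.30, 0.05, w(3.0, 45.0), 1997),
        ("CFS", 0.009, 0.004, 0.30, 0.05, w(3.5, 45.0), 1997),
        ("MD", 0.130, 0.070, 0.35, 0.05, w(2.5, 45.0), 1973),
        ("AD", 0.100, 0.060, 0.30, 0.05, w(2.5, 40.0), 1973),
        ("RA", 0.012, 0.005, 0.50, 0.02, w(5.0, 60.0), 1997),
        ("IBD", 0.008, 0.007, 0.50, 0.02, w(3.0, 45.0), 1997),
        ("GRA", 0.008, 0.002, 0.50, 0.02, w(4.0, 50.0), 1997),
        ("HASH", 0.012, 0.002, 0.50, 0.02, w(4.0, 50.0), 1997),
        ("PoRh", 0.006, 0.003, 0.50, 0.02, w(7.0, 70.0), 1997),
        ("BP", 0.150, 0.120, 0.30, 0.05, w(3.0, 50.0), 1997),
        ("MIG", 0.060, 0.020, 0.40, 0.05, w(3.0, 40.0), 1997),
        ("SD", 0.060, 0.050, 0.30, 0.05, w(3.0, 50.0), 1997),
    ]
    return [
        DisorderSimSpec(
            name=n, disorder_class=DISORDER_CLASSES[n],
            prevalence_female=pf, prevalence_male=pm, h2=h2, c2=c2,
            onset=onset, register_start_year=reg,
        )
        for n, pf, pm, h2, c2, onset, reg in specs
    ]


def default_genetic_correlations(names: list[str] | None = None) -> pd.DataFrame:
    """Block-structured genetic correlations for the 13-disorder panel.

    The functional-somatic disorders (FM especially) correlate broadly with
    the internalizing, pain and sleep blocks and weakly with the autoimmune
    block; autoimmune disorders correlate essentially only among themselves.
    """
    names = names or list(DISORDER_CLASSES)
    n = len(names)
    idx = {d: i for i, d in enumerate(names)}
    R = np.eye(n)

    def put(a, b, r):
        if a in idx and b in idx:
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = r

    put("FM", "IBS", 0.35); put("FM", "CFS", 0.30); put("IBS", "CFS", 0.25)
    put("FM", "MD", 0.35); put("FM", "AD", 0.30)
    put("IBS", "MD", 0.20); put("IBS", "AD", 0.20)
    put("CFS", "MD", 0.25); put("CFS", "AD", 0.20)
    put("FM", "RA", 0.15); put("FM", "HASH", 0.15); put("FM", "GRA", 0.10)
    put("FM", "BP", 0.40); put("FM", "MIG", 0.30); put("FM", "SD", 0.35)
    put("IBS", "IBD", 0.15); put("IBS", "BP", 0.20); put("IBS", "MIG", 0.15)
    put("IBS", "SD", 0.15)
    put("CFS", "BP", 0.15); put("CFS", "MIG", 0.15); put("CFS", "SD", 0.20)
    put("MD", "AD", 0.50)
    put("MD", "BP", 0.20); put("MD", "MIG", 0.15); put("MD", "SD", 0.30)
    put("AD", "SD", 0.20); put("AD", "BP", 0.15)
    put("RA", "IBD", 0.20); put("RA", "GRA", 0.25); put("RA", "HASH", 0.25)
    put("RA", "PoRh", 0.30); put("RA", "BP", 0.10)
    put("GRA", "HASH", 0.40); put("IBD", "GRA", 0.10); put("IBD", "HASH", 0.10)
    put("GRA", "PoRh", 0.10); put("HASH", "PoRh", 0.10)
    put("BP", "MIG", 0.25); put("BP", "SD", 0.20); put("MIG", "SD", 0.15)
    eig = np.linalg.eigvalsh(R)
    if eig.min() < 1e-6:  # guard: shrink off-diagonals toward identity
        lam = 1.0 / (1.0 - eig.min() + 1e-6)
        R = lam * R + (1 - lam) * np.eye(n)
    return pd.DataFrame(R, index=names, columns=names)


def fm_profile_config(**overrides) -> SimConfig:
    """Default 13-disorder scenario with the block-structured correlations."""
    cfg = SimConfig(
        genetic_correlations=default_genetic_correlations(
            [d.name for d in default_disorders()]
        ),
        **overrides,
    )
    return cfg


def single_disorder_config(
    h2: float,
    c2: float = 0.0,
    prevalence: float = 0.08,
    n_families: int = 620,
    register_start_year: int = 1900,
    name: str = "D",
    **overrides,
) -> SimConfig:
    """Parameter-recovery scenario: one disorder, full register coverage.

    Full coverage (register open before any birth) isolates genetic
    recovery from the coverage effects exercised elsewhere.
    """
    spec = DisorderSimSpec(
        name=name, disorder_class="fsd",
        prevalence_female=prevalence, prevalence_male=prevalence,
        h2=h2, c2=c2,
        onset={"dist": "weibull", "shape": 3.0, "scale": 45.0},
        register_start_year=register_start_year,
    )
    return SimConfig(n_families=n_families, disorders=[spec], **overrides)


def two_disorder_config(
    rg: float,
    h2: tuple[float, float] = (0.5, 0.5),
    prevalence: float = 0.08,
    n_families: int = 620,
    register_start_year: int = 1900,
    **overrides,
) -> SimConfig:
    """Genetic-correlation recovery scenario: disorders A and B, r_g given."""
    specs = [
        DisorderSimSpec(
            name=n, disorder_class="fsd",
            prevalence_female=prevalence, prevalence_male=prevalence,
            h2=h, c2=0.0,
            onset={"dist": "weibull", "shape": 3.0, "scale": 45.0},
            register_start_year=register_start_year,
        )
        for n, h in zip(("A", "B"), h2)
    ]
    R = pd.DataFrame([[1.0, rg], [rg, 1.0]], index=["A", "B"], columns=["A", "B"])
    return SimConfig(n_families=n_families, disorders=specs, genetic_correlations=R, **overrides)


def cohabitation_config(
    c2: float = 0.3,
    n_families: int = 400,
    **overrides,
) -> SimConfig:
    """Household-effect scenario: no genetics, strong shared environment.

    Half of the fathers never live with their children and remarriage is
    common, so both rearing classes of father-offspring and half-sib pairs
    are well populated for calibrating the cohabitation factors.
    """
    defaults = dict(
        p_father_absent=0.5, p_half_sib_paternal=0.3, p_half_sib_maternal=0.3
    )
    defaults.update(overrides)
    return single_disorder_config(h2=0.0, c2=c2, n_families=n_families, **defaults)


def profile_scenario_config(
    n_families: int = 900,
    prevalence: float = 0.08,
    **overrides,
) -> SimConfig:
    """Scaled-down profile scenario: 13 disorders, block genetic correlations.

    Prevalences are set uniformly higher than the registry defaults, onsets
    earlier, and register coverage full, so that desk-scale case groups are
    large enough for profile comparisons at the conservative alpha; the
    genetic architecture (heritabilities and the correlation blocks) is the
    quantity under study, not registry coverage.
    """
    disorders = [
        replace(
            d,
            prevalence_female=prevalence,
            prevalence_male=prevalence,
            onset={"dist": "weibull", "shape": 3.0, "scale": 35.0},
            register_start_year=1900,
        )
        for d in default_disorders()
    ]
    names = [d.name for d in disorders]
    rg = default_genetic_correlations(names)
    # amplify the FM row: desk-scale case groups (around a thousand cases)
    # can only resolve cross-block elevations at the conservative alpha when
    # the correlations sit at the strong end; the autoimmune links stay weak
    # so the contrast with the RA profile is preserved
    fm_row = {
        "IBS": 0.35, "CFS": 0.30, "MD": 0.50, "AD": 0.45,
        "RA": 0.0, "IBD": 0.10, "GRA": 0.10, "HASH": 0.25, "PoRh": 0.10,
        "BP": 0.50, "MIG": 0.45, "SD": 0.50,
    }
    for other, r in fm_row.items():
        rg.loc["FM", other] = rg.loc[other, "FM"] = r
    # the RA-like architecture is strictly confined to the autoimmune block
    autoimmune = {"RA", "IBD", "GRA", "HASH", "PoRh"}
    for other in names:
        if other not in autoimmune:
            rg.loc["RA", other] = rg.loc[other, "RA"] = 0.0
    arr = rg.to_numpy()
    eig = np.linalg.eigvalsh(arr)
    if eig.min() < 1e-6:
        lam = 1.0 / (1.0 - eig.min() + 1e-6)
        arr = lam * arr + (1 - lam) * np.eye(len(names))
        rg = pd.DataFrame(arr, index=names, columns=names)
    return SimConfig(
        n_families=n_families, disorders=disorders, genetic_correlations=rg, **overrides
    )


def null_profile_config(n_families: int = 150, prevalence: float = 0.08, **overrides) -> SimConfig:
    """Null scenario: 13 disorders with no familial aggregation at all.

    Zero heritability, zero household variance and zero genetic correlation:
    every FGRS is then pure noise, so every group comparison in a profile
    battery is a true null and measures the testing layer's type-I error.
    """
    cfg = profile_scenario_config(n_families=n_families, prevalence=prevalence, **overrides)
    cfg.disorders = [replace(d, h2=0.0, c2=0.0) for d in cfg.disorders]
    names = cfg.disorder_names
    cfg.genetic_correlations = pd.DataFrame(
        np.eye(len(names)), index=names, columns=names
    )
    return cfg


@dataclass
class SimResult:
    pedigree: Pedigree
    events: pd.DataFrame
    truth: pd.DataFrame
    proband_ids: list[str]
    config: SimConfig


# -- pedigree structure ------------------------------------------------------


class _Builder:
    """Accumulates one simulated population; persons indexed globally."""

    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.person_id: list[str] = []
        self.father: list[int] = []
        self.mother: list[int] = []
        self.sex: list[str] = []
        self.birth: list[int] = []
        self.generation: list[int] = []
        self.spells: list[tuple[int, str, int, int]] = []  # person, hh, start, end
        self._spell_idx: dict[int, list[int]] = {}
        self.exposures: list[list[str]] = []  # households contributing C
        self._hh_counter = 0
        self._fam = 0

    def new_person(self, sex: str, birth: int, gen: int, fa: int = -1, mo: int = -1) -> int:
        i = len(self.person_id)
        self.person_id.append(f"F{self._fam:05d}P{i:06d}")
        self.father.append(fa)
        self.mother.append(mo)
        self.sex.append(sex)
        self.birth.append(int(birth))
        self.generation.append(gen)
        self.exposures.append([])
        return i

    def add_spell(self, person: int, hh: str, start: int, end: int) -> None:
        self._spell_idx.setdefault(person, []).append(len(self.spells))
        self.spells.append((person, hh, start, end))

    def new_household(self) -> str:
        self._hh_counter += 1
        return f"H{self._hh_counter:07d}"

    def nuclear_family(
        self, fa: int, mo: int, child_births: list[int], gen: int,
        father_present: bool = True,
    ) -> tuple[list[int], str]:
        """Create children of a couple plus the shared household and spells."""
        rng = self.rng
        hh = self.new_household()
        children = []
        sexes = rng.random(len(child_births)) < 0.5
        for b, is_f in zip(child_births, sexes):
            c = self.new_person(FEMALE if is_f else MALE, b, gen, fa, mo)
            children.append(c)
            self.add_spell(c, hh, b, b + 18)
            self.exposures[c].append(hh)
        if children:
            lo = min(child_births)
            hi = max(child_births) + 18
            self._clip_spells(mo, lo)
            self.add_spell(mo, hh, lo, hi)
            self.exposures[mo].append(hh)
            if father_present:
                self._clip_spells(fa, lo)
                self.add_spell(fa, hh, lo, hi)
                self.exposures[fa].append(hh)
        return children, hh

    def _clip_spells(self, person: int, year: int) -> None:
        """Person leaves earlier households at ``year`` (no concurrent spells)."""
        for k in self._spell_idx.get(person, ()):
            p, h, s, e = self.spells[k]
            if e > year:
                self.spells[k] = (p, h, s, min(e, max(s, year)))

    def offspring_births(self, mother_birth: int, n: int) -> list[int]:
        rng = self.rng
        first = mother_birth + int(rng.uniform(22, 32))
        gaps = rng.integers(1, 4, size=max(n - 1, 0))
        births = [first]
        for g in gaps:
            births.append(births[-1] + int(g))
        return births[:n]

    def n_children(self, lineal: bool = False) -> int:
        n = int(self.rng.poisson(self.cfg.mean_offspring))
        n = min(n, self.cfg.max_offspring)
        return max(n, 1) if lineal else n


def _spawn_half_sibs(b: _Builder, fa: int, mo: int, hh: str, gen: int) -> None:
    """Remarriage half-sib branches for one nuclear couple."""
    cfg, rng = b.cfg, b.rng
    if rng.random() < cfg.p_half_sib_paternal:
        # father's second family: separate household (reared apart from
        # the primary children); the father leaves the first household
        partner = b.new_person(FEMALE, b.birth[fa] + int(rng.integers(-3, 4)), gen - 1)
        n = max(1, min(int(rng.poisson(cfg.half_sib_mean_children)), cfg.max_offspring))
        delay = int(rng.integers(3, 8))  # second family starts after the first
        births = [x + delay for x in b.offspring_births(b.birth[partner], n)]
        for k in b._spell_idx.get(fa, ()):
            p, h, s, e = b.spells[k]
            if h == hh:
                b.spells[k] = (p, h, s, min(e, max(s, min(births))))
        b.nuclear_family(fa, partner, births, gen, father_present=True)
    if rng.random() < cfg.p_half_sib_maternal:
        # mother's second partner: same household (maternal half-sibs are
        # reared with the primary children)
        partner = b.new_person(MALE, b.birth[mo] + int(rng.integers(-3, 4)), gen - 1)
        n = max(1, min(int(rng.poisson(cfg.half_sib_mean_children)), cfg.max_offspring))
        first = b.birth[mo] + int(rng.uniform(30, 38))
        births = [first]
        for _ in range(n - 1):
            births.append(births[-1] + int(rng.integers(1, 4)))
        sexes = rng.random(n) < 0.5
        lo, hi = min(births), max(births) + 18
        for x, is_f in zip(births, sexes):
            c = b.new_person(FEMALE if is_f else MALE, x, gen, partner, mo)
            b.add_spell(c, hh, x, x + 18)
            b.exposures[c].append(hh)
        b.add_spell(partner, hh, lo, hi)
        b.exposures[partner].append(hh)


def _collateral_descend(b: _Builder, person: int, gen: int, last_gen: int) -> None:
    """Carry a collateral branch down to the proband generation."""
    if gen >= last_gen:
        return
    rng = b.rng
    spouse_sex = FEMALE if b.sex[person] == MALE else MALE
    spouse = b.new_person(spouse_sex, b.birth[person] + int(rng.integers(-3, 4)), gen)
    n = b.n_children()
    if n == 0:
        return
    mo = person if b.sex[person] == FEMALE else spouse
    fa = spouse if b.sex[person] == FEMALE else person
    births = b.offspring_births(b.birth[mo], n)
    present = rng.random() >= b.cfg.p_father_absent
    children, _hh = b.nuclear_family(fa, mo, births, gen + 1, father_present=present)
    for c in children:
        _collateral_descend(b, c, gen + 1, last_gen)


def _lineal(b: _Builder, gen: int, target_birth: int, sex: str, last_gen: int) -> int:
    """A lineal ancestor at ``gen`` born near ``target_birth`` (recursive)."""
    rng = b.rng
    if gen == 0:
        return b.new_person(sex, target_birth + int(rng.integers(-2, 3)), 0)
    gap = int(rng.uniform(24, 32))
    fa = _lineal(b, gen - 1, target_birth - gap, MALE, last_gen)
    mo = _lineal(b, gen - 1, target_birth - gap + int(rng.integers(-3, 4)), FEMALE, last_gen)
    n = b.n_children(lineal=True)
    births = b.offspring_births(b.birth[mo], n)
    present = rng.random() >= b.cfg.p_father_absent
    children, hh = b.nuclear_family(fa, mo, births, gen, father_present=present)
    _spawn_half_sibs(b, fa, mo, hh, gen)
    # force the lineal child's sex
    lineal_child = children[0]
    b.sex[lineal_child] = sex
    for c in children[1:]:
        _collateral_descend(b, c, gen, last_gen)
    return lineal_child


def build_pedigree_structure(config: SimConfig, rng: np.random.Generator) -> _Builder:
    b = _Builder(config, rng)
    G = config.generations
    lo, hi = config.proband_anchor_years
    for fam in range(config.n_families):
        b._fam = fam
        anchor = int(rng.uniform(lo, hi))
        gap = int(rng.uniform(24, 32))
        fa = _lineal(b, G - 2, anchor - gap, MALE, G - 1)
        mo = _lineal(b, G - 2, anchor - gap + int(rng.integers(-3, 4)), FEMALE, G - 1)
        n = b.n_children(lineal=True)
        births = b.offspring_births(b.birth[mo], n)
        present = rng.random() >= config.p_father_absent
        children, hh = b.nuclear_family(fa, mo, births, G - 1, father_present=present)
        _spawn_half_sibs(b, fa, mo, hh, G - 1)
    return b


# -- phenotypes --------------------------------------------------------------


def _correlation_factor(R: np.ndarray) -> np.ndarray:
    """Factor F with F F' = R, robust to semi-definite R."""
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def _draw_onset_ages(spec: DisorderSimSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    o = spec.onset
    if o["dist"] == "weibull":
        ages = o["scale"] * rng.weibull(o["shape"], size=n)
    elif o["dist"] == "uniform":
        ages = rng.uniform(o["low"], o["high"], size=n)
    else:
        raise ValueError(f"unknown onset distribution {o['dist']!r}")
    return np.maximum(np.rint(ages).astype(int), 0)


def simulate(config: SimConfig, seed: int) -> SimResult:
    """Generate a pedigree, registry events, and the latent truth behind them."""
    rng = np.random.default_rng(seed)
    b = build_pedigree_structure(config, rng)
    n = len(b.person_id)
    names = config.disorder_names
    D = len(names)
    h2 = np.array([d.h2 for d in config.disorders])
    c2 = np.array([d.c2 for d in config.disorders])
    Rg = config.genetic_correlations.to_numpy()
    Fg = _correlation_factor(Rg)

    birth = np.array(b.birth)
    sex = np.array(b.sex)
    father = np.array(b.father)
    mother = np.array(b.mother)
    generation = np.array(b.generation)

    # end of follow-up: death or administrative censoring
    lifespan = rng.normal(config.life_expectancy, config.life_sd, size=n)
    lifespan = np.maximum(np.rint(lifespan).astype(int), 1)
    end = np.minimum(birth + lifespan, config.follow_up_end)
    end = np.maximum(end, birth)  # late-born children: zero follow-up, not negative

    # additive genetic values, generation by generation (parents come first)
    A = np.zeros((n, D))
    sqrt_h = np.sqrt(h2)
    depth = np.where((father >= 0) | (mother >= 0), -1, 0)
    # generation order guarantees parents precede children
    order = np.argsort(generation, kind="stable")
    seg = rng.standard_normal((n, D)) @ Fg.T * sqrt_h  # pre-drawn innovations
    for i in order:
        f, m = father[i], mother[i]
        if f < 0 and m < 0:
            A[i] = seg[i]
        else:
            mid = 0.5 * (A[f] + A[m]) if (f >= 0 and m >= 0) else 0.5 * A[max(f, m)]
            A[i] = mid + seg[i] * math.sqrt(0.5)

    # household environment: mean effect of the households a person was
    # reared in / reared children in, normalized to unit variance
    hh_ids = sorted({hh for _, hh, _, _ in b.spells})
    hh_index = {h: k for k, h in enumerate(hh_ids)}
    U = rng.standard_normal((len(hh_ids), D))
    Cmat = np.zeros((n, D))
    for i in range(n):
        exp = b.exposures[i]
        if exp:
            ks = [hh_index[h] for h in exp]
            Cmat[i] = U[ks].sum(axis=0) / math.sqrt(len(ks))
    Cmat *= np.sqrt(c2)

    E = rng.standard_normal((n, D)) * np.sqrt(np.maximum(1.0 - h2 - c2, 0.0))
    L = A + Cmat + E

    # affection by sex-specific analytic thresholds, registration by onset
    # age reached inside follow-up and inside the register era
    from scipy import stats as _st

    events_rows = []
    affected = np.zeros((n, D), dtype=bool)
    onset_age = np.full((n, D), -1, dtype=int)
    is_female = sex == FEMALE
    for j, spec in enumerate(config.disorders):
        t_f = _st.norm.isf(spec.prevalence_female)
        t_m = _st.norm.isf(spec.prevalence_male)
        t = np.where(is_female, t_f, t_m)
        aff = L[:, j] > t
        affected[:, j] = aff
        idx = np.flatnonzero(aff)
        ages = _draw_onset_ages(spec, len(idx), rng)
        onset_age[idx, j] = ages
        reg_year = birth[idx] + ages
        observable = (reg_year <= end[idx]) & (reg_year >= spec.register_start_year)
        for k, yr in zip(idx[observable], reg_year[observable]):
            events_rows.append((b.person_id[k], spec.name, int(yr)))

    events = pd.DataFrame(events_rows, columns=["person_id", "disorder", "year"])

    persons = pd.DataFrame(
        {
            "person_id": b.person_id,
            "father_id": [b.person_id[f] if f >= 0 else None for f in father],
            "mother_id": [b.person_id[m] if m >= 0 else None for m in mother],
            "sex": sex,
            "birth_year": birth,
            "end_year": end,
        }
    )
    spells = pd.DataFrame(
        [(b.person_id[p], hh, s, min(e, int(end[p]))) for p, hh, s, e in b.spells],
        columns=HOUSEHOLD_COLUMNS,
    )
    spells = spells[spells["end_year"] > spells["start_year"]]
    spells = _merge_spells(spells)

    proband_mask = generation == config.generations - 1
    proband_ids = [b.person_id[i] for i in np.flatnonzero(proband_mask)]

    if config.relative_missingness > 0:
        keep = rng.random(n) >= config.relative_missingness
        keep[proband_mask] = True
        persons = persons[keep].reset_index(drop=True)
        kept = set(persons["person_id"])
        spells = spells[spells["person_id"].isin(kept)]
        events = events[events["person_id"].isin(kept)]

    pedigree = Pedigree(persons[PEDIGREE_COLUMNS], spells.reset_index(drop=True))

    truth = pd.DataFrame({"person_id": b.person_id, "generation": generation})
    for j, name in enumerate(names):
        truth[f"A_{name}"] = A[:, j]
        truth[f"liability_{name}"] = L[:, j]
        truth[f"affected_{name}"] = affected[:, j]
        truth[f"onset_age_{name}"] = onset_age[:, j]
    if config.relative_missingness > 0:
        truth = truth[truth["person_id"].isin(set(pedigree.person_ids))].reset_index(drop=True)

    return SimResult(
        pedigree=pedigree,
        events=events.reset_index(drop=True),
        truth=truth,
        proband_ids=proband_ids,
        config=config,
    )


def _merge_spells(spells: pd.DataFrame) -> pd.DataFrame:
    """Merge a person's overlapping spells in the same household."""
    if not len(spells):
        return spells
    out = []
    for (pid, hh), grp in spells.groupby(["person_id", "household_id"], sort=False):
        grp = grp.sort_values("start_year")
        cur_s, cur_e = None, None
        for s, e in zip(grp["start_year"], grp["end_year"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((pid, hh, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((pid, hh, cur_s, cur_e))
    return pd.DataFrame(out, columns=HOUSEHOLD_COLUMNS)


def summarize_pedigree(
    pedigree: Pedigree, proband_ids: list[str] | None = None, max_degree: int = 5
) -> dict:
    """Relative counts per proband (overall and by degree) plus founder count."""
    if proband_ids is None:
        proband_ids = list(pedigree.person_ids)
    if not len(pedigree):
        raise ValueError("empty pedigree")
    pairs = kinship.relative_pair_table(pedigree, proband_ids, max_degree)
    per = pairs.groupby("proband_id").size().reindex(proband_ids).fillna(0)
    by_degree = (
        pairs.groupby(["proband_id", "degree"]).size().unstack(fill_value=0)
        .reindex(proband_ids).fillna(0)
    )
    founders = int(((pedigree.father_idx < 0) & (pedigree.mother_idx < 0)).sum())
    return {
        "n_probands": len(proband_ids),
        "mean_relatives": float(per.mean()),
        "median_relatives": float(per.median()),
        "mean_by_degree": {int(d): float(by_degree[d].mean()) for d in by_degree.columns},
        "n_founders": founders,
        "n_persons": len(pedigree),
    }
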