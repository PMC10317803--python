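"""Registry-style tables: pedigrees, first-registration events, score matrices.

The pedigree container used throughout the package is :class:`Pedigree`, a
validated, indexed view of a person table (one row per person, with parent
links, sex, birth year and end of follow-up) plus an optional household-spell
table recording who lived in which household in which years.  All dates are
held at year resolution: every analysis in this package operates on years of
birth and first registration.

File formats are plain TSV.  The native pedigree schema is::

    person_id  father_id  mother_id  sex  birth_year  end_year

with sex spelled ``female``/``male`` and missing parents as an empty field.
A PLINK ``.fam``-compatible reader is provided for pedigree interchange
(columns FID IID father mother sex phenotype; sex 1=male, 2=female; missing
parent ``0``; the phenotype column is ignored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("fgrs")

FEMALE = "female"
MALE = "male"

PEDIGREE_COLUMNS = ["person_id", "father_id", "mother_id", "sex", "birth_year", "end_year"]
HOUSEHOLD_COLUMNS = ["person_id", "household_id", "start_year", "end_year"]
EVENT_COLUMNS = ["person_id", "disorder", "year"]


@dataclass(frozen=True)
class Person:
    """A single registry person.

    ``end_year`` is the end of follow-up: death, emigration or administrative
    censoring, whichever comes first.  ``household_spells`` lists
    ``(household_id, start_year, end_year)`` tuples, non-overlapping in time.
    """

    person_id: str
    father_id: str | None
    mother_id: str | None
    sex: str
    birth_year: int
    end_year: int
    household_spells: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"sex must be '{FEMALE}' or '{MALE}', got {self.sex!r}")
        if self.birth_year > self.end_year:
            raise ValueError(
                f"person {self.person_id}: birth_year {self.birth_year} > end_year {self.end_year}"
            )
        if self.person_id in (self.father_id, self.mother_id):
            raise ValueError(f"person {self.person_id} listed as its own parent")


@dataclass(frozen=True)
class DiagnosisEvent:
    """First registration of a disorder for a person (year resolution)."""

    person_id: str
    disorder: str
    year: int


@dataclass(frozen=True)
class DisorderConfig:
    """A disorder as defined for scoring: name, diagnosis codes, register era, class.

    ``register_start_year`` is the first calendar year in which the relevant
    code era is observable (for most disorders here, the start of the ICD-10
    era).  ``disorder_class`` groups disorders for profile displays:
    functional somatic (``fsd``), ``internalizing``, ``autoimmune``, ``pain``
    or ``sleep``.
    """

    name: str
    code_set: tuple[str, ...] = ()
    register_start_year: int = 1997
    disorder_class: str = "fsd"

    _CLASSES = ("fsd", "internalizing", "autoimmune", "pain", "sleep")

    def __post_init__(self) -> None:
        if self.disorder_class not in self._CLASSES:
            raise ValueError(
                f"disorder class {self.disorder_class!r} not in {self._CLASSES}"
            )
        if not 1850 <= self.register_start_year <= 2100:
            raise ValueError(f"implausible register_start_year {self.register_start_year}")


class PedigreeError(ValueError):
    pass


class Pedigree:
    """Validated pedigree: person table + optional household spells.

    Parameters
    ----------
    persons
        DataFrame with the native pedigree columns.  Parent ids that do not
        appear as persons are treated as external founders (recorded in
        ``external_parents``) and the link is dropped.
    households
        Optional DataFrame with columns person_id, household_id, start_year,
        end_year.
    """

    def __init__(self, persons: pd.DataFrame, households: pd.DataFrame | None = None):
        persons = persons.reset_index(drop=True).copy()
        missing = [c for c in PEDIGREE_COLUMNS if c not in persons.columns]
        if missing:
            raise PedigreeError(f"pedigree table missing columns {missing}")
        ids = persons["person_id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise PedigreeError(f"duplicate person_id(s): {sorted(set(dup))[:5]}")
        persons["person_id"] = ids
        for col in ("father_id", "mother_id"):
            persons[col] = (
                persons[col]
                .astype(object)
                .where(persons[col].notna(), None)
                .map(lambda v: None if v in (None, "", "0") else str(v))
            )
        bad_sex = ~persons["sex"].isin([FEMALE, MALE])
        if bad_sex.any():
            raise PedigreeError(
                f"invalid sex values: {sorted(persons.loc[bad_sex, 'sex'].unique())}"
            )
        persons["birth_year"] = persons["birth_year"].astype(int)
        persons["end_year"] = persons["end_year"].astype(int)
        if (persons["birth_year"] > persons["end_year"]).any():
            bad = persons.loc[persons["birth_year"] > persons["end_year"], "person_id"]
            raise PedigreeError(f"birth_year > end_year for {list(bad[:5])}")
        self_parent = (persons["person_id"] == persons["father_id"]) | (
            persons["person_id"] == persons["mother_id"]
        )
        if self_parent.any():
            pid = persons.loc[self_parent, "person_id"].iloc[0]
            raise PedigreeError(f"cyclic parentage: {pid} is its own parent")

        self.persons = persons
        self._index = {pid: i for i, pid in enumerate(persons["person_id"])}

        known = set(self._index)
        self.external_parents: set[str] = set()
        fa_idx = np.full(len(persons), -1, dtype=np.int64)
        mo_idx = np.full(len(persons), -1, dtype=np.int64)
        for i, (f, m) in enumerate(zip(persons["father_id"], persons["mother_id"])):
            if f is not None:
                if f in known:
                    fa_idx[i] = self._index[f]
                else:
                    self.external_parents.add(f)
            if m is not None:
                if m in known:
                    mo_idx[i] = self._index[m]
                else:
                    self.external_parents.add(m)
        self.father_idx = fa_idx
        self.mother_idx = mo_idx

        self._check_acyclic()
        self.depth = self._compute_depth()
        self.component = self._compute_components()

        if households is None:
            households = pd.DataFrame(columns=HOUSEHOLD_COLUMNS)
        households = households.reset_index(drop=True).copy()
        missing = [c for c in HOUSEHOLD_COLUMNS if c not in households.columns]
        if missing:
            raise PedigreeError(f"household table missing columns {missing}")
        if len(households):
            households["person_id"] = households["person_id"].astype(str)
            unknown = set(households["person_id"]) - known
            if unknown:
                raise PedigreeError(f"household spells for unknown persons {sorted(unknown)[:5]}")
            self._check_spells(households)
        self.households = households

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_persons(cls, persons: Iterable[Person]) -> "Pedigree":
        rows, hh = [], []
        for p in persons:
            rows.append(
                (p.person_id, p.father_id, p.mother_id, p.sex, p.birth_year, p.end_year)
            )
            for hid, s, e in p.household_spells:
                hh.append((p.person_id, hid, s, e))
        return cls(
            pd.DataFrame(rows, columns=PEDIGREE_COLUMNS),
            pd.DataFrame(hh, columns=HOUSEHOLD_COLUMNS) if hh else None,
        )

    # -- validation -----------------------------------------------------------

    def _check_acyclic(self) -> None:
        n = len(self.persons)
        state = np.zeros(n, dtype=np.int8)  # 0 unseen, 1 in-stack, 2 done
        for start in range(n):
            if state[start]:
                continue
            stack = [(start, 0)]
            while stack:
                node, phase = stack.pop()
                if phase == 0:
                    if state[node] == 1:
                        continue
                    state[node] = 1
                    stack.append((node, 1))
                    for par in (self.father_idx[node], self.mother_idx[node]):
                        if par >= 0:
                            if state[par] == 1:
                                a = self.persons["person_id"].iloc[node]
                                b = self.persons["person_id"].iloc[par]
                                raise PedigreeError(
                                    f"cyclic parentage involving {b} and {a}"
                                )
                            if state[par] == 0:
                                stack.append((par, 0))
                else:
                    state[node] = 2

    def _compute_depth(self) -> np.ndarray:
        """Generation depth: 0 for founders, 1 + max(parent depth) otherwise."""
        n = len(self.persons)
        depth = np.full(n, -1, dtype=np.int64)
        order = []
        indeg = (self.father_idx >= 0).astype(int) + (self.mother_idx >= 0).astype(int)
        children: dict[int, list[int]] = {}
        for i in range(n):
            for par in (self.father_idx[i], self.mother_idx[i]):
                if par >= 0:
                    children.setdefault(par, []).append(i)
        queue = [i for i in range(n) if indeg[i] == 0]
        depth[queue] = 0
        while queue:
            node = queue.pop()
            order.append(node)
            for ch in children.get(node, ()):
                indeg[ch] -= 1
                d = max(depth[self.father_idx[ch]] if self.father_idx[ch] >= 0 else -1,
                        depth[self.mother_idx[ch]] if self.mother_idx[ch] >= 0 else -1)
                if indeg[ch] == 0:
                    depth[ch] = d + 1
                    queue.append(ch)
        self._topo_order = np.array(order, dtype=np.int64)
        return depth

    def _compute_components(self) -> np.ndarray:
        """Connected components over parent-child edges (union-find)."""
        n = len(self.persons)
        parent = np.arange(n)

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for par in (self.father_idx[i], self.mother_idx[i]):
                if par >= 0:
                    ra, rb = find(i), find(int(par))
                    if ra != rb:
                        parent[ra] = rb
        roots = np.array([find(i) for i in range(n)])
        _, labels = np.unique(roots, return_inverse=True)
        return labels

    @staticmethod
    def _check_spells(households: pd.DataFrame) -> None:
        for pid, grp in households.groupby("person_id"):
            spans = sorted(zip(grp["start_year"], grp["end_year"]))
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise PedigreeError(
                        f"overlapping household spells for person {pid}"
                    )

    # -- access ---------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.persons)

    def __contains__(self, person_id: str) -> bool:
        return person_id in self._index

    @property
    def person_ids(self) -> pd.Series:
        return self.persons["person_id"]

    def index_of(self, person_id: str) -> int:
        try:
            return self._index[person_id]
        except KeyError:
            raise KeyError(f"unknown person_id {person_id!r}") from None

    def person(self, person_id: str) -> Person:
        row = self.persons.iloc[self.index_of(person_id)]
        spells = self.households[self.households["person_id"] == person_id]
        return Person(
            person_id=row["person_id"],
            father_id=row["father_id"],
            mother_id=row["mother_id"],
            sex=row["sex"],
            birth_year=int(row["birth_year"]),
            end_year=int(row["end_year"]),
            household_spells=tuple(
                (r.household_id, int(r.start_year), int(r.end_year))
                for r in spells.itertuples()
            ),
        )


# -- pedigree files ---------------------------------------------------------


def read_pedigree(
    path: str | Path,
    dialect: str = "native_tsv",
    households_path: str | Path | None = None,
) -> Pedigree:
    """Read a pedigree file in the native TSV or PLINK .fam-compatible dialect."""
    path = Path(path)
    if dialect == "native_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"person_id": str, "father_id": str, "mother_id": str})
    elif dialect == "fam_compatible":
        raw = pd.read_csv(
            path, sep=r"\s+", header=None,
            names=["fid", "person_id", "father_id", "mother_id", "sex_code", "phenotype"],
            dtype=str,
        )
        sex_map = {"1": MALE, "2": FEMALE}
        bad = ~raw["sex_code"].isin(sex_map)
        if bad.any():
            raise PedigreeError(
                f"fam sex codes must be 1/2, got {sorted(raw.loc[bad, 'sex_code'].unique())}"
            )
        df = pd.DataFrame(
            {
                "person_id": raw["person_id"],
                "father_id": raw["father_id"].replace("0", None),
                "mother_id": raw["mother_id"].replace("0", None),
                "sex": raw["sex_code"].map(sex_map),
                "birth_year": 0,
                "end_year": 0,
            }
        )
    else:
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    hh = None
    if households_path is not None:
        hh = pd.read_csv(households_path, sep="\t", dtype={"person_id": str, "household_id": str})
    return Pedigree(df, hh)


def write_pedigree(pedigree: Pedigree, path: str | Path, households_path: str | Path | None = None) -> None:
    df = pedigree.persons[PEDIGREE_COLUMNS].copy()
    df.to_csv(path, sep="\t", index=False)
    if households_path is not None:
        pedigree.households.to_csv(households_path, sep="\t", index=False)


# -- event files ------------------------------------------------------------


def read_events(
    path: str | Path,
    disorders: Sequence[str] | None = None,
    pedigree: Pedigree | None = None,
) -> pd.DataFrame:
    """Read first-registration events; collapse duplicates to the earliest year.

    Rows whose disorder is not in ``disorders`` (when given) raise; rows dated
    before the person's birth (when a pedigree is given) are rejected with a
    warning.  Returns a DataFrame with columns person_id, disorder, year.
    """
    df = pd.read_csv(path, sep="\t", dtype={"person_id": str, "disorder": str})
    if not len(df):
        return pd.DataFrame(columns=EVENT_COLUMNS)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    df["year"] = df["year"].astype(int)
    if disorders is not None:
        known = set(disorders)
        unknown = set(df["disorder"]) - known
        if unknown:
            raise ValueError(
                f"unknown disorder(s) {sorted(unknown)}; known: {sorted(known)}"
            )
    if pedigree is not None:
        birth = pedigree.persons.set_index("person_id")["birth_year"]
        b = df["person_id"].map(birth)
        bad = df["year"] < b
        if bad.any():
            logger.warning("rejected %d event row(s) dated before birth", int(bad.sum()))
            df = df[~bad]
    n_before = len(df)
    df = df.sort_values("year", kind="stable").drop_duplicates(["person_id", "disorder"], keep="first")
    n_dup = n_before - len(df)
    if n_dup:
        logger.warning("collapsed %d duplicate (person, disorder) event row(s)", n_dup)
    return df.reset_index(drop=True)[EVENT_COLUMNS]


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


# -- score files ------------------------------------------------------------


def write_scores(matrix, path: str | Path) -> None:
    """Write an FGRS matrix (probands x disorders) as TSV with full precision."""
    scores: pd.DataFrame = getattr(matrix, "scores", matrix)
    out = scores.copy()
    out.index.name = "proband_id"
    # default float formatting is the shortest round-trippable repr
    out.to_csv(path, sep="\t")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", index_col="proband_id", dtype={"proband_id": str},
        float_precision="round_trip",
    )


# -- configuration ----------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def disorder_configs_from_mapping(mapping: dict) -> dict[str, DisorderConfig]:
    """Build DisorderConfig objects from a ``disorders:`` config section."""
    out = {}
    for name, spec in mapping.items():
        spec = spec or {}
        out[name] = DisorderConfig(
            name=name,
            code_set=tuple(spec.get("codes", ())),
            register_start_year=int(spec.get("register_start_year", 1997)),
            disorder_class=spec.get("class", spec.get("disorder_class", "fsd")),
        )
    return out
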