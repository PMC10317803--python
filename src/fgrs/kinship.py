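"""Relatives of a proband: relatedness coefficients, degree, cohabitation.

Relatedness here is the expected proportion of genes shared identical by
descent between two outbred relatives (the numerator relationship, twice the
kinship coefficient): 0.5 for first-degree relatives, halving with each
degree, and summing over all distinct genealogical paths (so double first
cousins score 0.25).  It is computed with the tabular method on each
connected pedigree component; a Monte-Carlo gene-dropping estimator is
provided as an independent check.

Degree is bookkeeping derived from total relatedness,
``round(-log2(relatedness))``, so a multi-path relative is assigned the
degree its total gene sharing implies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_registry import Pedigree

RELATEDNESS_EPS = 1e-12


@dataclass(frozen=True)
class RelativePair:
    """One proband-relative pair with its genetic and household relationship.

    ``cohabited`` is True when the pair ever shared a household during the
    overlap with the proband's ages 0-15; ``reared_by`` applies to
    parent-offspring pairs only and marks parents who lived in the child's
    household during upbringing.  ``None`` means "unknown" (no household
    data), which downstream scoring treats conservatively as reared.
    """

    proband_id: str
    relative_id: str
    relatedness: float
    degree: int
    relation_label: str
    cohabited: bool | None = None
    reared_by: bool | None = None


def relationship_matrix(pedigree: Pedigree, member_idx: np.ndarray) -> np.ndarray:
    """Additive (numerator) relationship matrix for one pedigree component.

    ``member_idx`` must be closed under parentage within the pedigree.
    Diagonal entries are 1 + F (inbreeding); off-diagonal entries are the
    relatedness coefficients.
    """
    pos = {int(g): i for i, g in enumerate(member_idx)}
    depth = pedigree.depth[member_idx]
    order = np.argsort(depth, kind="stable")
    n = len(member_idx)
    A = np.zeros((n, n))
    fa = pedigree.father_idx[member_idx]
    mo = pedigree.mother_idx[member_idx]
    for i in order:
        f = pos.get(int(fa[i]), -1) if fa[i] >= 0 else -1
        m = pos.get(int(mo[i]), -1) if mo[i] >= 0 else -1
        if f >= 0 and m >= 0:
            A[i, :] = 0.5 * (A[f, :] + A[m, :])
            self_val = 1.0 + 0.5 * A[f, m]
        elif f >= 0:
            A[i, :] = 0.5 * A[f, :]
            self_val = 1.0
        elif m >= 0:
            A[i, :] = 0.5 * A[m, :]
            self_val = 1.0
        else:
            A[i, :] = 0.0
            self_val = 1.0
        A[:, i] = A[i, :]
        A[i, i] = self_val
    return A


def _degree(relatedness: float) -> int:
    return int(round(-np.log2(relatedness)))


def relation_label(pedigree: Pedigree, proband_id: str, relative_id: str) -> str:
    """Structural label for close relationships; 'other' beyond the classics."""
    i = pedigree.index_of(proband_id)
    j = pedigree.index_of(relative_id)
    fa, mo = pedigree.father_idx, pedigree.mother_idx

    def parents(k):
        return {int(p) for p in (fa[k], mo[k]) if p >= 0}

    pi, pj = parents(i), parents(j)
    if j in pi:
        return "parent"
    if i in pj:
        return "offspring"
    if pi and pi == pj:
        return "full_sib"
    if pi & pj:
        return "half_sib"
    gpi = {g for p in pi for g in parents(p)}
    gpj = {g for p in pj for g in parents(p)}
    if j in gpi:
        return "grandparent"
    if i in gpj:
        return "grandchild"
    # aunt/uncle: j is a sibling (full or half) of a parent of i
    for p in pi:
        if parents(p) and parents(p) & pj:
            return "aunt_uncle"
    for p in pj:
        if parents(p) and parents(p) & pi:
            return "niece_nephew"
    # first cousins: parents are siblings
    for p in pi:
        for q in pj:
            if parents(p) and parents(p) & parents(q):
                return "cousin"
    return "other"


def enumerate_relatives(
    pedigree: Pedigree,
    proband_id: str,
    max_degree: int = 5,
    classify_households: bool = True,
) -> list[RelativePair]:
    """All relatives of ``proband_id`` with degree <= ``max_degree``.

    Each relative appears once, with relatedness summed over every connecting
    genealogical path (tabular method over the proband's pedigree component).
    """
    i = pedigree.index_of(proband_id)
    comp = pedigree.component[i]
    member_idx = np.flatnonzero(pedigree.component == comp)
    A = relationship_matrix(pedigree, member_idx)
    pos = int(np.searchsorted(member_idx, i))
    ids = pedigree.person_ids.to_numpy()
    pairs: list[RelativePair] = []
    for k, g in enumerate(member_idx):
        if k == pos:
            continue
        r = float(A[pos, k])
        if r <= RELATEDNESS_EPS:
            continue
        deg = _degree(r)
        if deg > max_degree:
            continue
        rel_id = str(ids[g])
        pair = RelativePair(
            proband_id=proband_id,
            relative_id=rel_id,
            relatedness=r,
            degree=deg,
            relation_label=relation_label(pedigree, proband_id, rel_id),
        )
        if classify_households:
            pair = classify_cohabitation(pedigree, pair)
        pairs.append(pair)
    return pairs


def relative_pair_table(
    pedigree: Pedigree,
    proband_ids: list[str] | np.ndarray,
    max_degree: int = 5,
) -> pd.DataFrame:
    """Vectorized proband-relative enumeration for many probands.

    Returns columns proband_id, relative_id, relatedness, degree plus the
    structural flags needed for cohabitation correction: ``is_parent``
    (relative is the proband's parent), ``is_offspring``, ``is_full_sib``.
    Cohabitation itself is filled in by :func:`cohabitation_flags`.
    """
    ids = pedigree.person_ids.to_numpy()
    idx = np.array([pedigree.index_of(p) for p in proband_ids], dtype=np.int64)
    fa, mo = pedigree.father_idx, pedigree.mother_idx
    out = []
    comp_of = pedigree.component
    for comp in np.unique(comp_of[idx]):
        member_idx = np.flatnonzero(comp_of == comp)
        A = relationship_matrix(pedigree, member_idx)
        pos_of = {int(g): k for k, g in enumerate(member_idx)}
        pro_here = idx[comp_of[idx] == comp]
        for g in pro_here:
            k = pos_of[int(g)]
            row = A[k].copy()
            row[k] = 0.0
            keep = np.flatnonzero(row > RELATEDNESS_EPS)
            r = row[keep]
            deg = np.rint(-np.log2(r)).astype(int)
            sel = deg <= max_degree
            keep, r, deg = keep[sel], r[sel], deg[sel]
            rel_global = member_idx[keep]
            pg = int(g)
            par_p = {int(x) for x in (fa[pg], mo[pg]) if x >= 0}
            is_parent = np.isin(rel_global, list(par_p)) if par_p else np.zeros(len(rel_global), bool)
            is_offspring = (fa[rel_global] == pg) | (mo[rel_global] == pg)
            full_sib = np.zeros(len(rel_global), bool)
            if len(par_p) == 2:
                full_sib = (
                    (fa[rel_global] == fa[pg]) & (mo[rel_global] == mo[pg])
                    & (fa[rel_global] >= 0) & (mo[rel_global] >= 0)
                )
            out.append(
                pd.DataFrame(
                    {
                        "proband_id": ids[pg],
                        "relative_id": ids[rel_global],
                        "relatedness": r,
                        "degree": deg,
                        "is_parent": is_parent,
                        "is_offspring": is_offspring,
                        "is_full_sib": full_sib,
                    }
                )
            )
    if not out:
        return pd.DataFrame(
            columns=[
                "proband_id", "relative_id", "relatedness", "degree",
                "is_parent", "is_offspring", "is_full_sib",
            ]
        )
    return pd.concat(out, ignore_index=True)


def write_relative_pairs(pairs: list[RelativePair], path) -> None:
    """Export enumerated relative pairs as TSV for inspection."""
    pd.DataFrame(
        [
            (p.proband_id, p.relative_id, p.relatedness, p.degree,
             p.relation_label, p.cohabited, p.reared_by)
            for p in pairs
        ],
        columns=["proband_id", "relative_id", "relatedness", "degree",
                 "relation_label", "cohabited", "reared_by"],
    ).to_csv(path, sep="\t", index=False)


# -- cohabitation ------------------------------------------------------------


def _shared_years(sp_a, sp_b, lo: int, hi: int) -> int:
    """Years both spell lists share the same household inside [lo, hi]."""
    total = 0
    for hid_a, s_a, e_a in sp_a:
        for hid_b, s_b, e_b in sp_b:
            if hid_a != hid_b:
                continue
            s = max(s_a, s_b, lo)
            e = min(e_a, e_b, hi)
            if e > s:
                total += e - s
    return total


def classify_cohabitation(
    pedigree: Pedigree, pair: RelativePair, min_reared_years: int = 1
) -> RelativePair:
    """Fill the cohabited / reared_by flags of a pair from household spells.

    Cohabitation is shared household membership during the proband's ages
    0-15.  With no household data at all the flags stay ``None`` (unknown),
    which scoring treats as reared — the conservative choice, since the
    cohabitation factor only ever shrinks contributions.
    """
    if not len(pedigree.households):
        return pair
    hh = pedigree.households
    sp_p = [
        (r.household_id, int(r.start_year), int(r.end_year))
        for r in hh[hh["person_id"] == pair.proband_id].itertuples()
    ]
    sp_r = [
        (r.household_id, int(r.start_year), int(r.end_year))
        for r in hh[hh["person_id"] == pair.relative_id].itertuples()
    ]
    birth = int(pedigree.persons["birth_year"].iloc[pedigree.index_of(pair.proband_id)])
    shared = _shared_years(sp_p, sp_r, birth, birth + 15)
    cohabited = shared >= 1
    reared_by = None
    if pair.relation_label in ("parent", "offspring"):
        if pair.relation_label == "parent":
            child_birth = birth
            sp_child, sp_parent = sp_p, sp_r
        else:
            child_birth = int(
                pedigree.persons["birth_year"].iloc[pedigree.index_of(pair.relative_id)]
            )
            sp_child, sp_parent = sp_r, sp_p
        reared_by = (
            _shared_years(sp_child, sp_parent, child_birth, child_birth + 15)
            >= min_reared_years
        )
    return replace(pair, cohabited=cohabited, reared_by=reared_by)


def cohabitation_flags(
    pedigree: Pedigree, pairs: pd.DataFrame, min_reared_years: int = 1
) -> pd.DataFrame:
    """Vectorized cohabitation classification for a relative-pair table.

    Adds a ``cohabited`` column: for parent/offspring pairs, True means the
    parent lived in the child's household for at least ``min_reared_years``
    of the child's ages 0-15; for other pairs, shared household during the
    proband's ages 0-15.  Without household data everything is flagged True
    (unknown-as-reared).
    """
    pairs = pairs.copy()
    if not len(pedigree.households) or not len(pairs):
        pairs["cohabited"] = True
        return pairs
    hh = pedigree.households
    birth = pedigree.persons.set_index("person_id")["birth_year"]

    # the child of the pair: the proband, unless the relative is the offspring
    child = np.where(pairs["is_offspring"], pairs["relative_id"], pairs["proband_id"])
    other = np.where(pairs["is_offspring"], pairs["proband_id"], pairs["relative_id"])
    key = pd.DataFrame({"child": child, "other": other})
    key["lo"] = key["child"].map(birth)
    key["hi"] = key["lo"] + 15
    key["row"] = np.arange(len(key))

    a = key.merge(hh, left_on="child", right_on="person_id")
    b = a.merge(hh, left_on=["other", "household_id"], right_on=["person_id", "household_id"],
                suffixes=("_c", "_o"))
    if not len(b):
        pairs["cohabited"] = False
        return pairs
    s = np.maximum.reduce([b["start_year_c"], b["start_year_o"], b["lo"]])
    e = np.minimum.reduce([b["end_year_c"], b["end_year_o"], b["hi"]])
    b["shared"] = np.maximum(e - s, 0)
    shared = b.groupby("row")["shared"].sum()
    years = np.zeros(len(pairs))
    years[shared.index] = shared.to_numpy()
    is_po = (pairs["is_parent"] | pairs["is_offspring"]).to_numpy()
    pairs["cohabited"] = np.where(is_po, years >= min_reared_years, years >= 1)
    return pairs


# -- gene-dropping oracle ----------------------------------------------------


def relatedness_gene_dropping_oracle(
    pedigree: Pedigree,
    id_a: str,
    id_b: str,
    n_reps: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Monte-Carlo relatedness: drop one biallelic locus through the pedigree.

    Founders receive unique allele labels; each child inherits one random
    allele from each parent.  The estimate is twice the kinship coefficient
    (the probability a random allele from each is identical by descent).
    Returns (estimate, standard error).
    """
    if n_reps < 10_000:
        raise ValueError("n_reps must be >= 10^4 for a usable oracle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ia, ib = pedigree.index_of(id_a), pedigree.index_of(id_b)
    n = len(pedigree)
    order = pedigree._topo_order
    alleles = np.zeros((n, 2, n_reps), dtype=np.int32)
    next_label = 1
    for node in order:
        f, m = pedigree.father_idx[node], pedigree.mother_idx[node]
        if f >= 0:
            pick = rng.integers(0, 2, n_reps)
            alleles[node, 0] = alleles[f, pick, np.arange(n_reps)]
        else:
            alleles[node, 0] = next_label
            next_label += 1
        if m >= 0:
            pick = rng.integers(0, 2, n_reps)
            alleles[node, 1] = alleles[m, pick, np.arange(n_reps)]
        else:
            alleles[node, 1] = next_label
            next_label += 1
    a, b = alleles[ia], alleles[ib]
    share = np.zeros(n_reps)
    for i in range(2):
        for j in range(2):
            share += a[i] == b[j]
    share /= 4.0  # kinship realization per replicate
    est = 2.0 * share.mean()
    se = 2.0 * share.std(ddof=1) / np.sqrt(n_reps)
    return float(est), float(se)
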