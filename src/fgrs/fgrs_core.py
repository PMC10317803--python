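"""The family genetic risk score: per-proband aggregation of relatives' status.

For each proband and disorder, every 1st-5th degree relative contributes the
product of four components:

* ``z`` — the relative's liability z-score (sex- and birth-decade-specific
  conditional mean liability given registration status),
* ``w`` — the time-at-risk weight (1 if affected, else the completed
  fraction of the observable onset distribution),
* ``r`` — the relatedness coefficient (expected proportion of shared genes),
* ``c`` — a cohabitation correction in (0, 1] applied to cohabiting
  first-degree relatives, calibrated from the resemblance of reared-apart
  versus reared-together pairs, so that shared-household signal is stripped
  from the genetic score.

The proband's raw score is the weighted mean sum(z*w*r*c)/sum(w*r); an
empirical-Bayes reliability factor var_b/(var_b + var_w/n_w) shrinks scores
of probands with little relative information toward 0; finally scores are
standardized to mean 0, s.d. 1 within year of birth, which also absorbs
register-coverage differences across cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_registry import DisorderConfig, Pedigree
from . import kinship
from .liability import (
    birth_decade,
    estimate_onset_cdf,
    estimate_thresholds,
    threshold_from_prevalence,
    time_at_risk_weight,
)

logger = logging.getLogger("fgrs")

VAR_BETWEEN_FLOOR = 1e-6


@dataclass
class ScoreOptions:
    """Knobs of the scoring pipeline; defaults reproduce the full model."""

    max_degree: int = 5
    cohabitation_correction: bool = True
    shrinkage: bool = True
    min_reared_years: int = 1
    standardize_min_cell: int = 2
    exclude_relative_disorders: tuple[str, ...] = ()
    # "events": excluded disorders' registrations are ignored in relatives'
    # contributions; "relatives": relatives carrying such a registration are
    # dropped from every proband's relative set.
    exclude_mode: str = "events"


@dataclass
class CohabitationFactors:
    """Correction factors for cohabiting first-degree relatives of one disorder.

    Each factor is resemblance(reared apart) / resemblance(reared together),
    clipped to [0, 1]; 1 means no correction (including every degenerate
    case: missing pair class, non-positive reared resemblance).
    """

    disorder: str
    parent_offspring_factor: float = 1.0
    sibling_factor: float = 1.0
    parent_offspring_se: float = float("nan")
    sibling_se: float = float("nan")
    n_po_reared: int = 0
    n_po_apart: int = 0
    n_sib_reared: int = 0
    n_sib_apart: int = 0


@dataclass
class FGRSMatrix:
    """Standardized family genetic risk scores: probands x disorders."""

    scores: pd.DataFrame                 # index proband_id, one column per disorder
    birth_years: pd.Series               # per proband
    metadata: dict = field(default_factory=dict)

    @property
    def disorders(self) -> list[str]:
        return list(self.scores.columns)


# -- tetrachoric resemblance -------------------------------------------------


def tetrachoric_correlation(n11: int, n10: int, n01: int, n00: int) -> float:
    """Tetrachoric correlation from a 2x2 affection table.

    Thresholds come from the table margins; the correlation is the value for
    which the bivariate-normal upper-orthant probability matches the observed
    both-affected fraction.  Returns NaN for degenerate tables (zero margin).
    """
    n = n11 + n10 + n01 + n00
    if n == 0:
        return float("nan")
    p1 = (n11 + n10) / n
    p2 = (n11 + n01) / n
    p11 = n11 / n
    if min(p1, p2) <= 0 or max(p1, p2) >= 1:
        return float("nan")
    t1 = threshold_from_prevalence(p1)
    t2 = threshold_from_prevalence(p2)

    def orthant(rho: float) -> float:
        cov = [[1.0, rho], [rho, 1.0]]
        # P(X > t1, Y > t2) by symmetry of the bivariate normal
        return float(
            stats.multivariate_normal.cdf([-t1, -t2], mean=[0.0, 0.0], cov=cov)
        )

    def f(rho: float) -> float:
        return orthant(rho) - p11

    lo, hi = -0.999, 0.999
    try:
        if f(lo) * f(hi) > 0:
            return float("nan")
        return float(optimize.brentq(f, lo, hi, xtol=1e-6))
    except Exception:
        return float("nan")


def _pair_affection_table(
    pairs: pd.DataFrame, affected: set[str], col_a: str, col_b: str
) -> tuple[int, int, int, int]:
    a = pairs[col_a].isin(affected).to_numpy()
    b = pairs[col_b].isin(affected).to_numpy()
    return (
        int((a & b).sum()),
        int((a & ~b).sum()),
        int((~a & b).sum()),
        int((~a & ~b).sum()),
    )


def parent_offspring_pairs(pedigree: Pedigree, parent_sex: str | None = "male") -> pd.DataFrame:
    """(parent_id, child_id, reared) pairs; ``reared`` from household spells.

    By default only father-offspring pairs are returned, mirroring the
    calibration on pairs where the father sired and raised his child versus
    sired but never lived with them.
    """
    persons = pedigree.persons
    ids = persons["person_id"].to_numpy()
    rows = []
    for parent_col in ("father_id", "mother_id"):
        sex = "male" if parent_col == "father_id" else "female"
        if parent_sex is not None and sex != parent_sex:
            continue
        has = persons[parent_col].notna() & persons[parent_col].isin(set(ids))
        rows.append(
            pd.DataFrame(
                {"parent_id": persons.loc[has, parent_col], "child_id": persons.loc[has, "person_id"]}
            )
        )
    if not rows:
        return pd.DataFrame(columns=["parent_id", "child_id", "reared"])
    po = pd.concat(rows, ignore_index=True)
    flags = kinship.cohabitation_flags(
        pedigree,
        po.rename(columns={"parent_id": "relative_id", "child_id": "proband_id"}).assign(
            is_parent=True, is_offspring=False, is_full_sib=False
        ),
    )
    po["reared"] = flags["cohabited"].to_numpy()
    return po


def half_sib_pairs(pedigree: Pedigree) -> pd.DataFrame:
    """(id_a, id_b, reared) for all half-sib pairs (exactly one shared parent)."""
    persons = pedigree.persons
    rows = []
    for parent_col in ("father_id", "mother_id"):
        other_col = "mother_id" if parent_col == "father_id" else "father_id"
        sub = persons[persons[parent_col].notna()]
        for _, grp in sub.groupby(parent_col):
            if len(grp) < 2:
                continue
            recs = grp[["person_id", other_col]].to_numpy()
            for i in range(len(recs)):
                for j in range(i + 1, len(recs)):
                    a, oa = recs[i]
                    b, ob = recs[j]
                    if oa is not None and oa == ob:
                        continue  # full sibs
                    rows.append((a, b))
    if not rows:
        return pd.DataFrame(columns=["id_a", "id_b", "reared"])
    hs = pd.DataFrame(rows, columns=["id_a", "id_b"]).drop_duplicates()
    flags = kinship.cohabitation_flags(
        pedigree,
        hs.rename(columns={"id_a": "proband_id", "id_b": "relative_id"}).assign(
            is_parent=False, is_offspring=False, is_full_sib=False
        ),
    )
    hs["reared"] = flags["cohabited"].to_numpy()
    return hs


def estimate_cohabitation_factors(
    pedigree: Pedigree,
    events: pd.DataFrame,
    disorder: str,
    po_pairs: pd.DataFrame | None = None,
    hs_pairs: pd.DataFrame | None = None,
    min_pairs: int = 50,
) -> CohabitationFactors:
    """Calibrate cohabitation correction factors for one disorder.

    The parent-offspring factor compares the tetrachoric affection
    resemblance of father-offspring pairs reared together versus apart; the
    sibling factor does the same for half-sibs.  A factor of 1 (no
    correction) is returned whenever a pair class is too small, a table is
    degenerate, or the reared resemblance is not positive.
    """
    affected = set(events.loc[events["disorder"] == disorder, "person_id"])
    if po_pairs is None:
        po_pairs = parent_offspring_pairs(pedigree)
    if hs_pairs is None:
        hs_pairs = half_sib_pairs(pedigree)

    def factor(pairs: pd.DataFrame, ca: str, cb: str, kind: str) -> tuple[float, int, int]:
        reared = pairs[pairs["reared"]]
        apart = pairs[~pairs["reared"]]
        if len(reared) < min_pairs or len(apart) < min_pairs:
            return 1.0, len(reared), len(apart)
        r_reared = tetrachoric_correlation(*_pair_affection_table(reared, affected, ca, cb))
        r_apart = tetrachoric_correlation(*_pair_affection_table(apart, affected, ca, cb))
        if not np.isfinite(r_reared) or not np.isfinite(r_apart) or r_reared <= 0:
            logger.warning(
                "degenerate %s resemblance for %s; factor set to 1", kind, disorder
            )
            return 1.0, len(reared), len(apart)
        return float(np.clip(r_apart / r_reared, 0.0, 1.0)), len(reared), len(apart)

    po_f, n_po_r, n_po_a = factor(po_pairs, "parent_id", "child_id", "parent-offspring")
    sib_f, n_hs_r, n_hs_a = factor(hs_pairs, "id_a", "id_b", "half-sib")
    return CohabitationFactors(
        disorder=disorder,
        parent_offspring_factor=po_f,
        sibling_factor=sib_f,
        n_po_reared=n_po_r,
        n_po_apart=n_po_a,
        n_sib_reared=n_hs_r,
        n_sib_apart=n_hs_a,
    )


# -- score aggregation -------------------------------------------------------


def raw_fgrs(z, w, r, c) -> tuple[float, float]:
    """Weighted-mean aggregation over one proband's relatives.

    raw = sum(z*w*r*c) / sum(w*r); n_weighted = sum(w*r).  Returns
    (nan, 0) when no relative carries weight.
    """
    z, w, r, c = (np.asarray(x, dtype=float) for x in (z, w, r, c))
    n_w = float(np.sum(w * r))
    if n_w <= 0:
        return float("nan"), 0.0
    return float(np.sum(z * w * r * c) / n_w), n_w


def shrink_score(raw_score, n_weighted, var_between: float, var_within: float):
    """Empirical-Bayes reliability shrinkage toward the population mean.

    shrunk = raw * var_b / (var_b + var_w / n_w); the factor lies in (0, 1)
    and grows with the weighted number of relatives.
    """
    if var_between <= 0 or var_within <= 0:
        raise ValueError("variance components must be positive")
    raw_score = np.asarray(raw_score, dtype=float)
    n_weighted = np.asarray(n_weighted, dtype=float)
    factor = np.where(
        n_weighted > 0,
        var_between / (var_between + var_within / np.where(n_weighted > 0, n_weighted, 1.0)),
        np.nan,
    )
    return raw_score * factor


def standardize_by_birth_year(
    scores: pd.Series, birth_years: pd.Series, min_cell: int = 2
) -> pd.Series:
    """Z-standardize scores within birth year (mean 0, s.d. 1 per year).

    Years with fewer than ``min_cell`` non-missing scores are pooled with the
    nearest adjacent year.  Missing scores propagate as missing.  Constant
    scores within a cell raise (degenerate s.d.).
    """
    scores = scores.astype(float)
    valid = scores.notna()
    counts = birth_years[valid].value_counts().sort_index()
    # years with at least min_cell probands and non-constant scores anchor
    # their own cell and are standardized exactly from their own mean and
    # s.d.; sparse (or constant-valued, hence s.d.-free) years borrow the
    # parameters of the nearest anchor year, so they cannot perturb it
    params: dict[int, tuple[float, float]] = {}
    large = []
    for y in counts.index:
        if counts[y] < min_cell:
            continue
        vals = scores[valid & (birth_years == y)]
        sd = float(vals.std(ddof=0))
        if np.isfinite(sd) and sd > 0:
            large.append(y)
            params[int(y)] = (float(vals.mean()), sd)
    large = np.array(large)
    if len(large):
        anchor_of = {
            int(y): int(large[np.argmin(np.abs(large - y))]) for y in counts.index
        }
    else:
        vals = scores[valid]
        mu = float(vals.mean())
        sd = float(vals.std(ddof=0))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError("degenerate (constant) scores in pooled birth-year cell")
        params[-1] = (mu, sd)
        anchor_of = {int(y): -1 for y in counts.index}
    out = pd.Series(np.nan, index=scores.index)
    for y, anchor in anchor_of.items():
        mu, sd = params[anchor]
        mask = (birth_years == y) & valid
        out[mask] = (scores[mask] - mu) / sd
    return out


# -- full pipeline -----------------------------------------------------------


def compute_fgrs_matrix(
    pedigree: Pedigree,
    events: pd.DataFrame,
    disorder_configs: dict[str, DisorderConfig],
    proband_ids: list[str] | np.ndarray | None = None,
    options: ScoreOptions | None = None,
) -> FGRSMatrix:
    """Standardized FGRS for every proband and disorder (deterministic).

    Thresholds, onset CDFs and cohabitation factors are estimated from the
    supplied pedigree and events; the proband's own registrations never enter
    their own score (probands are not their own relatives).
    """
    options = options or ScoreOptions()
    persons = pedigree.persons
    if proband_ids is None:
        proband_ids = list(persons["person_id"])
    proband_ids = list(proband_ids)

    pairs = kinship.relative_pair_table(pedigree, proband_ids, options.max_degree)
    pairs = kinship.cohabitation_flags(pedigree, pairs, options.min_reared_years)

    person_info = persons.set_index("person_id")[["sex", "birth_year", "end_year"]]
    pairs = pairs.join(person_info, on="relative_id")
    pairs["birth_decade"] = birth_decade(pairs["birth_year"])
    pairs["first_degree_cohab"] = (
        pairs["is_parent"] | pairs["is_offspring"] | pairs["is_full_sib"]
    ) & pairs["cohabited"]
    pairs["po_cohab"] = (pairs["is_parent"] | pairs["is_offspring"]) & pairs["cohabited"]
    pairs["sib_cohab"] = pairs["is_full_sib"] & pairs["cohabited"]

    if options.cohabitation_correction:
        po = parent_offspring_pairs(pedigree)
        hs = half_sib_pairs(pedigree)
    else:
        po = hs = None

    excl = set(options.exclude_relative_disorders)
    proband_birth = person_info.loc[proband_ids, "birth_year"]
    proband_birth.index = pd.Index(proband_ids, name="proband_id")

    cols: dict[str, pd.Series] = {}
    meta: dict[str, dict] = {"thresholds": {}, "cohabitation": {}, "shrinkage": {}}
    for name, cfg in disorder_configs.items():
        ev = events[events["disorder"] == name]
        thresholds = estimate_thresholds(events, pedigree, name)
        onset = estimate_onset_cdf(events, pedigree, name, cfg.register_start_year)

        affected_ids = set(ev["person_id"])
        p = pairs
        if name in excl:
            if options.exclude_mode == "relatives":
                p = pairs[~pairs["relative_id"].isin(affected_ids)]
            affected_scoring: set[str] = set()
        else:
            affected_scoring = affected_ids
        if options.exclude_mode == "relatives" and excl - {name}:
            drop = set(
                events.loc[events["disorder"].isin(excl), "person_id"]
            )
            p = p[~p["relative_id"].isin(drop)]

        p = p.copy()
        p["affected"] = p["relative_id"].isin(affected_scoring)
        tt = thresholds.table.set_index(["sex", "birth_decade"])
        key = pd.MultiIndex.from_frame(p[["sex", "birth_decade"]])
        strat = tt.reindex(key)
        if strat["z_affected"].isna().any():
            missing = sorted(set(key[strat["z_affected"].isna()]))[:5]
            raise KeyError(f"missing threshold stratum while scoring {name}: {missing}")
        p["z"] = np.where(
            p["affected"], strat["z_affected"].to_numpy(), strat["z_unaffected"].to_numpy()
        )
        w_unaff = time_at_risk_weight(
            p["birth_year"].to_numpy(), p["end_year"].to_numpy(), onset, cfg.register_start_year
        )
        p["w"] = np.where(p["affected"], 1.0, w_unaff)

        if options.cohabitation_correction:
            factors = estimate_cohabitation_factors(pedigree, events, name, po, hs)
            c = np.ones(len(p))
            c[p["po_cohab"].to_numpy()] = factors.parent_offspring_factor
            c[p["sib_cohab"].to_numpy()] = factors.sibling_factor
            p["c"] = c
            meta["cohabitation"][name] = factors
        else:
            p["c"] = 1.0

        p["wr"] = p["w"] * p["relatedness"]
        p["contrib"] = p["z"] * p["wr"] * p["c"]
        agg = p.groupby("proband_id").agg(num=("contrib", "sum"), n_w=("wr", "sum"))
        agg = agg.reindex(proband_ids)
        raw = (agg["num"] / agg["n_w"]).where(agg["n_w"] > 0)
        n_w = agg["n_w"].fillna(0.0)

        if options.shrinkage:
            zc = (p["z"] * p["c"]).to_numpy()
            var_w = float(np.var(zc))
            ok = raw.notna() & (n_w > 0)
            mean_nw = float(n_w[ok].mean()) if ok.any() else 1.0
            var_b = float(np.var(raw[ok])) - var_w / mean_nw
            var_b = max(var_b, VAR_BETWEEN_FLOOR)
            score = pd.Series(
                shrink_score(raw.to_numpy(), n_w.to_numpy(), var_b, var_w),
                index=raw.index,
            ).where(ok)
            meta["shrinkage"][name] = {"var_between": var_b, "var_within": var_w}
        else:
            score = raw

        cols[name] = standardize_by_birth_year(
            score, proband_birth, options.standardize_min_cell
        )
        meta["thresholds"][name] = thresholds

    scores = pd.DataFrame(cols, index=pd.Index(proband_ids, name="proband_id"))
    return FGRSMatrix(scores=scores, birth_years=proband_birth, metadata=meta)
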