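"""Liability-threshold machinery: thresholds, conditional means, risk weights.

Under the liability-threshold model a disorder with prevalence K arises when
a standard-normal liability exceeds t = Phi^-1(1-K).  Registration status is
converted to a liability z-score: affected persons get the mean liability
above the threshold, z_aff = phi(t)/K, and unaffected persons the mean below
it, z_unaff = -phi(t)/(1-K), so that K*z_aff + (1-K)*z_unaff = 0.

Thresholds are estimated per (disorder, sex, birth decade) stratum so that
secular and sex differences in registration rates translate into different
thresholds rather than biased scores.  Unaffected relatives additionally
carry a time-at-risk weight: the fraction of the disorder's age-at-first-
registration distribution they have lived through under observable register
coverage, with left truncation by register era handled by renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_registry import Pedigree


def threshold_from_prevalence(K):
    """t = Phi^-1(1 - K)."""
    return stats.norm.isf(K)


def conditional_means(K):
    """(z_affected, z_unaffected) for prevalence K under the threshold model."""
    K = np.asarray(K, dtype=float)
    t = stats.norm.isf(K)
    phi_t = stats.norm.pdf(t)
    return phi_t / K, -phi_t / (1.0 - K)


def birth_decade(years) -> np.ndarray:
    """Calendar decade of birth (1937 -> 1930)."""
    return (np.asarray(years, dtype=int) // 10) * 10


@dataclass
class ThresholdTable:
    """Per (disorder, sex, birth_decade): prevalence, threshold, conditional means."""

    table: pd.DataFrame  # columns: disorder, sex, birth_decade, n, K, t, z_affected, z_unaffected

    def lookup(self, disorder: str, sex: str, decade: int) -> pd.Series:
        t = self.table
        hit = t[(t["disorder"] == disorder) & (t["sex"] == sex) & (t["birth_decade"] == decade)]
        if not len(hit):
            raise KeyError(
                f"no threshold stratum for disorder={disorder}, sex={sex}, decade={decade}"
            )
        return hit.iloc[0]


def estimate_thresholds(
    events: pd.DataFrame,
    pedigree: Pedigree,
    disorder: str,
    n_min: int = 100,
    strict: bool = False,
) -> ThresholdTable:
    """Stratum prevalences and liability thresholds for one disorder.

    Prevalence per (sex, birth decade) stratum is the observed registration
    proportion.  Zero-case strata get K floored at 0.5/n so the threshold
    stays finite; with ``strict=True`` strata smaller than ``n_min`` raise
    instead of being estimated.
    """
    persons = pedigree.persons
    if not len(persons):
        raise ValueError("empty pedigree")
    affected_ids = set(events.loc[events["disorder"] == disorder, "person_id"])
    df = pd.DataFrame(
        {
            "sex": persons["sex"],
            "birth_decade": birth_decade(persons["birth_year"]),
            "affected": persons["person_id"].isin(affected_ids),
        }
    )
    grp = df.groupby(["sex", "birth_decade"], as_index=False).agg(
        n=("affected", "size"), cases=("affected", "sum")
    )
    if strict and (grp["n"] < n_min).any():
        small = grp.loc[grp["n"] < n_min, ["sex", "birth_decade"]]
        raise ValueError(f"strata below n_min={n_min}: {small.to_dict('records')}")
    n = grp["n"].to_numpy(dtype=float)
    K = grp["cases"].to_numpy(dtype=float) / n
    K = np.clip(K, 0.5 / n, 1.0 - 0.5 / n)
    z_aff, z_unaff = conditional_means(K)
    out = grp.assign(
        disorder=disorder,
        K=K,
        t=threshold_from_prevalence(K),
        z_affected=z_aff,
        z_unaffected=z_unaff,
    )
    cols = ["disorder", "sex", "birth_decade", "n", "cases", "K", "t", "z_affected", "z_unaffected"]
    return ThresholdTable(out[cols])


@dataclass
class OnsetCDF:
    """Empirical CDF of age at first registration, a step function on integer ages."""

    disorder: str
    ages: np.ndarray     # sorted unique onset ages
    cdf: np.ndarray      # F(ages[i]), ends at 1
    n_events: int

    def __call__(self, age) -> np.ndarray:
        """F(age): fraction of onsets at or before ``age``."""
        age = np.asarray(age, dtype=float)
        idx = np.searchsorted(self.ages, age, side="right")
        vals = np.concatenate([[0.0], self.cdf])
        return vals[idx]


def estimate_onset_cdf(
    events: pd.DataFrame,
    pedigree: Pedigree,
    disorder: str,
    register_start_year: int | None = None,
) -> OnsetCDF:
    """Empirical age-at-first-registration distribution for one disorder."""
    ev = events[events["disorder"] == disorder]
    if register_start_year is not None:
        ev = ev[ev["year"] >= register_start_year]
    if not len(ev):
        raise ValueError(f"no usable events for disorder {disorder!r}")
    birth = pedigree.persons.set_index("person_id")["birth_year"]
    ages = (ev["year"].to_numpy() - ev["person_id"].map(birth).to_numpy()).astype(int)
    if (ages < 0).any():
        raise ValueError("event before birth encountered in onset estimation")
    uniq, counts = np.unique(ages, return_counts=True)
    cdf = np.cumsum(counts) / counts.sum()
    return OnsetCDF(disorder=disorder, ages=uniq, cdf=cdf, n_events=int(len(ev)))


def time_at_risk_weight(
    birth_year: int | np.ndarray,
    end_year: int | np.ndarray,
    onset_cdf: OnsetCDF,
    register_start_year: int,
) -> np.ndarray:
    """Completed fraction of observable time at risk for unaffected persons.

    With F the onset CDF, a_obs the age at end of follow-up and a_start the
    age at which register coverage began for this person (0 if born after
    the register opened)::

        weight = (F(a_obs) - F(a_start)) / (1 - F(a_start))

    clamped to [0, 1].  A person whose whole risk period predates coverage
    (F(a_start) = 1) carries no information and gets weight 0.
    """
    birth_year = np.asarray(birth_year, dtype=int)
    end_year = np.asarray(end_year, dtype=int)
    a_obs = np.maximum(end_year - birth_year, 0)
    a_start = np.maximum(register_start_year - birth_year, 0)
    F_obs = onset_cdf(a_obs)
    F_start = onset_cdf(a_start)
    denom = 1.0 - F_start
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, (F_obs - F_start) / denom, 0.0)
    return np.clip(w, 0.0, 1.0)


def liability_zscore(
    thresholds: ThresholdTable,
    disorder: str,
    sex: str,
    birth_year: int,
    affected: bool,
) -> float:
    """Liability z-score for one person: stratum conditional mean by status."""
    row = thresholds.lookup(disorder, sex, int(birth_decade(birth_year)))
    return float(row["z_affected"] if affected else row["z_unaffected"])
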