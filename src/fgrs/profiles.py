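"""Case-group FGRS profiles and their comparisons.

A *profile* is the vector of mean standardized FGRSs (one per disorder) in a
case group, with normal-approximation 95% confidence intervals.  Group
comparisons follow a two-stage scheme: an overall one-way analysis of means
across all groups per disorder, then the unique pairwise comparisons as
unequal-variance (Welch) tests.  Because profile batteries involve many
non-independent tests, the default significance threshold is the
conservative alpha = 1e-4.

Also here: the comorbidity-hierarchy operation (probands carrying a
higher-ranked diagnosis are removed from lower-ranked groups) and Venn-style
overlap counts, both used in sensitivity analyses of group definitions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fgrs_core import FGRSMatrix

DEFAULT_ALPHA = 1e-4


@dataclass
class CaseGroup:
    """A named set of scored probands (typically: cases of one disorder)."""

    name: str
    proband_ids: frozenset
    definition: str = ""

    def __len__(self) -> int:
        return len(self.proband_ids)


def case_groups_from_events(
    events: pd.DataFrame, matrix: FGRSMatrix, disorders: list[str] | None = None
) -> dict[str, CaseGroup]:
    """One case group per disorder: scored probands with a registration."""
    scored = set(matrix.scores.index)
    disorders = disorders or matrix.disorders
    groups = {}
    for d in disorders:
        ids = frozenset(events.loc[events["disorder"] == d, "person_id"]) & scored
        groups[d] = CaseGroup(name=d, proband_ids=ids, definition=d)
    return groups


@dataclass
class ProfileResult:
    group_stats: pd.DataFrame   # group, disorder, n, mean, ci_lo, ci_hi
    pairwise: pd.DataFrame      # group_a, group_b, disorder, diff, lo, hi, p, significant
    overall: pd.DataFrame       # disorder, stat, p
    alpha: float = DEFAULT_ALPHA


def welch_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch two-sample mean comparison; returns (difference, p-value)."""
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(np.mean(x) - np.mean(y)), float(res.pvalue)


def permutation_pvalue(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Two-sided permutation p-value for a mean difference (label shuffling)."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    n_x = len(x)
    obs = abs(np.mean(x) - np.mean(y))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = abs(perm[:n_x].mean() - perm[n_x:].mean())
        if d >= obs - 1e-15:
            count += 1
    return (count + 1) / (n_perm + 1)


def profile(
    groups: dict[str, CaseGroup] | list[CaseGroup],
    matrix: FGRSMatrix,
    alpha: float = DEFAULT_ALPHA,
) -> ProfileResult:
    """Mean FGRS profiles per group with overall and pairwise comparisons."""
    if isinstance(groups, dict):
        groups = list(groups.values())
    if not groups:
        raise ValueError("no case groups supplied")
    scores = matrix.scores
    for g in groups:
        if len(g) < 2:
            raise ValueError(f"case group {g.name!r} has fewer than 2 probands")
        unknown = g.proband_ids - set(scores.index)
        if unknown:
            raise ValueError(f"group {g.name!r} contains unscored probands")

    disorders = matrix.disorders
    rows, pair_rows, overall_rows = [], [], []
    samples = {g.name: scores.loc[sorted(g.proband_ids)] for g in groups}
    for d in disorders:
        per_group = {}
        for g in groups:
            v = samples[g.name][d].dropna().to_numpy()
            per_group[g.name] = v
            n = len(v)
            mean = float(v.mean()) if n else float("nan")
            half = 1.96 * v.std(ddof=1) / np.sqrt(n) if n > 1 else float("nan")
            rows.append((g.name, d, n, mean, mean - half, mean + half))
        if len(groups) >= 3:
            res = stats.f_oneway(*[per_group[g.name] for g in groups])
            overall_rows.append((d, float(res.statistic), float(res.pvalue)))
        for ga, gb in itertools.combinations([g.name for g in groups], 2):
            x, y = per_group[ga], per_group[gb]
            diff, p = welch_test(x, y)
            se = np.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
            pair_rows.append(
                (ga, gb, d, diff, diff - 1.96 * se, diff + 1.96 * se, p, p < alpha)
            )
    return ProfileResult(
        group_stats=pd.DataFrame(
            rows, columns=["group", "disorder", "n", "mean", "ci_lo", "ci_hi"]
        ),
        pairwise=pd.DataFrame(
            pair_rows,
            columns=["group_a", "group_b", "disorder", "diff", "lo", "hi", "p", "significant"],
        ),
        overall=pd.DataFrame(overall_rows, columns=["disorder", "stat", "p"]),
        alpha=alpha,
    )


def group_elevation(
    groups: dict[str, CaseGroup] | list[CaseGroup],
    matrix: FGRSMatrix,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """One-sample z-tests of each group's mean FGRS against the population 0.

    Standardized scores have mean 0 in the whole scored population, so a
    significantly positive group mean is an *elevation* of genetic risk.
    """
    if isinstance(groups, dict):
        groups = list(groups.values())
    rows = []
    for g in groups:
        sub = matrix.scores.loc[sorted(g.proband_ids)]
        for d in matrix.disorders:
            v = sub[d].dropna().to_numpy()
            n = len(v)
            if n < 2:
                continue
            se = v.std(ddof=1) / np.sqrt(n)
            z = v.mean() / se if se > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z))
            rows.append((g.name, d, n, float(v.mean()), float(z), float(p),
                         bool(p < alpha and v.mean() > 0)))
    return pd.DataFrame(
        rows, columns=["group", "disorder", "n", "mean", "z", "p", "elevated"]
    )


def plot_profiles(
    result: ProfileResult,
    path,
    disorder_classes: dict[str, str] | None = None,
) -> None:
    """Bar plot of mean FGRS with 95% CIs per group, disorders on the x-axis.

    Bars are colored by disorder class when ``disorder_classes`` is given.
    Requires matplotlib (an optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    palette = {"fsd": "#c0392b", "internalizing": "#f1c40f",
               "autoimmune": "#27ae60", "pain": "#2980b9", "sleep": "#8e44ad"}
    stats_df = result.group_stats
    groups = list(dict.fromkeys(stats_df["group"]))
    disorders = list(dict.fromkeys(stats_df["disorder"]))
    fig, axes = plt.subplots(
        len(groups), 1, figsize=(0.6 * len(disorders) + 2, 2.2 * len(groups)),
        sharex=True, squeeze=False,
    )
    x = np.arange(len(disorders))
    for ax, g in zip(axes[:, 0], groups):
        sub = stats_df[stats_df["group"] == g].set_index("disorder").loc[disorders]
        colors = [
            palette.get((disorder_classes or {}).get(d, ""), "#7f8c8d") for d in disorders
        ]
        ax.bar(x, sub["mean"], color=colors)
        ax.errorbar(
            x, sub["mean"],
            yerr=[sub["mean"] - sub["ci_lo"], sub["ci_hi"] - sub["mean"]],
            fmt="none", ecolor="black", capsize=2, lw=1,
        )
        ax.axhline(0, color="black", lw=0.8)
        ax.set_ylabel(f"{g}\nmean FGRS")
    axes[-1, 0].set_xticks(x)
    axes[-1, 0].set_xticklabels(disorders, rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def apply_hierarchy(
    groups: dict[str, CaseGroup], rule: list[str]
) -> tuple[dict[str, CaseGroup], dict[str, int]]:
    """Impose a severity hierarchy on overlapping case groups.

    ``rule`` lists group names from highest to lowest: a proband carrying a
    higher-ranked diagnosis is removed from every lower-ranked group.
    Returns the filtered groups and the number removed from each.
    """
    unknown = [r for r in rule if r not in groups]
    if unknown:
        raise KeyError(f"hierarchy rule references undefined groups {unknown}")
    out = dict(groups)
    removed = {name: 0 for name in groups}
    claimed: set = set()
    for name in rule:
        g = groups[name]
        kept = g.proband_ids - claimed
        removed[name] = len(g.proband_ids) - len(kept)
        out[name] = CaseGroup(name=g.name, proband_ids=frozenset(kept), definition=g.definition)
        claimed |= g.proband_ids
    return out, removed


def comorbidity_table(groups: dict[str, CaseGroup]) -> pd.DataFrame:
    """Venn-style disjoint overlap counts over all non-empty group subsets.

    The counts partition the union: summing the ``count`` column gives the
    number of probands in at least one group.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a comorbidity table")
    names = sorted(groups)
    membership: dict = {}
    for name in names:
        for pid in groups[name].proband_ids:
            membership.setdefault(pid, set()).add(name)
    counts: dict[frozenset, int] = {}
    for pid, mem in membership.items():
        key = frozenset(mem)
        counts[key] = counts.get(key, 0) + 1
    rows = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            key = frozenset(combo)
            rows.append(("+".join(combo), len(combo), counts.get(key, 0)))
    return pd.DataFrame(rows, columns=["subset", "size", "count"])
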