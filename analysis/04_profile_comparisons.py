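#!/usr/bin/env python
"""Compare FGRS profiles of the FM, IBS, CFS, MD and RA case groups.

Runs the two-stage comparison (overall analysis of means, then unique
pairwise Welch tests at the conservative alpha = 1e-4), the comorbidity
overlap table, the CFS-over-FM hierarchy sensitivity analysis, and the
relative-exclusion sensitivity analysis (removing FM registrations from
relatives before rescoring).  Tables land under results/profiles/.
"""

from pathlib import Path

import pandas as pd

from fgrs import fgrs_core, io_registry, profiles
from fgrs.synthetic_data import DISORDER_CLASSES

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "profiles"
GROUPS = ["FM", "IBS", "CFS", "MD", "RA"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scores = io_registry.read_scores(ROOT / "fgrs_scores.tsv")
    matrix = fgrs_core.FGRSMatrix(
        scores=scores, birth_years=pd.Series(index=scores.index, dtype=float)
    )
    events = pd.read_csv(ROOT / "registry" / "events.tsv", sep="\t", dtype={"person_id": str})
    groups = profiles.case_groups_from_events(events, matrix, GROUPS)
    print("group sizes:", {k: len(v) for k, v in groups.items()})

    res = profiles.profile(groups, matrix)
    res.group_stats.to_csv(OUT / "means.tsv", sep="\t", index=False)
    res.pairwise.to_csv(OUT / "pairwise.tsv", sep="\t", index=False)
    res.overall.to_csv(OUT / "overall.tsv", sep="\t", index=False)
    n_sig = int(res.pairwise["significant"].sum())
    print(f"pairwise comparisons: {len(res.pairwise)}, significant at 1e-4: {n_sig}")

    try:
        profiles.plot_profiles(res, OUT / "profiles.png", DISORDER_CLASSES)
        print(f"profile figure: {OUT/'profiles.png'}")
    except ImportError:
        pass  # plotting is optional

    elev = profiles.group_elevation(groups, matrix)
    elev.to_csv(OUT / "elevations.tsv", sep="\t", index=False)
    for g in ("FM", "RA"):
        cls = sorted({DISORDER_CLASSES[d] for d in elev[(elev["group"] == g) & elev["elevated"]]["disorder"]})
        print(f"{g} cases: significantly elevated FGRS in classes {cls}")

    fsd_groups = {k: groups[k] for k in ("FM", "IBS", "CFS")}
    overlap = profiles.comorbidity_table(fsd_groups)
    overlap.to_csv(OUT / "comorbidity.tsv", sep="\t", index=False)
    print("FSD comorbidity overlap:")
    print(overlap.to_string(index=False))

    ranked, removed = profiles.apply_hierarchy(dict(fsd_groups), ["CFS", "FM", "IBS"])
    print(f"hierarchy CFS > FM > IBS removed: {removed}")
    res_h = profiles.profile(ranked, matrix)
    res_h.group_stats.to_csv(OUT / "means_hierarchy.tsv", sep="\t", index=False)

    # relative-exclusion sensitivity: drop FM registrations from relatives
    ped = io_registry.read_pedigree(
        ROOT / "registry" / "pedigree.tsv",
        households_path=ROOT / "registry" / "households.tsv",
    )
    probands = list(scores.index)
    configs = {
        d: io_registry.DisorderConfig(name=d, register_start_year=1900,
                                      disorder_class=DISORDER_CLASSES[d])
        for d in sorted(events["disorder"].unique())
    }
    opts = fgrs_core.ScoreOptions(exclude_relative_disorders=("FM",), exclude_mode="relatives")
    excl = fgrs_core.compute_fgrs_matrix(ped, events, configs, probands, opts)
    fm_ids = sorted(groups["FM"].proband_ids)
    before = matrix.scores.loc[fm_ids].mean()
    after = excl.scores.loc[fm_ids].mean()
    cmp = pd.DataFrame({"mean_full": before, "mean_fm_relatives_excluded": after})
    cmp.to_csv(OUT / "fm_relative_exclusion.tsv", sep="\t")
    print("FM-case mean FGRS with vs without FM-affected relatives:")
    print(cmp.round(3).to_string())


if __name__ == "__main__":
    main()
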