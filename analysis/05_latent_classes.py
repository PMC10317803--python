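#!/usr/bin/env python
"""Latent-class analysis of FM cases' FGRS vectors.

Fits diagonal Gaussian mixtures with 1-5 classes to the FM cases' scores on
FM plus two disorders from each associated block (internalizing, autoimmune,
pain/sleep), selects by BIC, and reports whether the class means are graded
along one axis (quantitative differences) or form distinct subtypes.
"""

from pathlib import Path

import pandas as pd

from fgrs import lca
from fgrs.io_registry import read_scores

ROOT = Path(__file__).resolve().parent.parent / "results"
DIMS = ["FM", "MD", "AD", "RA", "HASH", "BP", "MIG"]
SEED = 2024


def main() -> None:
    scores = read_scores(ROOT / "fgrs_scores.tsv")
    events = pd.read_csv(ROOT / "registry" / "events.tsv", sep="\t", dtype={"person_id": str})
    fm_cases = sorted(set(events.loc[events["disorder"] == "FM", "person_id"]) & set(scores.index))
    X = scores.loc[fm_cases, DIMS].dropna()
    print(f"FM cases with complete score vectors: {len(X)}")
    model, table = lca.select_classes(X, max_classes=5, seed=SEED)
    out = ROOT / "lca"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "fit.tsv", sep="\t", index=False)
    means = pd.DataFrame(model.means, columns=DIMS)
    means.insert(0, "weight", model.weights)
    means.to_csv(out / "class_means.tsv", sep="\t", index=False)
    print(table.round(1).to_string(index=False))
    print(f"selected {model.n_classes} class(es) by BIC")
    coll = lca.means_collinearity(model)
    print(f"class-mean collinearity: {coll:.2f} "
          f"({'graded severity (quantitative)' if coll > 0.8 else 'distinct subtypes (qualitative)'})")
    print(means.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
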