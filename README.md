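# fgrs — family genetic risk scores from pedigree and registry data

Functional somatic disorders — fibromyalgia (FM), irritable bowel syndrome
(IBS), chronic fatigue syndrome (CFS) — have no established biomarkers, and
their familial background is hard to study with molecular polygenic scores.
The **family genetic risk score (FGRS)** takes the phenotype route instead:
it estimates a person's aggregate genetic liability to a disorder from
first-registration diagnoses in their first- through fifth-degree
relatives.  This package implements the full scoring pipeline, the
downstream profile and latent-class analyses used to compare disorders, and
a synthetic-registry generator with known genetic architecture so that
every step is testable end to end without access to confidential
national-register data.

For a proband *i* and disorder *d*, each relative *j* contributes the
product of four components, averaged with weights:

```
FGRS_i = standardize_by_birth_year( shrink( Σ_j z_j · w_j · r_ij · c_j / Σ_j w_j · r_ij ) )
```

* `z_j` — liability z-score under the liability-threshold model:
  φ(t)/K if registered, −φ(t)/(1−K) if not, with t = Φ⁻¹(1−K) from the
  (sex, birth-decade)-specific registration prevalence K;
* `w_j` — completed fraction of the age-at-first-registration distribution
  under observable register coverage (1 if registered);
* `r_ij` — relatedness (expected proportion of shared genes, path-counted);
* `c_j` — cohabitation correction for first-degree relatives who shared a
  household, calibrated from reared-together versus reared-apart pairs;

followed by empirical-Bayes shrinkage toward the population mean for
probands with little family information, and standardization to mean 0,
s.d. 1 within year of birth.

## Layout

* `src/fgrs/` — the library: `io_registry` (tables, files, validation),
  `kinship` (relative enumeration, gene-dropping oracle), `liability`
  (thresholds, onset CDFs, time-at-risk weights), `fgrs_core` (scoring),
  `profiles` (case-group comparisons), `lca` (Gaussian-mixture latent
  classes), `synthetic_data` (registry simulation).
* `analysis/` — numbered drivers reproducing the analysis sequence on a
  simulated registry: simulate, estimate thresholds, score, compare
  profiles, fit latent classes.  Each writes its tables under `results/`.
* `fgrs` CLI — `fgrs simulate | thresholds | score | profile | lca`, thin
  wrappers over the library for shell use.

## Worked example

```python
from fgrs import synthetic_data as sd, fgrs_core, profiles

cfg = sd.single_disorder_config(h2=0.6)      # one disorder, h² = 0.6
res = sd.simulate(cfg, seed=11)
mat = fgrs_core.compute_fgrs_matrix(
    res.pedigree, res.events, cfg.disorder_configs(), res.proband_ids
)
cases = set(res.events.loc[res.events.disorder == "D", "person_id"])
s = mat.scores["D"]
gap = s[s.index.isin(cases)].mean() - s[~s.index.isin(cases)].mean()
print(f"{len(res.proband_ids)} probands, case-control FGRS gap {gap:.2f}")
```

prints

```
18768 probands, case-control FGRS gap 0.64
```

— registered cases carry a mean standardized FGRS 0.64 s.d. above
non-cases; at h² = 0.4 the same experiment gives 0.44 and at h² = 0.2 it
gives 0.26, so the score ranks genetic architectures correctly.  The
analysis drivers show the multivariate version: on a 13-disorder registry
with block-structured genetic correlations, the FM-like case group shows
significantly elevated FGRSs across the functional-somatic, internalizing,
pain and sleep classes, while the RA-like group's elevations stay confined
to the autoimmune class — the qualitative contrast between a broad
functional-somatic risk profile and a classic autoimmune one.

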