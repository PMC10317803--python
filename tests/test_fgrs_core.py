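"""Score aggregation, shrinkage, standardization, cohabitation factors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fgrs import fgrs_core as core
from fgrs import synthetic_data as synth


class TestRawFgrs:
    def test_single_affected_parent(self):
        raw, n_w = core.raw_fgrs([2.0], [1.0], [0.5], [1.0])
        assert raw == pytest.approx(2.0)
        assert n_w == pytest.approx(0.5)

    def test_two_relatives(self):
        raw, _ = core.raw_fgrs([2.0, -0.5], [1.0, 1.0], [0.5, 0.5], [1.0, 1.0])
        assert raw == pytest.approx((1.0 - 0.25) / 1.0)

    def test_all_unaffected_negative(self):
        raw, _ = core.raw_fgrs([-0.3, -0.3, -0.5], [1, 1, 1], [0.5, 0.5, 0.25], [1, 1, 1])
        assert raw < 0

    def test_no_informative_relative_is_missing(self):
        raw, n_w = core.raw_fgrs([2.0], [0.0], [0.5], [1.0])
        assert np.isnan(raw) and n_w == 0.0


class TestShrinkScore:
    def test_many_relatives_limit(self):
        shrunk = core.shrink_score(1.0, 1e9, var_between=1.0, var_within=1.0)
        assert shrunk == pytest.approx(1.0, abs=1e-6)

    def test_equal_variances_single_relative(self):
        assert core.shrink_score(2.0, 1.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_monotone_in_relative_count(self):
        n = np.array([0.5, 1.0, 2.0, 8.0])
        shrunk = core.shrink_score(np.ones(4), n, 0.5, 1.0)
        assert np.all(np.diff(shrunk) > 0)

    def test_invalid_variances_raise(self):
        with pytest.raises(ValueError):
            core.shrink_score(1.0, 1.0, 0.0, 1.0)


class TestStandardize:
    def test_exact_moments_and_rank(self):
        rng = np.random.default_rng(0)
        idx = pd.Index([f"p{i}" for i in range(300)])
        scores = pd.Series(rng.standard_normal(300) * 3 + 1, index=idx)
        years = pd.Series(rng.choice([1960, 1961, 1962], 300), index=idx)
        out = core.standardize_by_birth_year(scores, years)
        for y in (1960, 1961, 1962):
            v = out[years == y]
            assert v.mean() == pytest.approx(0.0, abs=1e-10)
            assert v.std(ddof=0) == pytest.approx(1.0, abs=1e-10)
            orig = scores[years == y]
            assert (v.rank() == orig.rank()).all()

    def test_missing_propagates(self):
        idx = pd.Index(list("abcd"))
        scores = pd.Series([1.0, 2.0, np.nan, 4.0], index=idx)
        years = pd.Series([1960] * 4, index=idx)
        out = core.standardize_by_birth_year(scores, years)
        assert np.isnan(out["c"]) and out.drop("c").notna().all()

    def test_sparse_year_borrows_neighbor_parameters(self):
        idx = pd.Index([f"p{i}" for i in range(21)])
        scores = pd.Series(np.r_[np.arange(20, dtype=float), [100.0]], index=idx)
        years = pd.Series([1960] * 20 + [1970], index=idx)
        out = core.standardize_by_birth_year(scores, years)
        v = out[years == 1960]
        assert v.mean() == pytest.approx(0.0, abs=1e-10)
        # the lone 1970 proband is standardized with 1960's parameters
        mu, sd = scores[:20].mean(), scores[:20].std(ddof=0)
        assert out["p20"] == pytest.approx((100.0 - mu) / sd)

    def test_constant_cell_raises(self):
        idx = pd.Index(list("abc"))
        scores = pd.Series([1.0, 1.0, 1.0], index=idx)
        years = pd.Series([1960] * 3, index=idx)
        with pytest.raises(ValueError, match="degenerate"):
            core.standardize_by_birth_year(scores, years)


class TestTetrachoric:
    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.6])
    def test_recovers_bivariate_normal_correlation(self, rho):
        rng = np.random.default_rng(42)
        n = 60_000
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        t = stats.norm.isf(0.15)
        a, b = x > t, y > t
        est = core.tetrachoric_correlation(
            int((a & b).sum()), int((a & ~b).sum()), int((~a & b).sum()), int((~a & ~b).sum())
        )
        assert est == pytest.approx(rho, abs=0.05)

    def test_degenerate_margin_is_nan(self):
        assert np.isnan(core.tetrachoric_correlation(0, 0, 5, 95))


class TestCohabitationFactors:
    def test_no_household_effect_gives_factor_near_one(self):
        """With c2 = 0 reared and non-reared pairs resemble equally."""
        cfg = synth.cohabitation_config(c2=0.0, n_families=300)
        res = synth.simulate(cfg, seed=3)
        # use the latent affection truth to avoid registration noise
        aff = res.truth.loc[res.truth["affected_D"], "person_id"]
        events = pd.DataFrame({"person_id": aff, "disorder": "D", "year": 2000})
        fac = core.estimate_cohabitation_factors(res.pedigree, events, "D")
        assert fac.parent_offspring_factor == pytest.approx(1.0, abs=0.1)

    def test_identical_tables_give_factor_one(self):
        po = pd.DataFrame(
            {
                "parent_id": [f"f{i}" for i in range(200)],
                "child_id": [f"c{i}" for i in range(200)],
                "reared": [True] * 100 + [False] * 100,
            }
        )
        affected = {f"f{i}" for i in range(0, 200, 4)} | {f"c{i}" for i in range(0, 200, 4)}
        cfg = synth.single_disorder_config(h2=0.5, n_families=2)
        res = synth.simulate(cfg, seed=0)
        events = pd.DataFrame(
            {"person_id": sorted(affected), "disorder": "D", "year": 2000}
        )
        fac = core.estimate_cohabitation_factors(
            res.pedigree, events, "D", po_pairs=po,
            hs_pairs=pd.DataFrame(columns=["id_a", "id_b", "reared"]),
        )
        assert fac.parent_offspring_factor == pytest.approx(1.0)


class TestComputeMatrix:
    def test_determinism(self, small_sim, small_matrix):
        res = small_sim
        again = core.compute_fgrs_matrix(
            res.pedigree, res.events, res.config.disorder_configs(), res.proband_ids
        )
        pd.testing.assert_frame_equal(small_matrix.scores, again.scores, check_exact=True)

    def test_case_enrichment(self, small_sim, small_matrix):
        """h2=0.5 cases carry visibly higher FGRS than non-cases."""
        res = small_sim
        cases = set(res.events.loc[res.events["disorder"] == "D", "person_id"])
        s = small_matrix.scores["D"]
        in_cases = s.index.isin(cases & set(res.proband_ids))
        assert s[in_cases].mean() - s[~in_cases].mean() > 0.2

    def test_standardization_invariants(self, small_matrix):
        s = small_matrix.scores["D"]
        by = small_matrix.birth_years
        for y, v in s.groupby(by):
            if v.notna().sum() >= 2 and v.nunique() >= 2:
                assert v.mean() == pytest.approx(0.0, abs=1e-10)
                assert v.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_own_events_do_not_enter_own_score(self, small_sim):
        """Dropping the proband's own registration leaves the score unchanged."""
        res = small_sim
        cases = res.events.merge(
            pd.DataFrame({"person_id": res.proband_ids}), on="person_id"
        )
        pid = cases["person_id"].iloc[0]
        probands = res.proband_ids[:200]
        if pid not in probands:
            probands = [pid] + probands
        full = core.compute_fgrs_matrix(
            res.pedigree, res.events, res.config.disorder_configs(), probands
        )
        # the proband never appears as its own relative
        from fgrs import kinship

        pairs = kinship.relative_pair_table(res.pedigree, [pid])
        assert pid not in set(pairs["relative_id"])
        assert np.isfinite(full.scores.loc[pid, "D"])

    def test_relative_exclusion_shifts_scores(self, small_sim, small_matrix):
        res = small_sim
        opts = core.ScoreOptions(exclude_relative_disorders=("D",))
        excl = core.compute_fgrs_matrix(
            res.pedigree, res.events, res.config.disorder_configs(), res.proband_ids, opts
        )
        assert not excl.scores["D"].equals(small_matrix.scores["D"])

    def test_no_shrinkage_option(self, small_sim):
        res = small_sim
        opts = core.ScoreOptions(shrinkage=False)
        mat = core.compute_fgrs_matrix(
            res.pedigree, res.events, res.config.disorder_configs(),
            res.proband_ids[:2000], opts
        )
        assert "D" not in mat.metadata["shrinkage"]
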