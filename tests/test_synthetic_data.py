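"""Generative model checks: pedigree structure, variance components, onsets."""

import numpy as np
import pandas as pd
import pytest

from fgrs import kinship
from fgrs import synthetic_data as synth
from fgrs.io_registry import Pedigree


class TestConfigValidation:
    def test_non_psd_correlations_rejected(self):
        disorders = synth.default_disorders()[:2]
        names = [d.name for d in disorders]
        bad = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=names, columns=names)
        with pytest.raises(ValueError, match="positive semi-definite|symmetric"):
            synth.SimConfig(disorders=disorders, genetic_correlations=bad)

    def test_h2_plus_c2_bounded(self):
        with pytest.raises(ValueError, match="h2"):
            synth.DisorderSimSpec(
                name="X", disorder_class="fsd",
                prevalence_female=0.1, prevalence_male=0.1, h2=0.8, c2=0.4,
            )

    def test_prevalence_bounds(self):
        with pytest.raises(ValueError, match="prevalence"):
            synth.DisorderSimSpec(
                name="X", disorder_class="fsd",
                prevalence_female=0.0, prevalence_male=0.1, h2=0.3, c2=0.0,
            )


class TestStructure:
    def test_reproducible(self):
        cfg = synth.single_disorder_config(0.4, n_families=5)
        a = synth.simulate(cfg, seed=9)
        b = synth.simulate(cfg, seed=9)
        pd.testing.assert_frame_equal(a.pedigree.persons, b.pedigree.persons)
        pd.testing.assert_frame_equal(a.events, b.events)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_generated_pedigree_passes_validators(self, small_sim):
        # construction re-validates: no duplicate ids, no cycles, spells ok
        ped = small_sim.pedigree
        Pedigree(ped.persons, ped.households)

    def test_mean_relative_count_in_band(self, small_sim):
        """Default family structure yields 30-50 relatives per proband."""
        s = synth.summarize_pedigree(small_sim.pedigree, small_sim.proband_ids)
        assert 30 <= s["mean_relatives"] <= 50

    def test_all_degrees_one_to_five_present(self, small_sim):
        s = synth.summarize_pedigree(small_sim.pedigree, small_sim.proband_ids)
        assert set(s["mean_by_degree"]) == {1, 2, 3, 4, 5}
        assert all(v > 0 for v in s["mean_by_degree"].values())

    def test_summary_matches_brute_force_on_fixture(self, extended_pedigree):
        s = synth.summarize_pedigree(extended_pedigree, ["kid"])
        pairs = kinship.enumerate_relatives(extended_pedigree, "kid")
        assert s["mean_relatives"] == len(pairs)

    def test_trio_only_families(self):
        cfg = synth.SimConfig(
            n_families=10, generations=2, mean_offspring=1.0, max_offspring=1,
            p_half_sib_paternal=0.0, p_half_sib_maternal=0.0,
            disorders=[synth.default_disorders()[0]],
        )
        res = synth.simulate(cfg, seed=1)
        s = synth.summarize_pedigree(res.pedigree, res.proband_ids)
        assert s["mean_relatives"] == pytest.approx(2.0)


class TestVarianceComponents:
    def test_parent_offspring_additive_correlation(self):
        """With h2=1, c2=0 the parent-offspring liability correlation is 1/2."""
        cfg = synth.single_disorder_config(h2=1.0, n_families=700)
        res = synth.simulate(cfg, seed=13)
        tr = res.truth.set_index("person_id")
        ped = res.pedigree.persons
        has_fa = ped["father_id"].notna()
        child = tr.loc[ped.loc[has_fa, "person_id"], "liability_D"].to_numpy()
        father = tr.loc[ped.loc[has_fa, "father_id"], "liability_D"].to_numpy()
        r = np.corrcoef(child, father)[0, 1]
        assert len(child) > 30_000
        assert r == pytest.approx(0.5, abs=0.02)

    def test_realized_prevalence_matches_target(self):
        cfg = synth.single_disorder_config(h2=0.4, prevalence=0.1, n_families=700)
        res = synth.simulate(cfg, seed=17)
        realized = res.truth["affected_D"].mean()
        assert len(res.truth) > 50_000
        assert abs(realized - 0.1) / 0.1 < 0.1

    def test_no_household_effect_equal_resemblance(self):
        """c2=0: reared and non-reared father-offspring pairs resemble equally."""
        from fgrs import fgrs_core

        cfg = synth.cohabitation_config(c2=0.0, n_families=250)
        res = synth.simulate(cfg, seed=23)
        aff = set(res.truth.loc[res.truth["affected_D"], "person_id"])
        po = fgrs_core.parent_offspring_pairs(res.pedigree)
        rates = {}
        for label, sub in (("reared", po[po["reared"]]), ("apart", po[~po["reared"]])):
            both = sub["parent_id"].isin(aff) & sub["child_id"].isin(aff)
            either = sub["parent_id"].isin(aff)
            rates[label] = both.sum() / max(either.sum(), 1)
        assert abs(rates["reared"] - rates["apart"]) < 0.03

    def test_sibling_concordance_tracks_genetic_correlation(self):
        """Cross-disorder sibling concordance rises with r_g (rank over 3 settings)."""
        stats = []
        for rg in (0.0, 0.4, 0.8):
            cfg = synth.two_disorder_config(rg, n_families=150)
            res = synth.simulate(cfg, seed=31)
            tr = res.truth.set_index("person_id")
            ped = res.pedigree.persons
            sibs = []
            grp = ped[ped["father_id"].notna() & ped["mother_id"].notna()]
            for _, fam in grp.groupby(["father_id", "mother_id"]):
                ids = list(fam["person_id"])
                sibs += [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
            a = np.array([x for x, _ in sibs])
            b = np.array([y for _, y in sibs])
            cross = np.corrcoef(
                tr.loc[a, "liability_A"].to_numpy(), tr.loc[b, "liability_B"].to_numpy()
            )[0, 1]
            stats.append(cross)
        assert stats[0] < stats[1] < stats[2]
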