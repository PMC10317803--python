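"""Relatedness coefficients, degree bookkeeping, cohabitation, gene-dropping."""

import numpy as np
import pytest

from fgrs import kinship
from fgrs.io_registry import MALE

from conftest import make_pedigree, random_pedigree


def rel_map(ped, proband, **kw):
    return {p.relative_id: p for p in kinship.enumerate_relatives(ped, proband, **kw)}


class TestEnumerateRelatives:
    def test_trio(self, trio):
        rels = rel_map(trio, "kid")
        assert set(rels) == {"dad", "mom"}
        for r in rels.values():
            assert r.relatedness == pytest.approx(0.5)
            assert r.degree == 1

    def test_standard_coefficients(self, extended_pedigree):
        rels = rel_map(extended_pedigree, "kid")
        assert rels["sib"].relatedness == pytest.approx(0.5)
        assert rels["sib"].relation_label == "full_sib"
        assert rels["halfsib"].relatedness == pytest.approx(0.25)
        assert rels["halfsib"].relation_label == "half_sib"
        assert rels["cuz"].relatedness == pytest.approx(0.125)
        assert rels["cuz"].relation_label == "cousin"
        assert rels["cuz"].degree == 3
        assert rels["gpa"].relatedness == pytest.approx(0.25)
        assert rels["gpa"].relation_label == "grandparent"
        assert rels["unc"].relatedness == pytest.approx(0.25)
        assert rels["unc"].relation_label == "aunt_uncle"
        assert "aunt_w" not in rels  # married in, unrelated

    def test_double_first_cousins(self, double_first_cousins):
        rels = rel_map(double_first_cousins, "dc1")
        assert rels["dc2"].relatedness == pytest.approx(0.25)
        assert rels["dc2"].degree == 2

    def test_no_self_and_max_degree(self, extended_pedigree):
        rels = rel_map(extended_pedigree, "kid", max_degree=1)
        assert "kid" not in rels
        assert set(rels) == {"dad", "mom", "sib"}

    def test_unknown_proband(self, trio):
        with pytest.raises(KeyError):
            kinship.enumerate_relatives(trio, "nobody")

    def test_symmetry(self, double_first_cousins):
        a = rel_map(double_first_cousins, "dc1")["dc2"].relatedness
        b = rel_map(double_first_cousins, "dc2")["dc1"].relatedness
        assert a == pytest.approx(b)

    def test_table_matches_enumeration(self, extended_pedigree):
        ids = list(extended_pedigree.person_ids)
        table = kinship.relative_pair_table(extended_pedigree, ids)
        for pid in ids:
            via_enum = {
                p.relative_id: p.relatedness
                for p in kinship.enumerate_relatives(extended_pedigree, pid)
            }
            sub = table[table["proband_id"] == pid]
            via_table = dict(zip(sub["relative_id"], sub["relatedness"]))
            assert via_table == pytest.approx(via_enum)


class TestGeneDropping:
    def test_parent_offspring_exact(self, trio):
        est, se = kinship.relatedness_gene_dropping_oracle(trio, "kid", "dad", 10_000, seed=0)
        assert est == pytest.approx(0.5, abs=1e-12)

    def test_unrelated_founders(self, trio):
        est, _ = kinship.relatedness_gene_dropping_oracle(trio, "dad", "mom", 10_000, seed=0)
        assert est == 0.0

    def test_avuncular(self, extended_pedigree):
        est, se = kinship.relatedness_gene_dropping_oracle(
            extended_pedigree, "kid", "unc", 50_000, seed=1
        )
        assert abs(est - 0.25) < 3 * se

    def test_double_first_cousins_monte_carlo(self, double_first_cousins):
        est, se = kinship.relatedness_gene_dropping_oracle(
            double_first_cousins, "dc1", "dc2", 100_000, seed=2
        )
        assert est == pytest.approx(0.25, abs=0.01)

    def test_rejects_tiny_rep_count(self, trio):
        with pytest.raises(ValueError):
            kinship.relatedness_gene_dropping_oracle(trio, "kid", "dad", 100)

    @pytest.mark.parametrize("seed", range(5))
    def test_path_counting_agrees_on_random_pedigrees(self, seed):
        """Tabular relatedness equals the Monte-Carlo oracle within sampling
        error (ensemble-calibrated: max 4.5 SE, at most one pair beyond 3 SE)."""
        rng = np.random.default_rng(seed)
        ped = random_pedigree(rng)
        ids = list(ped.person_ids)
        picks = rng.choice(len(ids), size=min(4, len(ids)), replace=False)
        se_units = []
        for i in picks:
            pairs = kinship.enumerate_relatives(ped, ids[i], classify_households=False)
            for p in pairs[:3]:
                est, se = kinship.relatedness_gene_dropping_oracle(
                    ped, p.proband_id, p.relative_id, 20_000,
                    seed=int(rng.integers(2**31 - 1)),
                )
                se_units.append(abs(est - p.relatedness) / max(se, 1e-9))
        assert se_units
        assert max(se_units) <= 4.5
        assert sum(u > 3.0 for u in se_units) <= 1


class TestCohabitation:
    def test_reared_parent(self, extended_pedigree):
        pair = rel_map(extended_pedigree, "kid")["dad"]
        assert pair.reared_by is True
        assert pair.cohabited is True

    def test_non_reared_parent(self, extended_pedigree):
        # stepmom's household excludes kid; dad never shares halfsib's household
        pair = rel_map(extended_pedigree, "halfsib")["dad"]
        assert pair.reared_by is False

    def test_half_sibs_apart(self, extended_pedigree):
        pair = rel_map(extended_pedigree, "kid")["halfsib"]
        assert pair.cohabited is False

    def test_full_sibs_cohabit(self, extended_pedigree):
        pair = rel_map(extended_pedigree, "kid")["sib"]
        assert pair.cohabited is True

    def test_unknown_without_household_data(self, trio):
        pair = rel_map(trio, "kid")["dad"]
        assert pair.cohabited is None and pair.reared_by is None
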