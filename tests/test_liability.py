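"""Liability-threshold identities, onset CDFs, time-at-risk weights."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from fgrs import liability as lia
from fgrs.io_registry import FEMALE, MALE

from conftest import make_pedigree


def numeric_conditional_means(K: float) -> tuple[float, float]:
    """Truncated-normal means by numerical integration (independent oracle)."""
    t = stats.norm.isf(K)
    above, _ = integrate.quad(lambda x: x * stats.norm.pdf(x), t, 12)
    below, _ = integrate.quad(lambda x: x * stats.norm.pdf(x), -12, t)
    return above / K, below / (1 - K)


class TestConditionalMeans:
    def test_half_prevalence(self):
        z_aff, z_unaff = lia.conditional_means(0.5)
        assert z_aff == pytest.approx(0.7979, abs=1e-4)
        assert z_unaff == pytest.approx(-0.7979, abs=1e-4)

    def test_one_percent_threshold(self):
        assert lia.threshold_from_prevalence(0.01) == pytest.approx(2.3263, abs=1e-4)

    @pytest.mark.parametrize("K", [0.001, 0.01, 0.1, 0.25, 0.5, 0.9])
    def test_against_numerical_integration(self, K):
        z_aff, z_unaff = lia.conditional_means(K)
        num_aff, num_unaff = numeric_conditional_means(K)
        assert z_aff == pytest.approx(num_aff, abs=1e-8)
        assert z_unaff == pytest.approx(num_unaff, abs=1e-8)

    def test_conservation_identity(self):
        rng = np.random.default_rng(1)
        K = rng.uniform(0.001, 0.999, size=200)
        z_aff, z_unaff = lia.conditional_means(K)
        assert np.allclose(K * z_aff + (1 - K) * z_unaff, 0.0, atol=1e-12)

    def test_z_affected_monotone_in_rarity(self):
        K = np.array([0.5, 0.1, 0.01, 0.001])
        z_aff, _ = lia.conditional_means(K)
        assert np.all(np.diff(z_aff) > 0)


class TestEstimateThresholds:
    def _events(self, ids):
        return pd.DataFrame({"person_id": ids, "disorder": "FM", "year": 2000})

    def test_stratum_prevalence(self):
        rows = [(f"p{i}", None, None, FEMALE, 1955, 2017) for i in range(100)]
        ped = make_pedigree(rows)
        ev = self._events([f"p{i}" for i in range(10)])
        tab = lia.estimate_thresholds(ev, ped, "FM").table
        assert len(tab) == 1
        assert tab["K"].iloc[0] == pytest.approx(0.1)
        assert tab["t"].iloc[0] == pytest.approx(stats.norm.isf(0.1))

    def test_zero_case_stratum_floored(self):
        rows = [(f"p{i}", None, None, MALE, 1941, 2017) for i in range(50)]
        ped = make_pedigree(rows)
        ev = pd.DataFrame(columns=["person_id", "disorder", "year"])
        tab = lia.estimate_thresholds(ev, ped, "FM").table
        assert tab["K"].iloc[0] == pytest.approx(0.5 / 50)
        assert np.isfinite(tab["t"].iloc[0])

    def test_strict_small_stratum_raises(self):
        ped = make_pedigree([("a", None, None, MALE, 1950, 2017)])
        with pytest.raises(ValueError, match="n_min"):
            lia.estimate_thresholds(self._events(["a"]), ped, "FM", strict=True)

    def test_missing_stratum_lookup_raises(self):
        rows = [(f"p{i}", None, None, FEMALE, 1955, 2017) for i in range(10)]
        ped = make_pedigree(rows)
        tab = lia.estimate_thresholds(self._events(["p0"]), ped, "FM")
        with pytest.raises(KeyError):
            tab.lookup("FM", MALE, 1950)


class TestOnsetCDF:
    def test_empirical_steps(self):
        ped = make_pedigree([(f"p{i}", None, None, FEMALE, 1950, 2017) for i in range(3)])
        ev = pd.DataFrame(
            {"person_id": ["p0", "p1", "p2"], "disorder": "FM",
             "year": [1980, 1990, 2000]}  # ages 30, 40, 50
        )
        cdf = lia.estimate_onset_cdf(ev, ped, "FM")
        assert cdf(29) == 0.0
        assert cdf(30) == pytest.approx(1 / 3)
        assert cdf(45) == pytest.approx(2 / 3)
        assert cdf(50) == 1.0

    def test_single_age_step(self):
        ped = make_pedigree([("a", None, None, FEMALE, 1950, 2017)])
        ev = pd.DataFrame({"person_id": ["a"], "disorder": "FM", "year": [1990]})
        cdf = lia.estimate_onset_cdf(ev, ped, "FM")
        assert cdf(39) == 0.0 and cdf(40) == 1.0

    def test_no_events_raises(self, trio):
        ev = pd.DataFrame(columns=["person_id", "disorder", "year"])
        with pytest.raises(ValueError, match="no usable"):
            lia.estimate_onset_cdf(ev, trio, "FM")

    def test_register_era_filter(self):
        ped = make_pedigree([(f"p{i}", None, None, FEMALE, 1950, 2017) for i in range(2)])
        ev = pd.DataFrame(
            {"person_id": ["p0", "p1"], "disorder": "FM", "year": [1990, 2000]}
        )
        cdf = lia.estimate_onset_cdf(ev, ped, "FM", register_start_year=1997)
        assert cdf.n_events == 1

    def test_matches_generating_distribution(self):
        """With full coverage and complete follow-up, the empirical onset CDF
        reproduces the simulator's Weibull (KS < 0.03)."""
        from fgrs import synthetic_data as synth

        cfg = synth.single_disorder_config(
            h2=0.3, prevalence=0.5, n_families=120,
            follow_up_end=2300, life_expectancy=250.0, life_sd=1.0,
        )
        res = synth.simulate(cfg, seed=99)
        spec = cfg.disorders[0]
        cdf = lia.estimate_onset_cdf(res.events, res.pedigree, spec.name)
        assert cdf.n_events > 3000
        grid = np.arange(0, 200)
        wb = stats.weibull_min(spec.onset["shape"], scale=spec.onset["scale"])
        ks = np.abs(cdf(grid) - wb.cdf(grid + 0.5)).max()
        assert ks < 0.03


class TestTimeAtRiskWeight:
    def _uniform_cdf(self):
        ages = np.arange(20, 81)
        return lia.OnsetCDF("FM", ages, (ages - 19) / 61.0, n_events=61)

    def test_complete_follow_up(self):
        cdf = self._uniform_cdf()
        w = lia.time_at_risk_weight(1900, 1990, cdf, register_start_year=1900)
        assert w == pytest.approx(1.0)

    def test_death_at_birth(self):
        cdf = self._uniform_cdf()
        assert lia.time_at_risk_weight(1950, 1950, cdf, 1900) == 0.0

    def test_left_truncated_uniform(self):
        """Born 1940, register opens 1997, followed to 2017, onsets ~U(20,80)."""
        cdf = self._uniform_cdf()
        w = lia.time_at_risk_weight(1940, 2017, cdf, register_start_year=1997)
        expected = (cdf(77) - cdf(57)) / (1 - cdf(57))
        assert w == pytest.approx(expected)
        assert w == pytest.approx(0.87, abs=0.02)  # continuous-uniform value 0.8696

    def test_pre_register_life_carries_no_information(self):
        cdf = self._uniform_cdf()
        # dead before the register opened: whole risk period unobservable
        w = lia.time_at_risk_weight(1900, 1990, cdf, register_start_year=1997)
        assert w == 0.0

    def test_monotone_in_follow_up(self):
        cdf = self._uniform_cdf()
        ends = np.arange(1950, 2018)
        w = lia.time_at_risk_weight(
            np.full_like(ends, 1940), ends, cdf, register_start_year=1900
        )
        assert np.all(np.diff(w) >= 0)


class TestLiabilityZscore:
    def test_status_selects_conditional_mean(self):
        rows = [(f"p{i}", None, None, FEMALE, 1955, 2017) for i in range(10)]
        ped = make_pedigree(rows)
        ev = pd.DataFrame({"person_id": [f"p{i}" for i in range(5)],
                           "disorder": "FM", "year": 2000})
        tab = lia.estimate_thresholds(ev, ped, "FM")
        z_aff = lia.liability_zscore(tab, "FM", FEMALE, 1955, affected=True)
        z_unaff = lia.liability_zscore(tab, "FM", FEMALE, 1955, affected=False)
        assert z_aff == pytest.approx(0.7979, abs=1e-4)
        assert z_unaff == pytest.approx(-0.7979, abs=1e-4)
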