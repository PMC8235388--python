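"""Tests for nutrient accounting, VaR and NAR statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutrisk import nutrition_risk as nr
from nutrisk.shock_engine import ConsumptionDistribution


class TestNutrientSupply:
    def test_zero_supply(self):
        out = nr.nutrient_supply(0.0, {"protein": 0.12, "iron": 0.035})
        assert all(v == 0.0 for v in out.values())

    def test_arithmetic(self):
        out = nr.nutrient_supply(100.0, {"protein": 0.1})
        assert out["protein"] == pytest.approx(10.0)

    def test_linearity(self):
        profile = {"protein": 0.123, "zinc": 0.026}
        one = nr.nutrient_supply(50.0, profile)
        two = nr.nutrient_supply(100.0, profile)
        for n in profile:
            assert two[n] == pytest.approx(2 * one[n])

    def test_negative_supply_rejected(self):
        with pytest.raises(ValueError):
            nr.nutrient_supply(-1.0, {"protein": 1.0})


class TestPopulationRequirement:
    def test_single_stratum_arithmetic(self):
        pyramid = pd.Series({"20-39|F": 1.0})
        rni = pd.DataFrame({"protein": [50.0]}, index=["20-39|F"])
        req = nr.population_requirement(pyramid, rni, births=0.0)
        assert req["protein"] == pytest.approx(18_250.0)

    def test_zero_births_no_increment(self):
        pyramid = pd.Series({"a": 2.0})
        rni = pd.DataFrame({"iron": [10.0]}, index=["a"])
        with_births = nr.population_requirement(
            pyramid, rni, births=100.0, pregnancy_increment={"iron": 9.0}
        )
        without = nr.population_requirement(
            pyramid, rni, births=0.0, pregnancy_increment={"iron": 9.0}
        )
        assert with_births["iron"] - without["iron"] == pytest.approx(100 * 9.0 * 365)

    def test_spreadsheet_oracle_four_strata(self):
        """Independent spreadsheet-style recomputation on a toy pyramid."""
        strata = ["child|F", "child|M", "adult|F", "adult|M"]
        counts = [120.0, 130.0, 400.0, 380.0]
        protein = [20.0, 22.0, 46.0, 56.0]
        energy = [1400.0, 1500.0, 2200.0, 2600.0]
        births = 12.0
        preg = {"protein": 6.0, "energy": 280.0}
        biomass = 1.07
        # hand computation, cell by cell
        expected_protein = 0.0
        expected_energy = 0.0
        for c, pr, en in zip(counts, protein, energy):
            expected_protein += c * pr
            expected_energy += c * en
        expected_protein = (expected_protein + births * preg["protein"]) * biomass * 365
        expected_energy = (expected_energy + births * preg["energy"]) * biomass * 365

        pyramid = pd.Series(dict(zip(strata, counts)))
        rni = pd.DataFrame({"protein": protein, "energy": energy}, index=strata)
        req = nr.population_requirement(
            pyramid, rni, births=births, biomass_adjustment=biomass,
            pregnancy_increment=preg,
        )
        assert req["protein"] == pytest.approx(expected_protein, rel=1e-12)
        assert req["energy"] == pytest.approx(expected_energy, rel=1e-12)

    def test_biomass_only_scales_energy_protein(self):
        pyramid = pd.Series({"a": 10.0})
        rni = pd.DataFrame({"protein": [50.0], "iron": [10.0]}, index=["a"])
        r1 = nr.population_requirement(pyramid, rni, biomass_adjustment=1.0)
        r2 = nr.population_requirement(pyramid, rni, biomass_adjustment=1.2)
        assert r2["protein"] == pytest.approx(1.2 * r1["protein"])
        assert r2["iron"] == pytest.approx(r1["iron"])

    def test_missing_stratum_rejected(self):
        pyramid = pd.Series({"a": 1.0, "ghost": 2.0})
        rni = pd.DataFrame({"protein": [50.0]}, index=["a"])
        with pytest.raises(ValueError, match="ghost"):
            nr.population_requirement(pyramid, rni)

    def test_negative_counts_rejected(self):
        pyramid = pd.Series({"a": -1.0})
        rni = pd.DataFrame({"protein": [50.0]}, index=["a"])
        with pytest.raises(ValueError, match="nonnegative"):
            nr.population_requirement(pyramid, rni)


class TestValueAtRisk:
    def test_forced_order_statistic(self):
        dist = np.array([-10.0, -5.0] + [0.0] * 18)
        assert nr.value_at_risk(dist, 0.05) == -10.0

    def test_all_zero(self):
        assert nr.value_at_risk(np.zeros(100), 0.05) == 0.0

    def test_uniform_analytic(self):
        """5% VaR of U(-1, 0) is about -0.95; mean over replicates."""
        rng = np.random.default_rng(0)
        estimates = [
            nr.value_at_risk(rng.uniform(-1.0, 0.0, size=1000), 0.05)
            for _ in range(100)
        ]
        assert float(np.mean(estimates)) == pytest.approx(-0.95, abs=0.02)

    def test_50th_smallest_of_1000(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=1000)
        assert nr.value_at_risk(v, 0.05) == float(np.sort(v)[49])

    @given(
        values=st.lists(st.floats(-100, 100), min_size=1, max_size=200),
        p=st.floats(0.01, 0.49),
    )
    @settings(max_examples=100, deadline=None)
    def test_brute_force_sort_oracle(self, values, p):
        import math

        v = np.asarray(values)
        expected = sorted(values)[math.ceil(p * len(values)) - 1]
        assert nr.value_at_risk(v, p) == expected

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=500)
        vars_ = [nr.value_at_risk(v, p) for p in (0.01, 0.05, 0.1, 0.25, 0.49)]
        assert vars_ == sorted(vars_)

    def test_bad_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            nr.value_at_risk(np.array([]), 0.05)
        with pytest.raises(ValueError, match="probability"):
            nr.value_at_risk(np.zeros(10), 0.6)


class TestNAR:
    def test_identity_share(self):
        out = nr.nar(-10.0, {"protein": 1.0})
        assert out[0].nar_pct == pytest.approx(-10.0)

    def test_linearity_in_share(self):
        out = nr.nar(-10.0, {"zinc": 2.0})
        assert out[0].nar_pct == pytest.approx(-20.0)

    def test_zero_share(self):
        out = nr.nar(-50.0, {"folate": 0.0})
        assert out[0].nar_pct == 0.0

    def test_one_record_per_nutrient(self):
        out = nr.nar(-5.0, {"protein": 1.0, "zinc": 0.5, "iron": 0.2}, region="m")
        assert {r.nutrient for r in out} == {"protein", "zinc", "iron"}
        assert all(r.region == "m" for r in out)

    def test_high_dependence_consistency_pattern(self):
        """Back-solved shares times a -13.7% tail loss reproduce the
        high-dependence NAR pattern (-18.0% protein, -37.4% magnesium)
        as an exact arithmetic identity."""
        var = -13.7
        shares = {"protein": 18.0 / 13.7, "magnesium": 37.4 / 13.7}
        out = {r.nutrient: r.nar_pct for r in nr.nar(var, shares)}
        assert out["protein"] == pytest.approx(-18.0, abs=1e-9)
        assert out["magnesium"] == pytest.approx(-37.4, abs=1e-9)

    @given(
        var=st.floats(-50, 0),
        share=st.floats(0, 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_exact_linearity(self, var, share):
        out = nr.nar(var, {"x": share})
        assert out[0].nar_pct == var * share


class TestContributionShare:
    def test_validation(self):
        with pytest.raises(ValueError, match="nonnegative"):
            nr.ContributionShare({"m": {"protein": -0.1}})

    def test_lookup(self):
        cs = nr.ContributionShare({"m": {"protein": 1.31}})
        assert cs.of("m", "protein") == pytest.approx(1.31)


class TestReturnPeriodAmplification:
    def _dist(self, values, scenario="Y", seed=0):
        v = np.asarray(values, dtype=float)
        return ConsumptionDistribution(
            region="r", values=v, scenario=scenario, seed=seed, n_draws=v.size
        )

    def test_identity(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=500)
        out = nr.return_period_amplification(self._dist(v), self._dist(v, "YQ"), 0.05)
        assert out["probability"] == pytest.approx(0.05, abs=1e-12)
        assert out["return_period_years"] == pytest.approx(20.0)

    def test_shifted_down_probability_one(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=200)
        shifted = v - (v.max() - v.min()) - 1.0
        out = nr.return_period_amplification(
            self._dist(v), self._dist(shifted, "YQ"), 0.05
        )
        assert out["probability"] == 1.0

    def test_unpaired_rejected(self):
        a = self._dist(np.zeros(100))
        b = self._dist(np.zeros(99), "YQ")
        with pytest.raises(ValueError, match="draw counts"):
            nr.return_period_amplification(a, b)
        c = self._dist(np.zeros(100), "YQ", seed=1)
        with pytest.raises(ValueError, match="seeds"):
            nr.return_period_amplification(a, c)


class TestNarTable:
    def test_flagging(self):
        records = nr.nar(-10.0, {"protein": 1.0, "iron": 0.2}, region="m")
        records += nr.nar(-1.0, {"protein": 1.0, "iron": 0.2}, region="ok")
        table = nr.nar_table(records, flag_threshold=5.0)
        assert table.loc["m", "flagged"] == "protein"
        assert table.loc["ok", "flagged"] == ""

    def test_empty(self):
        assert nr.nar_table([]).empty
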