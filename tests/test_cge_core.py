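"""Tests for the equilibrium system, solver, quotas and Walras diagnostics."""

import numpy as np
import pytest

from nutrisk import cge_core as cg
from nutrisk import sam_calibration as sc
from nutrisk import synthetic_world as sw


def ones(n):
    return cg.ShockVector.ones(n)


class TestShockVector:
    def test_floor_enforced(self):
        with pytest.raises(ValueError, match="floor"):
            cg.ShockVector(np.array([0.2, 1.0]))

    def test_custom_floor(self):
        cg.ShockVector(np.array([0.1, 1.0]), floor=0.1)


class TestBuildSystem:
    def test_benchmark_residual_tiny(self, default_params):
        system = cg.build_system(default_params, ones(3))
        r = system.residual(system.benchmark_point())
        assert np.max(np.abs(r)) < 1e-8

    def test_census_balances(self, default_params):
        system = cg.build_system(default_params, ones(3))
        census = system.census()
        assert sum(census["unknowns"].values()) == sum(census["equations"].values())
        R, S = default_params.n_regions, default_params.n_sectors
        assert census["unknowns"]["mobile wage"] == R
        assert census["equations"]["composite clearing"] == R * S

    def test_shock_locality_at_benchmark(self, default_params):
        """A wheat shifter in one region perturbs only that region's wheat
        zero-profit and wheat-market blocks at the benchmark point."""
        p = default_params
        R, S = p.n_regions, p.n_sectors
        shock = cg.ShockVector(np.array([0.9, 1.0, 1.0]))
        system = cg.build_system(p, shock)
        r = system.residual(system.benchmark_point())
        wheat = p.sector_index(p.wheat_sector)
        # block layout: [labor (R)] [zero profit (R*S)] [composite (R*S)] [links]
        zp = r[R : R + R * S].reshape(R, S)
        assert abs(zp[0, wheat]) > 1e-3
        mask = np.ones((R, S), dtype=bool)
        mask[0, wheat] = False
        assert np.max(np.abs(zp[mask])) < 1e-10
        goods = r[R + R * S : R + 2 * R * S].reshape(R, S)
        mask_goods = np.ones((R, S), dtype=bool)
        mask_goods[0, wheat] = False
        assert np.max(np.abs(goods[mask_goods])) < 1e-10

    def test_wrong_shock_length(self, default_params):
        with pytest.raises(ValueError, match="entries"):
            cg.build_system(default_params, ones(5))


class TestSolve:
    def test_benchmark_replication(self, default_params):
        sol = cg.solve(cg.build_system(default_params, ones(3)))
        assert sol.converged
        np.testing.assert_allclose(sol.p_composite, 1.0, atol=1e-8)
        np.testing.assert_allclose(sol.wage, 1.0, atol=1e-8)
        np.testing.assert_allclose(
            sol.consumption, default_params.benchmark["C"], rtol=1e-8
        )
        np.testing.assert_allclose(
            sol.gross_output, default_params.benchmark["Z"], rtol=1e-8
        )

    def test_continuity_small_shock(self, default_params):
        """Consumption responds linearly to a small shock: the response to
        +eps mirrors the response to -eps (first-order continuity oracle)."""
        eps = 1e-4
        up = cg.solve(
            cg.build_system(default_params, cg.ShockVector(np.array([1 + eps, 1, 1])))
        )
        dn = cg.solve(
            cg.build_system(default_params, cg.ShockVector(np.array([1 - eps, 1, 1])))
        )
        base = default_params.benchmark["C"]
        dup = up.consumption - base
        ddn = dn.consumption - base
        # symmetric first-order response; curvature is O(eps^2)
        np.testing.assert_allclose(dup, -ddn, rtol=5e-3, atol=1e-9 * np.max(base))

    def test_symmetric_world_symmetric_solution(self, symmetric_params):
        sol = cg.solve(
            cg.build_system(symmetric_params, cg.ShockVector(np.array([0.8, 0.8])))
        )
        assert sol.wage[0] == pytest.approx(sol.wage[1], rel=1e-8)
        np.testing.assert_allclose(sol.consumption[0], sol.consumption[1], rtol=1e-8)
        np.testing.assert_allclose(sol.p_composite[0], sol.p_composite[1], rtol=1e-8)

    def test_solution_positive_and_converged(self, default_params):
        sol = cg.solve(
            cg.build_system(default_params, cg.ShockVector(np.array([0.3, 1.2, 0.9])))
        )
        assert sol.converged and sol.max_residual < 1e-7
        for arr in (sol.p_composite, sol.wage, sol.consumption, sol.gross_output):
            assert (arr > 0).all()

    def test_budget_exhausted(self, default_params):
        """Household spending plus savings equals income within 1e-7."""
        p = default_params
        sol = cg.solve(cg.build_system(p, cg.ShockVector(np.array([0.6, 1.0, 1.1]))))
        for ri in range(p.n_regions):
            spend = float((sol.p_composite[ri] * sol.consumption[ri]).sum())
            total = spend + p.savings_rate[ri] * sol.income[ri]
            assert total == pytest.approx(sol.income[ri], rel=1e-9)

    def test_homogeneity_renormalization(self, default_params):
        """Shifting all log prices uniformly leaves every residual unchanged:
        real quantities are invariant to the price-level normalization."""
        system = cg.build_system(
            default_params, cg.ShockVector(np.array([0.7, 1.0, 1.0]))
        )
        sol = cg.solve(system)
        x = np.concatenate(
            [
                np.log(sol.wage),
                np.log(sol.capital_price).ravel(),
                np.log(sol.p_domestic).ravel(),
                np.log(sol.p_world),
            ]
        )
        r0 = system.residual(x)
        shift = np.full_like(x, 0.37)
        r1 = system.residual(x + shift)
        np.testing.assert_allclose(r1, r0, atol=1e-8)

    def test_numeraire_wage_is_one(self, default_params):
        sol = cg.solve(
            cg.build_system(default_params, cg.ShockVector(np.array([0.5, 1.0, 1.0])))
        )
        assert sol.wage[0] == pytest.approx(1.0, abs=1e-12)

    def test_deterministic(self, default_params):
        s1 = cg.solve(cg.build_system(default_params, cg.ShockVector(np.array([0.7, 1, 1]))))
        s2 = cg.solve(cg.build_system(default_params, cg.ShockVector(np.array([0.7, 1, 1]))))
        np.testing.assert_array_equal(s1.consumption, s2.consumption)


class TestWalras:
    def test_all_markets_clear(self, default_params):
        p = default_params
        sol = cg.solve(cg.build_system(p, cg.ShockVector(np.array([0.4, 1.3, 1.0]))))
        for r in p.regions:
            assert abs(cg.excess_demand(sol, ("labor", r))) < 1e-7 * p.labor_endow.max()
            for s in p.sectors:
                assert abs(cg.excess_demand(sol, ("commodity", r, s))) < 1e-6

    def test_dropped_bop_market_clears(self, default_params):
        """Walras' law: the balance-of-payments gaps, never solved for,
        vanish at every converged solution."""
        sol = cg.solve(
            cg.build_system(default_params, cg.ShockVector(np.array([0.4, 1.3, 1.0])))
        )
        for r in default_params.regions:
            assert abs(cg.excess_demand(sol, ("bop", r))) < 1e-6

    def test_perturbed_point_nonzero(self, default_params):
        sol = cg.solve(cg.build_system(default_params, cg.ShockVector.ones(3)))
        sol.consumption = sol.consumption * 1.01  # off-equilibrium by hand
        gaps = [
            cg.excess_demand(sol, ("commodity", r, s))
            for r in default_params.regions
            for s in default_params.sectors
        ]
        assert max(abs(g) for g in gaps) > 1e-3

    def test_unknown_market(self, default_params):
        sol = cg.solve(cg.build_system(default_params, cg.ShockVector.ones(3)))
        with pytest.raises(KeyError):
            cg.excess_demand(sol, ("stock market", "alpha"))


class TestQuotas:
    def test_nonbinding_quota_reproduces_reference(self, toy_params):
        qs = sc.quota_baseline(toy_params, ["exporter"], 1.0)
        sol = cg.solve(cg.build_system(toy_params, ones(3), qs))
        np.testing.assert_allclose(
            sol.consumption, toy_params.benchmark["C"], rtol=1e-9
        )
        assert sol.active_quotas == []

    def test_complementarity_bilateral(self, toy_params):
        qs = sc.quota_baseline(toy_params, ["exporter"], 0.5)
        sol = cg.solve(cg.build_system(toy_params, ones(3), qs))
        wheat = toy_params.sector_index("wheat")
        for (ex, im), ceil in qs.bilateral_ceilings.items():
            lid = toy_params.links.index(
                (toy_params.region_index(ex), toy_params.region_index(im), wheat)
            )
            exports = sol.trade_supply[lid]
            key = str(("link", lid, ceil))
            rent = sol.quota_rents.get(key, 0.0)
            binding = any(c[0] == "link" and c[1] == lid for c in sol.active_quotas)
            if binding:
                assert exports == pytest.approx(ceil, rel=1e-7)
                assert rent >= -1e-7
            else:
                assert exports <= ceil * (1 + 1e-7)

    def test_complementarity_aggregate(self, toy_params):
        qs = sc.quota_baseline(toy_params, ["exporter"], 0.5, mode="aggregate")
        sol = cg.solve(cg.build_system(toy_params, ones(3), qs))
        wheat = toy_params.sector_index("wheat")
        ei = toy_params.region_index("exporter")
        lids = toy_params.export_links[ei][wheat]
        total = float(sol.trade_supply[lids].sum())
        ceil = qs.aggregate_ceilings["exporter"]
        assert total == pytest.approx(ceil, rel=1e-7)
        assert all(v >= -1e-7 for v in sol.quota_rents.values())

    def test_rents_add_to_exporter_income(self, toy_params):
        qs = sc.quota_baseline(toy_params, ["exporter"], 0.5)
        sol = cg.solve(cg.build_system(toy_params, ones(3), qs))
        assert sum(sol.quota_rents.values()) > 0
        # Walras still holds with rents routed to the exporter household
        for r in toy_params.regions:
            assert abs(cg.excess_demand(sol, ("bop", r))) < 1e-6


class TestMechanism:
    def test_exporter_shock_hurts_importer(self, toy_params, toy_benchmark):
        """Lowering the dominant exporter's wheat productivity from 1.0 to
        0.7 raises the importer's wheat composite price and strictly lowers
        importer household wheat consumption."""
        wheat = toy_params.sector_index("wheat")
        imp = toy_params.region_index("importer")
        shocked = cg.solve(
            cg.build_system(toy_params, cg.ShockVector(np.array([0.7, 1.0, 1.0])))
        )
        assert shocked.p_composite[imp, wheat] > toy_benchmark.p_composite[imp, wheat]
        assert shocked.consumption[imp, wheat] < toy_benchmark.consumption[imp, wheat]

    def test_quota_deepens_importer_loss(self, toy_params):
        shock = cg.ShockVector(np.array([0.7, 1.0, 1.0]))
        free = cg.solve(cg.build_system(toy_params, shock))
        qs = sc.quota_baseline(toy_params, ["exporter"], 0.5)
        gated = cg.solve(cg.build_system(toy_params, shock, qs))
        assert gated.consumption_change_pct("importer") < free.consumption_change_pct(
            "importer"
        )
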