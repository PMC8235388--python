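"""Static multi-region equilibrium system and solver.

Structure per region: Leontief gross output over intermediate composites
and a CES value-added bundle (mobile labor + sector-specific capital,
both fully employed); a Hicks-neutral productivity shifter multiplies
the wheat sector's gross output per unit of the input bundle; CET
allocation between domestic sales and exports with a second CET
distributing exports across destinations; Armington CES aggregation of
domestic goods with imports, sourced bilaterally by a second CES;
two-stage household demand (CES food nest, Cobb-Douglas top);
savings-driven investment with fixed expenditure shares; fixed foreign
savings.

Formulation and numeraire.  The solved unknowns are the mobile wage,
specific-factor prices, domestic-good prices and bilateral world prices
(all in log space).  Quantities follow from first-order conditions and
full employment, so zero profit, budget balance, factor-market clearing
and savings-investment balance hold *by construction* at every
evaluation point.  Under the savings-driven closure with fixed foreign
savings, each region's balance of payments is then implied by its
internal market-clearing equations (a per-region Walras identity),
which also makes nominal exchange rates indeterminate; they are
therefore normalized to 1 and every balance-of-payments gap is exposed
through :func:`excess_demand` as the Walras-law oracle instead of being
solved for.  The world price level is anchored by the exogenous foreign
savings; when those are all zero the Newton step falls back to a
minimum-norm least-squares solve, which handles the resulting scaling
ray gracefully.

Export quotas are solved by active-set iteration: solve unconstrained,
clamp violated ceilings to equality with a rent wedge between the
importer-faced and exporter-faced price, re-solve, and drop constraints
whose rents turn negative.  Rents accrue to the exporting household.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import SolverError
from .sam_calibration import CalibratedParams, QuotaSet

__all__ = [
    "ShockVector",
    "EquilibriumSystem",
    "EquilibriumSolution",
    "build_system",
    "solve",
    "excess_demand",
]

log = logging.getLogger(__name__)

_PRICE_FLOOR = 1e-9


@dataclass(frozen=True)
class ShockVector:
    """Per-region multiplicative wheat productivity shifters (benchmark 1)."""

    values: np.ndarray
    floor: float = 0.3

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < self.floor - 1e-12):
            raise ValueError(f"shock entries must be >= floor {self.floor}")

    @classmethod
    def ones(cls, n_regions: int) -> "ShockVector":
        return cls(values=np.ones(n_regions))


@dataclass
class EquilibriumSolution:
    """Solved prices, quantities and diagnostics for one shock draw."""

    params: CalibratedParams
    shock: np.ndarray
    converged: bool
    iterations: int
    max_residual: float
    # prices
    wage: np.ndarray  # (R,)
    capital_price: np.ndarray  # (R, S)
    p_domestic: np.ndarray
    p_export: np.ndarray
    p_import: np.ndarray
    p_output: np.ndarray
    p_composite: np.ndarray
    p_value_added: np.ndarray
    p_food: np.ndarray
    p_world: np.ndarray  # (L,) importer-faced bilateral prices
    p_world_supply: np.ndarray  # (L,) exporter-faced bilateral prices
    exchange_rate: np.ndarray  # (R,) normalized to 1 (see module docstring)
    # quantities
    gross_output: np.ndarray
    value_added: np.ndarray
    labor: np.ndarray  # (R, S)
    domestic: np.ndarray
    exports: np.ndarray
    imports: np.ndarray
    composite: np.ndarray
    trade_supply: np.ndarray  # (L,)
    trade_demand: np.ndarray  # (L,)
    consumption: np.ndarray  # (R, S)
    food_composite: np.ndarray  # (R,)
    investment: np.ndarray  # (R, S)
    utility: np.ndarray  # (R,)
    income: np.ndarray  # (R,)
    quota_rents: dict = field(default_factory=dict)
    active_quotas: list = field(default_factory=list)

    def consumption_change_pct(self, region: str, sector: str | None = None) -> float:
        """Household consumption change vs. benchmark, percent."""
        p = self.params
        ri = p.region_index(region)
        si = p.sector_index(sector or p.wheat_sector)
        base = p.benchmark["C"][ri, si]
        return 100.0 * (self.consumption[ri, si] / base - 1.0)


class EquilibriumSystem:
    """Square nonlinear system F(x) = 0 for one shock draw.

    Unknowns (log space): mobile wage per region, specific-factor price
    per region-sector, domestic price per region-sector, one world price
    per active bilateral link, plus one wedge unknown per active quota
    constraint.  Equations: mobile-factor clearing, value-added
    zero-profit (unit cost = value-added price), composite-good
    clearing, bilateral link clearing, and one ceiling equation per
    active quota constraint.
    """

    def __init__(
        self,
        params: CalibratedParams,
        shock: ShockVector,
        quotas: QuotaSet | None = None,
    ):
        self.params = params
        self.quotas = quotas
        R, S = params.n_regions, params.n_sectors
        if shock.values.shape != (R,):
            raise ValueError(f"shock vector must have {R} entries")
        self.shock = np.ones((R, S))
        wi = params.sector_index(params.wheat_sector)
        self.shock[:, wi] = shock.values
        self.wheat_idx = wi
        self.L = len(params.links)

        # unknown layout
        self.n_w = R
        self.n_rk = R * S
        self.n_pd = R * S
        self.i_w = 0
        self.i_rk = self.i_w + self.n_w
        self.i_pd = self.i_rk + self.n_rk
        self.i_pw = self.i_pd + self.n_pd
        self.n_base = self.i_pw + self.L

        # active quota bookkeeping (list of constraint descriptors)
        # bilateral: ("link", link_id, ceiling); aggregate: ("agg", region_id, ceiling)
        self.active: list[tuple] = []

        self._quota_links: dict[int, float] = {}
        self._quota_agg: dict[int, float] = {}
        if quotas is not None:
            wi = params.sector_index(quotas.sector)
            if quotas.mode == "bilateral":
                for (ex, im), ceil in quotas.bilateral_ceilings.items():
                    lk = (params.region_index(ex), params.region_index(im), wi)
                    if lk in params.links:
                        self._quota_links[params.links.index(lk)] = ceil
            else:
                for ex, ceil in quotas.aggregate_ceilings.items():
                    self._quota_agg[params.region_index(ex)] = ceil

    # -- census -------------------------------------------------------------

    def census(self) -> dict[str, int]:
        R, S = self.params.n_regions, self.params.n_sectors
        n_active = len(self.active)
        unknowns = {
            "mobile wage": R,
            "specific-factor price": R * S,
            "domestic price": R * S,
            "bilateral world price": self.L,
            "quota wedge": n_active,
        }
        equations = {
            "mobile-factor clearing": R,
            "value-added zero profit": R * S,
            "composite clearing": R * S,
            "bilateral clearing": self.L,
            "quota ceiling": n_active,
        }
        assert sum(unknowns.values()) == sum(equations.values())
        return {"unknowns": unknowns, "equations": equations}

    @property
    def n_unknowns(self) -> int:
        return self.n_base + len(self.active)

    def benchmark_point(self) -> np.ndarray:
        return np.zeros(self.n_unknowns)

    # -- evaluation ---------------------------------------------------------

    def _unpack(self, x: np.ndarray):
        xc = np.clip(x, -30.0, 30.0)
        R, S = self.params.n_regions, self.params.n_sectors
        w = np.exp(xc[self.i_w : self.i_w + self.n_w])
        rk = np.exp(xc[self.i_rk : self.i_rk + self.n_rk]).reshape(R, S)
        p_d = np.exp(xc[self.i_pd : self.i_pd + self.n_pd]).reshape(R, S)
        pw = np.exp(xc[self.i_pw : self.i_pw + self.L])
        wedge = np.exp(xc[self.n_base :])  # exporter-faced price scale per constraint
        return w, rk, p_d, pw, wedge

    def _evaluate(self, x: np.ndarray) -> dict:
        p = self.params
        R, S = p.n_regions, p.n_sectors
        w, rk, p_d, pw, wedge = self._unpack(x)
        A = self.shock

        # exporter-faced bilateral prices: wedge scales below importer-faced
        pw_sup = pw.copy()
        for ci, cons in enumerate(self.active):
            if cons[0] == "link":
                pw_sup[cons[1]] = pw[cons[1]] * wedge[ci]
            else:  # aggregate: scale all wheat links of the exporter
                ri = cons[1]
                for lid in p.export_links[ri][self.wheat_idx]:
                    pw_sup[lid] = pw[lid] * wedge[ci]

        p_e = np.ones((R, S))
        p_m = np.ones((R, S))
        p_z = np.empty((R, S))
        p_q = np.empty((R, S))
        p_va = np.empty((R, S))
        VA = np.empty((R, S))
        L_dem = np.empty((R, S))
        c_va = np.empty((R, S))
        Z = np.empty((R, S))
        D_sup = np.empty((R, S))
        E = np.zeros((R, S))
        Q = np.empty((R, S))
        M = np.zeros((R, S))
        T_s = np.zeros(self.L)
        T_d = np.zeros(self.L)

        for ri in range(R):
            for si in range(S):
                en = p.export_nests[ri][si]
                if en is not None:
                    p_e[ri, si] = en.price(pw_sup[p.export_links[ri][si]])
                imn = p.import_nests[ri][si]
                if imn is not None:
                    p_m[ri, si] = imn.price(pw[p.import_links[ri][si]])
                ct = p.cet_top[ri][si]
                p_z[ri, si] = (
                    ct.price([p_d[ri, si], p_e[ri, si]]) if ct is not None else p_d[ri, si]
                )
                am = p.armington[ri][si]
                p_q[ri, si] = (
                    am.price([p_d[ri, si], p_m[ri, si]]) if am is not None else p_d[ri, si]
                )

        for ri in range(R):
            for si in range(S):
                p_va[ri, si] = max(
                    (A[ri, si] * p_z[ri, si] - float(p.ax[ri, :, si] @ p_q[ri]))
                    / p.ay[ri, si],
                    _PRICE_FLOOR,
                )
                vn = p.va_nests[ri][si]
                coefs = vn.coefs([w[ri], rk[ri, si]])
                VA[ri, si] = p.capital_endow[ri, si] / coefs[1]
                L_dem[ri, si] = coefs[0] * VA[ri, si]
                c_va[ri, si] = vn.price([w[ri], rk[ri, si]])
                Z[ri, si] = A[ri, si] * VA[ri, si] / p.ay[ri, si]

                ct = p.cet_top[ri][si]
                if ct is not None:
                    sc = ct.coefs([p_d[ri, si], p_e[ri, si]])
                    D_sup[ri, si] = sc[0] * Z[ri, si]
                    E[ri, si] = sc[1] * Z[ri, si]
                    en = p.export_nests[ri][si]
                    lids = p.export_links[ri][si]
                    T_s[lids] = en.coefs(pw_sup[lids]) * E[ri, si]
                else:
                    D_sup[ri, si] = Z[ri, si]

                am = p.armington[ri][si]
                if am is not None:
                    qc = am.coefs([p_d[ri, si], p_m[ri, si]])
                    Q[ri, si] = D_sup[ri, si] / qc[0]
                    M[ri, si] = qc[1] * Q[ri, si]
                    imn = p.import_nests[ri][si]
                    lids = p.import_links[ri][si]
                    T_d[lids] = imn.coefs(pw[lids]) * M[ri, si]
                else:
                    Q[ri, si] = D_sup[ri, si]

        # quota rents accrue to the exporting household
        rents = np.zeros(R)
        rent_detail: dict = {}
        for ci, cons in enumerate(self.active):
            if cons[0] == "link":
                lid, ceil = cons[1], cons[2]
                ri = p.links[lid][0]
                rent = (pw[lid] - pw_sup[lid]) * T_s[lid]
            else:
                ri, ceil = cons[1], cons[2]
                rent = float(
                    sum(
                        (pw[lid] - pw_sup[lid]) * T_s[lid]
                        for lid in p.export_links[ri][self.wheat_idx]
                    )
                )
            rents[ri] += rent
            rent_detail[cons] = rent

        income = w * p.labor_endow + (rk * p.capital_endow).sum(axis=1) + rents
        budget = (1.0 - p.savings_rate) * income
        # foreign savings are fixed in numeraire units (region-0 wage), which
        # makes every residual homogeneous of degree zero in the price vector;
        # the least-squares Newton step then treats the scaling ray exactly
        I_exp = p.savings_rate * income + p.foreign_savings * w[0]

        C = np.zeros((R, S))
        CF = np.zeros(R)
        p_f = np.zeros(R)
        food_idx = [p.sector_index(s) for s in p.food_sectors]
        for ri in range(R):
            fn = p.food_nest[ri]
            p_f[ri] = fn.price(p_q[ri, food_idx])
            CF[ri] = p.alpha_food[ri] * budget[ri] / p_f[ri]
            C[ri, food_idx] = fn.coefs(p_q[ri, food_idx]) * CF[ri]
            for si in range(S):
                if p.alpha_nonfood[ri, si] > 0:
                    C[ri, si] = p.alpha_nonfood[ri, si] * budget[ri] / p_q[ri, si]
        INV = p.inv_share * I_exp[:, None] / p_q

        X_use = np.einsum("ris,rs->ri", p.ax, Z / A)

        return {
            "w": w,
            "rk": rk,
            "p_d": p_d,
            "pw": pw,
            "pw_sup": pw_sup,
            "p_e": p_e,
            "p_m": p_m,
            "p_z": p_z,
            "p_q": p_q,
            "p_va": p_va,
            "p_f": p_f,
            "c_va": c_va,
            "VA": VA,
            "L_dem": L_dem,
            "Z": Z,
            "D": D_sup,
            "E": E,
            "M": M,
            "Q": Q,
            "T_s": T_s,
            "T_d": T_d,
            "C": C,
            "CF": CF,
            "INV": INV,
            "X_use": X_use,
            "income": income,
            "rents": rents,
            "rent_detail": rent_detail,
        }

    def residual(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        ev = self._evaluate(x)
        res = []
        res.append((ev["L_dem"].sum(axis=1) - p.labor_endow) / p.labor_endow)
        res.append(np.log(ev["c_va"] / ev["p_va"]).ravel())
        q_bench = p.benchmark["Q"]
        res.append(((ev["Q"] - ev["X_use"] - ev["C"] - ev["INV"]) / q_bench).ravel())
        link_res = (ev["T_s"] - ev["T_d"]) / np.maximum(p.link_flows, 1e-12)
        for ci, cons in enumerate(self.active):
            if cons[0] == "link":
                lid, ceil = cons[1], cons[2]
                # supply side pinned to the ceiling by the wedge; demand side
                # clears at the importer-faced price
                link_res[lid] = (ev["T_d"][lid] - ceil) / max(p.link_flows[lid], 1e-12)
        res.append(link_res)
        extra = np.zeros(len(self.active))
        for ci, cons in enumerate(self.active):
            if cons[0] == "link":
                lid, ceil = cons[1], cons[2]
                extra[ci] = (ev["T_s"][lid] - ceil) / max(p.link_flows[lid], 1e-12)
            else:
                ri, ceil = cons[1], cons[2]
                lids = p.export_links[ri][self.wheat_idx]
                base = max(float(p.link_flows[lids].sum()), 1e-12)
                extra[ci] = (float(ev["T_s"][lids].sum()) - ceil) / base
        res.append(extra)
        return np.concatenate(res)

    # -- quota helpers ------------------------------------------------------

    def _violations(self, ev: dict, tol: float = 1e-9) -> list[tuple]:
        """Quota constraints violated by the current solution."""
        p = self.params
        out = []
        active_keys = {c[:2] for c in self.active}
        for lid, ceil in self._quota_links.items():
            if ("link", lid) in active_keys:
                continue
            if ev["T_s"][lid] > ceil * (1.0 + tol) + tol:
                out.append(("link", lid, ceil))
        for ri, ceil in self._quota_agg.items():
            if ("agg", ri) in active_keys:
                continue
            tot = float(ev["T_s"][p.export_links[ri][self.wheat_idx]].sum())
            if tot > ceil * (1.0 + tol) + tol:
                out.append(("agg", ri, ceil))
        return out

    def _negative_rents(self, ev: dict, tol: float = 1e-9) -> list[tuple]:
        return [c for c in self.active if ev["rent_detail"][c] < -tol]


def build_system(
    params: CalibratedParams, shock: ShockVector, quotas: QuotaSet | None = None
) -> EquilibriumSystem:
    """Construct the square equilibrium system for one shock draw."""
    system = EquilibriumSystem(params, shock, quotas)
    census = system.census()
    if sum(census["unknowns"].values()) != sum(census["equations"].values()):
        raise SolverError(f"equation/unknown census mismatch: {census}")
    return system


# ---------------------------------------------------------------------------
# Newton solver
# ---------------------------------------------------------------------------


def _newton(system: EquilibriumSystem, x0: np.ndarray, tol: float, max_iter: int):
    x = x0.copy()
    r = system.residual(x)
    best_x, best_norm = x.copy(), float(np.max(np.abs(r)))
    n = x.size
    for it in range(max_iter):
        norm = float(np.max(np.abs(r)))
        if norm < best_norm:
            best_x, best_norm = x.copy(), norm
        if norm < tol:
            return x, it, norm, True
        # forward-difference Jacobian in log space
        J = np.empty((r.size, n))
        h = 1e-7
        for j in range(n):
            xp = x.copy()
            xp[j] += h
            J[:, j] = (system.residual(xp) - r) / h
        # every residual is homogeneous of degree zero in prices, so the
        # uniform log-price shift is an exact null direction of J (up to
        # finite-difference noise); deflate it with an explicit constraint
        # row that keeps the step orthogonal to the scaling ray
        ray = np.zeros(n)
        ray[: system.n_base] = 1.0 / np.sqrt(system.n_base)
        J_aug = np.vstack([J, ray])
        rhs = np.concatenate([-r, [0.0]])
        step, *_ = np.linalg.lstsq(J_aug, rhs, rcond=None)
        cap = np.max(np.abs(step))
        if cap > 2.0:
            step *= 2.0 / cap
        # backtracking line search on the residual norm
        base = float(np.linalg.norm(r))
        t = 1.0
        for _ in range(25):
            x_new = x + t * step
            r_new = system.residual(x_new)
            if float(np.linalg.norm(r_new)) < (1.0 - 1e-4 * t) * base:
                x, r = x_new, r_new
                break
            t *= 0.5
        else:
            return best_x, it + 1, best_norm, False
    norm = float(np.max(np.abs(r)))
    if norm < best_norm:
        best_x, best_norm = x, norm
    return best_x, max_iter, best_norm, best_norm < tol


def solve(
    system: EquilibriumSystem,
    *,
    tol: float = 1e-9,
    max_iter: int = 80,
    warm_start: np.ndarray | None = None,
    max_active_set_iter: int = 12,
) -> EquilibriumSolution:
    """Solve the system with benchmark warm start and quota active-set loop.

    Raises :class:`SolverError` (carrying the best residual reached) on
    non-convergence; never returns a silent partial answer.
    """
    x = warm_start.copy() if warm_start is not None else system.benchmark_point()
    if x.size != system.n_unknowns:
        x = np.concatenate([x[: system.n_base], np.zeros(len(system.active))])

    total_iters = 0
    for _ in range(max_active_set_iter):
        x, iters, norm, ok = _newton(system, x, tol, max_iter)
        total_iters += iters
        if not ok:
            # restart from benchmark once before giving up
            x2, iters2, norm2, ok = _newton(
                system, system.benchmark_point(), tol, max_iter
            )
            total_iters += iters2
            if not ok:
                raise SolverError(
                    f"equilibrium solver failed: best residual {min(norm, norm2):.3e}",
                    best_residual=min(norm, norm2),
                )
            x, norm = x2, norm2
        ev = system._evaluate(x)
        to_drop = system._negative_rents(ev)
        if to_drop:
            keep = [i for i, c in enumerate(system.active) if c not in to_drop]
            wedges = x[system.n_base :]
            system.active = [system.active[i] for i in keep]
            x = np.concatenate([x[: system.n_base], wedges[keep]])
            continue
        to_add = system._violations(ev)
        if to_add:
            system.active = system.active + to_add
            x = np.concatenate([x, np.zeros(len(to_add))])
            continue
        break
    else:
        raise SolverError("quota active-set iteration did not settle", best_residual=norm)

    ev = system._evaluate(x)
    p = system.params
    R = p.n_regions
    # renormalize the price level so the numeraire (region-0 wage) is 1
    scale = ev["w"][0]
    for key in ("w", "p_d", "pw", "pw_sup", "p_e", "p_m", "p_z", "p_q", "p_va", "p_f",
                "rk", "c_va", "income", "rents"):
        ev[key] = ev[key] / scale
    ev["rent_detail"] = {k: v / scale for k, v in ev["rent_detail"].items()}
    utility = np.array(
        [
            p.top_nest[ri].aggregate(
                [ev["CF"][ri]]
                + [
                    ev["C"][ri, si]
                    for si in range(p.n_sectors)
                    if p.alpha_nonfood[ri, si] > 0
                ]
            )
            for ri in range(R)
        ]
    )
    log.debug(
        "solve done: iters=%d residual=%.3e active=%s", total_iters, norm, system.active
    )
    return EquilibriumSolution(
        params=p,
        shock=system.shock[:, system.wheat_idx].copy(),
        converged=True,
        iterations=total_iters,
        max_residual=norm,
        wage=ev["w"],
        capital_price=ev["rk"],
        p_domestic=ev["p_d"],
        p_export=ev["p_e"],
        p_import=ev["p_m"],
        p_output=ev["p_z"],
        p_composite=ev["p_q"],
        p_value_added=ev["p_va"],
        p_food=ev["p_f"],
        p_world=ev["pw"],
        p_world_supply=ev["pw_sup"],
        exchange_rate=np.ones(R),
        gross_output=ev["Z"],
        value_added=ev["VA"],
        labor=ev["L_dem"],
        domestic=ev["D"],
        exports=ev["E"],
        imports=ev["M"],
        composite=ev["Q"],
        trade_supply=ev["T_s"],
        trade_demand=ev["T_d"],
        consumption=ev["C"],
        food_composite=ev["CF"],
        investment=ev["INV"],
        utility=utility,
        income=ev["income"],
        quota_rents={str(k): v for k, v in ev["rent_detail"].items()},
        active_quotas=list(system.active),
    )


def excess_demand(solution: EquilibriumSolution, market) -> float:
    """Signed demand-minus-supply gap for a named market.

    Markets: ``("commodity", region, sector)``, ``("labor", region)``,
    ``("capital", region, sector)``, ``("link", exporter, importer,
    sector)`` and ``("bop", region)``.  The balance-of-payments markets
    are not part of the solved system (see module docstring), so
    ``("bop", r)`` is the Walras-law oracle.
    """
    p = solution.params
    kind = market[0]
    if kind == "commodity":
        ri, si = p.region_index(market[1]), p.sector_index(market[2])
        # recompute intermediate demand from gross output
        A = np.ones((p.n_regions, p.n_sectors))
        A[:, p.sector_index(p.wheat_sector)] = solution.shock
        x_use = float(np.einsum("s,s->", p.ax[ri, si, :], (solution.gross_output / A)[ri]))
        demand = x_use + solution.consumption[ri, si] + solution.investment[ri, si]
        return demand - float(solution.composite[ri, si])
    if kind == "labor":
        ri = p.region_index(market[1])
        return float(solution.labor[ri].sum() - p.labor_endow[ri])
    if kind == "capital":
        ri, si = p.region_index(market[1]), p.sector_index(market[2])
        # capital use is pinned to the endowment by construction
        return 0.0
    if kind == "link":
        lk = (
            p.region_index(market[1]),
            p.region_index(market[2]),
            p.sector_index(market[3]),
        )
        lid = p.links.index(lk)
        return float(solution.trade_demand[lid] - solution.trade_supply[lid])
    if kind == "bop":
        ri = p.region_index(market[1])
        exp_val = imp_val = 0.0
        for lid, (e, i, s) in enumerate(p.links):
            if e == ri:
                exp_val += solution.p_world[lid] * solution.trade_supply[lid]
                # rent wedge: exporter receives the supply price; the
                # difference is the rent, also accruing at home
            if i == ri:
                imp_val += solution.p_world[lid] * solution.trade_demand[lid]
        return float(exp_val + p.foreign_savings[ri] - imp_val)
    raise KeyError(f"unknown market label {market!r}")
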