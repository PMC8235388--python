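"""Benchmark calibration: from a balanced SAM to all model parameters.

Under the unit-price convention every money flow in the SAM doubles as a
benchmark quantity, so share and scale parameters of every nest follow
from first-order conditions evaluated at the benchmark.  The resulting
:class:`CalibratedParams` satisfies benchmark replication: the
equilibrium system evaluated at unit prices reproduces the SAM flows
with residuals at machine precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._nests import Nest, cet
from .errors import CalibrationError
from .synthetic_world import SAMTable, WorldSpec

__all__ = ["Elasticities", "CalibratedParams", "QuotaSet", "calibrate", "quota_baseline"]


@dataclass(frozen=True)
class Elasticities:
    """Per-sector substitution/transformation elasticities.

    Cobb-Douglas limiting forms are triggered automatically inside the
    nest primitive when an elasticity is within 1e-6 of one.
    """

    value_added: dict[str, float]
    armington: dict[str, float]
    cet: dict[str, float]
    bilateral_armington: dict[str, float]
    bilateral_cet: dict[str, float]
    food_nest: float = 0.1

    @classmethod
    def from_spec(cls, spec: WorldSpec) -> "Elasticities":
        return cls(
            value_added=spec.va_elasticities(),
            armington=spec.armington_elasticities(),
            cet=spec.cet_elasticities(),
            bilateral_armington=spec.bilateral_armington(),
            bilateral_cet=spec.bilateral_cet(),
            food_nest=spec.food_nest_elasticity,
        )

    def validate(self, sectors) -> None:
        for name, table in (
            ("value_added", self.value_added),
            ("armington", self.armington),
            ("cet", self.cet),
            ("bilateral_armington", self.bilateral_armington),
            ("bilateral_cet", self.bilateral_cet),
        ):
            for s in sectors:
                if s not in table:
                    raise CalibrationError(f"missing {name} elasticity for sector {s!r}")
                if table[s] <= 0:
                    raise CalibrationError(f"{name} elasticity for {s!r} must be > 0")
        if self.food_nest <= 0:
            raise CalibrationError("food-nest elasticity must be > 0")


@dataclass
class QuotaSet:
    """Export ceilings on wheat flows for designated exporters."""

    sector: str
    fraction: float
    mode: str  # "bilateral" | "aggregate"
    # bilateral: (exporter, importer) -> ceiling quantity
    bilateral_ceilings: dict[tuple[str, str], float] = field(default_factory=dict)
    # aggregate: exporter -> ceiling on total exports
    aggregate_ceilings: dict[str, float] = field(default_factory=dict)

    @property
    def exporters(self) -> list[str]:
        if self.mode == "bilateral":
            return sorted({e for e, _ in self.bilateral_ceilings})
        return sorted(self.aggregate_ceilings)


@dataclass
class CalibratedParams:
    """Everything the equilibrium system needs, plus the benchmark record.

    Arrays are indexed by integer region/sector positions; ``regions`` and
    ``sectors`` give the label order.  Nest lists hold ``None`` where a
    margin is inactive (no exports / no imports at the benchmark).
    """

    regions: list[str]
    sectors: list[str]
    wheat_sector: str
    food_sectors: list[str]
    mobile_factor: str
    specific_factor: str
    elasticities: Elasticities

    ax: np.ndarray  # (R, S_in, S_out) intermediate coefficients per unit output
    ay: np.ndarray  # (R, S) value-added per unit gross output
    va_nests: list  # [r][s] Nest over (mobile, specific)
    labor_endow: np.ndarray  # (R,)
    capital_endow: np.ndarray  # (R, S)

    cet_top: list  # [r][s] Nest over (domestic, export) or None
    armington: list  # [r][s] Nest over (domestic, import) or None
    links: list  # [(exp_r, imp_r, s)] integer triples, benchmark flow > 0
    link_flows: np.ndarray  # (L,)
    export_links: list  # [r][s] -> list of link ids
    export_nests: list  # [r][s] Nest over outgoing links or None
    import_links: list
    import_nests: list

    alpha_food: np.ndarray  # (R,) Cobb-Douglas budget share of the food composite
    alpha_nonfood: np.ndarray  # (R, S), zero on food sectors
    food_nest: list  # [r] Nest over food-sector consumption
    top_nest: list  # [r] Cobb-Douglas Nest over (food composite, nonfood goods)
    savings_rate: np.ndarray  # (R,)
    inv_share: np.ndarray  # (R, S) investment expenditure shares
    foreign_savings: np.ndarray  # (R,) world-currency, sums to ~0

    benchmark: dict = field(default_factory=dict)

    # -- helpers ------------------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_sectors(self) -> int:
        return len(self.sectors)

    def region_index(self, name: str) -> int:
        return self.regions.index(name)

    def sector_index(self, name: str) -> int:
        return self.sectors.index(name)

    def link_labels(self) -> list[tuple[str, str, str]]:
        return [
            (self.regions[e], self.regions[i], self.sectors[s]) for (e, i, s) in self.links
        ]

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        def nest_dict(n):
            if n is None:
                return None
            return {
                "sigma": n.sigma,
                "delta": n.delta.tolist(),
                "scale": n.scale,
                "benchmark": n.benchmark.tolist(),
            }

        payload = {
            "regions": self.regions,
            "sectors": self.sectors,
            "wheat_sector": self.wheat_sector,
            "food_sectors": self.food_sectors,
            "mobile_factor": self.mobile_factor,
            "specific_factor": self.specific_factor,
            "elasticities": {
                "value_added": self.elasticities.value_added,
                "armington": self.elasticities.armington,
                "cet": self.elasticities.cet,
                "bilateral_armington": self.elasticities.bilateral_armington,
                "bilateral_cet": self.elasticities.bilateral_cet,
                "food_nest": self.elasticities.food_nest,
            },
            "ax": self.ax.tolist(),
            "ay": self.ay.tolist(),
            "va_nests": [[nest_dict(n) for n in row] for row in self.va_nests],
            "labor_endow": self.labor_endow.tolist(),
            "capital_endow": self.capital_endow.tolist(),
            "cet_top": [[nest_dict(n) for n in row] for row in self.cet_top],
            "armington_nests": [[nest_dict(n) for n in row] for row in self.armington],
            "links": [list(l) for l in self.links],
            "link_flows": self.link_flows.tolist(),
            "export_links": self.export_links,
            "export_nests": [[nest_dict(n) for n in row] for row in self.export_nests],
            "import_links": self.import_links,
            "import_nests": [[nest_dict(n) for n in row] for row in self.import_nests],
            "alpha_food": self.alpha_food.tolist(),
            "alpha_nonfood": self.alpha_nonfood.tolist(),
            "food_nest_params": [nest_dict(n) for n in self.food_nest],
            "top_nest": [nest_dict(n) for n in self.top_nest],
            "savings_rate": self.savings_rate.tolist(),
            "inv_share": self.inv_share.tolist(),
            "foreign_savings": self.foreign_savings.tolist(),
            "benchmark": {k: np.asarray(v).tolist() for k, v in self.benchmark.items()},
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CalibratedParams":
        d = json.loads(text)

        def nest(nd):
            if nd is None:
                return None
            return Nest(
                sigma=nd["sigma"],
                delta=np.array(nd["delta"]),
                scale=nd["scale"],
                benchmark=np.array(nd["benchmark"]),
            )

        el = Elasticities(**d["elasticities"])
        return cls(
            regions=d["regions"],
            sectors=d["sectors"],
            wheat_sector=d["wheat_sector"],
            food_sectors=d["food_sectors"],
            mobile_factor=d["mobile_factor"],
            specific_factor=d["specific_factor"],
            elasticities=el,
            ax=np.array(d["ax"]),
            ay=np.array(d["ay"]),
            va_nests=[[nest(n) for n in row] for row in d["va_nests"]],
            labor_endow=np.array(d["labor_endow"]),
            capital_endow=np.array(d["capital_endow"]),
            cet_top=[[nest(n) for n in row] for row in d["cet_top"]],
            armington=[[nest(n) for n in row] for row in d["armington_nests"]],
            links=[tuple(l) for l in d["links"]],
            link_flows=np.array(d["link_flows"]),
            export_links=d["export_links"],
            export_nests=[[nest(n) for n in row] for row in d["export_nests"]],
            import_links=d["import_links"],
            import_nests=[[nest(n) for n in row] for row in d["import_nests"]],
            alpha_food=np.array(d["alpha_food"]),
            alpha_nonfood=np.array(d["alpha_nonfood"]),
            food_nest=[nest(n) for n in d["food_nest_params"]],
            top_nest=[nest(n) for n in d["top_nest"]],
            savings_rate=np.array(d["savings_rate"]),
            inv_share=np.array(d["inv_share"]),
            foreign_savings=np.array(d["foreign_savings"]),
            benchmark={k: np.array(v) for k, v in d["benchmark"].items()},
        )


def calibrate(sam: SAMTable, elasticities: Elasticities) -> CalibratedParams:
    """Derive all functional-form parameters from a balanced benchmark SAM."""
    meta = sam.meta
    regions: list[str] = list(meta["regions"])
    sectors: list[str] = list(meta["sectors"])
    mobile = meta["mobile_factor"]
    specific = next(f for f in meta["factors"] if f != mobile)
    elasticities.validate(sectors)
    R, S = len(regions), len(sectors)
    m = sam.table

    def get(row, col) -> float:
        try:
            return float(m.loc[row, col])
        except KeyError:
            return 0.0

    D = np.zeros((R, S))
    T = np.zeros((R, R, S))
    inter = np.zeros((R, S, S))  # (r, s_in, s_out)
    labor_pay = np.zeros((R, S))
    capital_pay = np.zeros((R, S))
    C = np.zeros((R, S))
    INV = np.zeros((R, S))
    Shh = np.zeros(R)
    Sf = np.zeros(R)

    from .synthetic_world import GLOBAL_REGION

    for ri, r in enumerate(regions):
        for si, s in enumerate(sectors):
            D[ri, si] = get((r, "activity", s), (r, "commodity", s))
            for sj, s2 in enumerate(sectors):
                inter[ri, si, sj] = get((r, "commodity", s), (r, "activity", s2))
            labor_pay[ri, si] = get((r, "factor", mobile), (r, "activity", s))
            capital_pay[ri, si] = get((r, "factor", specific), (r, "activity", s))
            C[ri, si] = get((r, "commodity", s), (r, "household", "household"))
            INV[ri, si] = get((r, "commodity", s), (r, "savings", "savings"))
        Shh[ri] = get((r, "savings", "savings"), (r, "household", "household"))
        Sf[ri] = get((r, "savings", "savings"), (GLOBAL_REGION, "world", "world")) - get(
            (GLOBAL_REGION, "world", "world"), (r, "savings", "savings")
        )
        for rj, r2 in enumerate(regions):
            if r2 == r:
                continue
            for si, s in enumerate(sectors):
                T[ri, rj, si] = get((r, "activity", s), (r, "trade", r2))

    E = T.sum(axis=1)
    M = T.sum(axis=0)
    Z = D + E
    Q = D + M
    va_value = labor_pay + capital_pay

    for ri, r in enumerate(regions):
        for si, s in enumerate(sectors):
            inputs = inter[ri, :, si].sum() + va_value[ri, si]
            if Z[ri, si] <= 0:
                if inputs > 0:
                    raise CalibrationError(
                        f"account ({r!r}, {s!r}): zero gross output with positive"
                        f" input flows {inputs:.4g}"
                    )
                raise CalibrationError(f"account ({r!r}, {s!r}): sector has zero gross output")
    sam.validate()

    ax = inter / Z[:, None, :]
    ay = va_value / Z

    links: list[tuple[int, int, int]] = []
    link_flows: list[float] = []
    for ri in range(R):
        for rj in range(R):
            for si in range(S):
                if T[ri, rj, si] > 0:
                    links.append((ri, rj, si))
                    link_flows.append(T[ri, rj, si])
    link_ids = {lk: i for i, lk in enumerate(links)}

    va_nests, cet_top, armington = [], [], []
    export_links, export_nests, import_links, import_nests = [], [], [], []
    for ri in range(R):
        va_row, cet_row, arm_row = [], [], []
        el_row, en_row, il_row, in_row = [], [], [], []
        for si, s in enumerate(sectors):
            va_row.append(
                Nest.calibrate(
                    [labor_pay[ri, si], capital_pay[ri, si]], elasticities.value_added[s]
                )
            )
            out_ids = [link_ids[(ri, rj, si)] for rj in range(R) if (ri, rj, si) in link_ids]
            in_ids = [link_ids[(rj, ri, si)] for rj in range(R) if (rj, ri, si) in link_ids]
            el_row.append(out_ids)
            il_row.append(in_ids)
            if E[ri, si] > 0:
                cet_row.append(cet([D[ri, si], E[ri, si]], elasticities.cet[s]))
                en_row.append(cet([link_flows[i] for i in out_ids], elasticities.bilateral_cet[s]))
            else:
                cet_row.append(None)
                en_row.append(None)
            if M[ri, si] > 0:
                arm_row.append(
                    Nest.calibrate([D[ri, si], M[ri, si]], elasticities.armington[s])
                )
                in_row.append(
                    Nest.calibrate(
                        [link_flows[i] for i in in_ids], elasticities.bilateral_armington[s]
                    )
                )
            else:
                arm_row.append(None)
                in_row.append(None)
        va_nests.append(va_row)
        cet_top.append(cet_row)
        armington.append(arm_row)
        export_links.append(el_row)
        export_nests.append(en_row)
        import_links.append(il_row)
        import_nests.append(in_row)

    food_idx = [sectors.index(s) for s in meta["food_sectors"]]
    nonfood_idx = [i for i in range(S) if i not in food_idx]
    alpha_food = np.zeros(R)
    alpha_nonfood = np.zeros((R, S))
    food_nest, top_nest = [], []
    for ri in range(R):
        if (C[ri] <= 0).any():
            bad = sectors[int(np.argmin(C[ri]))]
            raise CalibrationError(
                f"region {regions[ri]!r}: nonpositive household consumption of {bad!r}"
            )
        budget = C[ri].sum()
        cf = C[ri, food_idx].sum()
        alpha_food[ri] = cf / budget
        for si in nonfood_idx:
            alpha_nonfood[ri, si] = C[ri, si] / budget
        food_nest.append(Nest.calibrate(C[ri, food_idx], elasticities.food_nest))
        top_nest.append(Nest.calibrate([cf] + [C[ri, si] for si in nonfood_idx], 1.0))

    income = va_value.sum(axis=(1,))
    Y = labor_pay.sum(axis=1) + capital_pay.sum(axis=1)
    if np.any(Shh >= Y) or np.any(Shh < 0):
        raise CalibrationError("household savings must lie in [0, income)")
    savings_rate = Shh / Y
    I_exp = INV.sum(axis=1)
    expected = Shh + Sf
    if np.any(np.abs(I_exp - expected) > 1e-6 * np.maximum(1.0, np.abs(I_exp))):
        raise CalibrationError("savings-investment balance violated in the benchmark SAM")
    inv_share = INV / I_exp[:, None]

    benchmark = {
        "Z": Z,
        "VA": va_value,
        "D": D,
        "E": E,
        "M": M,
        "Q": Q,
        "C": C,
        "INV": INV,
        "T": np.array(link_flows),
        "income": income,
        "labor_endow": labor_pay.sum(axis=1),
        "capital_endow": capital_pay,
        "food_composite": np.array([C[ri, food_idx].sum() for ri in range(R)]),
    }

    return CalibratedParams(
        regions=regions,
        sectors=sectors,
        wheat_sector=meta["wheat_sector"],
        food_sectors=list(meta["food_sectors"]),
        mobile_factor=mobile,
        specific_factor=specific,
        elasticities=elasticities,
        ax=ax,
        ay=ay,
        va_nests=va_nests,
        labor_endow=labor_pay.sum(axis=1),
        capital_endow=capital_pay,
        cet_top=cet_top,
        armington=armington,
        links=links,
        link_flows=np.array(link_flows),
        export_links=export_links,
        export_nests=export_nests,
        import_links=import_links,
        import_nests=import_nests,
        alpha_food=alpha_food,
        alpha_nonfood=alpha_nonfood,
        food_nest=food_nest,
        top_nest=top_nest,
        savings_rate=savings_rate,
        inv_share=inv_share,
        foreign_savings=Sf,
        benchmark=benchmark,
    )


def quota_baseline(
    params: CalibratedParams,
    exporters,
    fraction: float,
    *,
    mode: str = "bilateral",
) -> QuotaSet:
    """Size wheat export ceilings as a fraction of baseline export quantities.

    ``mode="bilateral"`` (default) caps each baseline bilateral flow;
    ``mode="aggregate"`` caps each exporter's total wheat exports.
    Exporters with no baseline wheat exports get a zero ceiling and a
    warning.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("quota fraction must lie in (0, 1]")
    if mode not in ("bilateral", "aggregate"):
        raise ValueError(f"unknown quota mode {mode!r}")
    unknown = set(exporters) - set(params.regions)
    if unknown:
        raise ValueError(f"unknown exporter regions: {sorted(unknown)}")
    wheat = params.sector_index(params.wheat_sector)
    qs = QuotaSet(sector=params.wheat_sector, fraction=fraction, mode=mode)
    for ex in exporters:
        ei = params.region_index(ex)
        out_ids = params.export_links[ei][wheat]
        total = float(sum(params.link_flows[i] for i in out_ids))
        if total <= 0:
            warnings.warn(f"exporter {ex!r} has zero baseline wheat exports; ceiling 0")
            if mode == "aggregate":
                qs.aggregate_ceilings[ex] = 0.0
            continue
        if mode == "aggregate":
            qs.aggregate_ceilings[ex] = fraction * total
        else:
            for i in out_ids:
                _, ij, _ = params.links[i]
                qs.bilateral_ceilings[(ex, params.regions[ij])] = fraction * float(
                    params.link_flows[i]
                )
    return qs
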