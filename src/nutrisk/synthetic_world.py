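"""Synthetic world generator.

Produces every input the downstream pipeline needs with known ground
truth: a balanced multi-region social accounting matrix (SAM) assembled
from a constructed benchmark equilibrium at unit prices, yearly yield
series with a known ARMA data-generating process, and nutrition tables
(wheat nutrient profile, population pyramid, recommended intakes, wheat
food supply).

The SAM is balanced *by construction*: quantities are drawn first, the
accounting identities (zero profit, market clearing, budget balance,
savings-investment balance, balance of payments) are imposed on the
draws, and the money flows are read off the resulting benchmark at unit
prices.  A single integer seed makes every generator deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InfeasibleWorldError

__all__ = [
    "WorldSpec",
    "NutritionSpec",
    "SAMTable",
    "YieldSeries",
    "NutritionTables",
    "generate_sam",
    "generate_yield_series",
    "generate_nutrition_tables",
]

NUTRIENTS = ("protein", "energy", "iron", "zinc", "folate", "magnesium")

#: Wheat nutrient content per kg of edible supply (protein g, energy kcal,
#: iron mg, zinc mg, folate ug, magnesium mg).  Order matches NUTRIENTS.
DEFAULT_WHEAT_CONTENT = {
    "protein": 123.0,
    "energy": 3320.0,
    "iron": 35.0,
    "zinc": 26.0,
    "folate": 410.0,
    "magnesium": 1260.0,
}

GLOBAL_REGION = "__world__"


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NutritionSpec:
    """Configuration of the synthetic nutrition tables.

    ``wheat_contribution`` optionally pins, per region, the contribution
    share of wheat for one anchor nutrient (supply is back-solved so the
    share holds exactly); remaining nutrients' shares then follow from the
    wheat nutrient profile.
    """

    age_bands: tuple[str, ...] = ("0-9", "10-19", "20-39", "40-59", "60+")
    sexes: tuple[str, ...] = ("F", "M")
    base_population: float = 1_000_000.0
    birth_rate: float = 0.015  # births per person per year
    # (nutrient, target share) per region; default anchor via wheat_share
    wheat_contribution: dict[str, tuple[str, float]] = field(default_factory=dict)
    default_share: float = 0.4  # anchor protein share when not pinned
    anchor_nutrient: str = "protein"
    iron_tier: str = "10%"
    zinc_tier: str = "moderate"
    energy_tier: str = "moderate"
    biomass_adjustment: float = 1.0


@dataclass(frozen=True)
class WorldSpec:
    """A miniature multi-region world: taxonomy, elasticities, trade shares.

    ``heterogeneity = 0`` makes all regions structurally identical, which
    is what the symmetry tests rely on.
    """

    regions: tuple[str, ...] = ("alpha", "beta", "gamma")
    sectors: tuple[str, ...] = ("wheat", "otherfood", "foodproc", "nonfood")
    wheat_sector: str = "wheat"
    food_sectors: tuple[str, ...] = ("wheat", "otherfood", "foodproc")
    factors: tuple[str, ...] = ("labor", "capital")
    mobile_factor: str = "labor"
    va_elasticity: dict[str, float] | float = 1.2
    armington_elasticity: dict[str, float] | float = field(
        default_factory=lambda: {"wheat": 4.45, "*": 2.0}
    )
    cet_elasticity: dict[str, float] | float = 2.0
    # second-stage (bilateral) nests; default mirrors the top-level values
    bilateral_armington_elasticity: dict[str, float] | float | None = None
    bilateral_cet_elasticity: dict[str, float] | float | None = None
    food_nest_elasticity: float = 0.1
    export_share: dict[str, float] | float = field(
        default_factory=lambda: {"wheat": 0.25, "otherfood": 0.15, "foodproc": 0.1, "nonfood": 0.05}
    )
    export_share_overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    # multiplicative gross-output adjustments per (region, sector)
    output_overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    import_weights: dict[tuple[str, str], float] | None = None  # (importer, exporter)
    savings_rate: dict[str, float] | float = 0.15
    heterogeneity: float = 0.25
    scale: float = 100.0
    reference_year: int = 2014
    nutrition: NutritionSpec = field(default_factory=NutritionSpec)
    seed: int = 0

    # -- resolved lookups ---------------------------------------------------

    def _per_sector(self, value, name: str) -> dict[str, float]:
        if isinstance(value, dict):
            default = value.get("*")
            out = {}
            for s in self.sectors:
                v = value.get(s, default)
                if v is None:
                    raise InfeasibleWorldError(f"no {name} given for sector {s!r}")
                out[s] = float(v)
            return out
        return {s: float(value) for s in self.sectors}

    def va_elasticities(self) -> dict[str, float]:
        return self._per_sector(self.va_elasticity, "value-added elasticity")

    def armington_elasticities(self) -> dict[str, float]:
        return self._per_sector(self.armington_elasticity, "Armington elasticity")

    def cet_elasticities(self) -> dict[str, float]:
        return self._per_sector(self.cet_elasticity, "CET elasticity")

    def bilateral_armington(self) -> dict[str, float]:
        src = self.bilateral_armington_elasticity
        if src is None:
            return self.armington_elasticities()
        return self._per_sector(src, "bilateral Armington elasticity")

    def bilateral_cet(self) -> dict[str, float]:
        src = self.bilateral_cet_elasticity
        if src is None:
            return self.cet_elasticities()
        return self._per_sector(src, "bilateral CET elasticity")

    def export_shares(self) -> dict[str, float]:
        return self._per_sector(self.export_share, "export share")

    def savings_rates(self) -> dict[str, float]:
        if isinstance(self.savings_rate, dict):
            return {r: float(self.savings_rate[r]) for r in self.regions}
        return {r: float(self.savings_rate) for r in self.regions}

    def validate(self) -> None:
        if len(self.regions) < 2:
            raise InfeasibleWorldError("need at least two regions")
        if len(set(self.regions)) != len(self.regions):
            raise InfeasibleWorldError("duplicate region labels")
        if self.wheat_sector not in self.sectors:
            raise InfeasibleWorldError("wheat sector missing from sector list")
        if self.wheat_sector not in self.food_sectors:
            raise InfeasibleWorldError("wheat sector must belong to the food subset")
        if not set(self.food_sectors) <= set(self.sectors):
            raise InfeasibleWorldError("food subset must be a subset of sectors")
        if self.mobile_factor not in self.factors:
            raise InfeasibleWorldError("mobile factor missing from factor list")
        if len(self.factors) != 2:
            raise InfeasibleWorldError("miniature world uses exactly two factors")
        for name, table in (
            ("value-added", self.va_elasticities()),
            ("Armington", self.armington_elasticities()),
            ("CET", self.cet_elasticities()),
            ("bilateral Armington", self.bilateral_armington()),
            ("bilateral CET", self.bilateral_cet()),
        ):
            for s, v in table.items():
                if v <= 0:
                    raise InfeasibleWorldError(f"{name} elasticity for {s!r} must be > 0")
        if self.food_nest_elasticity <= 0:
            raise InfeasibleWorldError("food-nest elasticity must be > 0")
        for s, v in self.export_shares().items():
            if not 0.0 <= v < 1.0:
                raise InfeasibleWorldError(f"export share for {s!r} must lie in [0, 1)")
        for key, v in self.export_share_overrides.items():
            if not 0.0 <= v < 1.0:
                raise InfeasibleWorldError(f"export share override {key} must lie in [0, 1)")
        for key in set(self.export_share_overrides) | set(self.output_overrides):
            r, s = key
            if r not in self.regions or s not in self.sectors:
                raise InfeasibleWorldError(f"override {key} names an unknown region/sector")
        for r, v in self.savings_rates().items():
            if not 0.0 < v < 1.0:
                raise InfeasibleWorldError(f"savings rate for {r!r} must lie in (0, 1)")
        if self.heterogeneity < 0:
            raise InfeasibleWorldError("heterogeneity must be nonnegative")


# ---------------------------------------------------------------------------
# SAM container
# ---------------------------------------------------------------------------


def _account_tuple(region: str, kind: str, name: str) -> tuple[str, str, str]:
    return (region, kind, name)


@dataclass
class SAMTable:
    """Square money-flow matrix over region-indexed accounts.

    ``table`` rows receive, columns pay.  The index is a 3-level
    MultiIndex ``(region, kind, name)`` with kinds ``activity``,
    ``commodity``, ``factor``, ``household``, ``savings``, ``trade`` (name
    is the importing region) and a single global clearing account
    ``world``.  ``meta`` carries the sector/factor taxonomy so downstream
    calibration never has to guess which account is the wheat sector.
    """

    table: pd.DataFrame
    meta: dict
    year: int = 2014

    @property
    def accounts(self) -> pd.MultiIndex:
        return self.table.index

    def balance_error(self) -> float:
        """max |row sum - column sum| / max entry."""
        m = self.table.to_numpy()
        gap = np.abs(m.sum(axis=1) - m.sum(axis=0))
        denom = m.max() if m.size and m.max() > 0 else 1.0
        return float(gap.max() / denom)

    def validate(self, tol: float = 1e-8) -> None:
        m = self.table.to_numpy()
        if m.shape[0] != m.shape[1]:
            raise InfeasibleWorldError("SAM must be square")
        if (m < -1e-12).any():
            raise InfeasibleWorldError("SAM entries must be nonnegative")
        err = self.balance_error()
        if err > tol:
            raise InfeasibleWorldError(f"SAM unbalanced: relative error {err:.3e}")

    def flow(self, row: tuple[str, str, str], col: tuple[str, str, str]) -> float:
        return float(self.table.loc[row, col])

    # -- plain-text round trip ---------------------------------------------

    def to_long_csv(self, path_or_buf) -> None:
        """Write nonzero flows as (account_row, account_col, value)."""
        m = self.table
        rows = []
        for i, rix in enumerate(m.index):
            for j, cix in enumerate(m.columns):
                v = m.iat[i, j]
                if v != 0.0:
                    rows.append(("|".join(rix), "|".join(cix), v))
        pd.DataFrame(rows, columns=["account_row", "account_col", "value"]).to_csv(
            path_or_buf, index=False
        )

    @classmethod
    def from_long_csv(cls, path_or_buf, meta: dict, year: int = 2014) -> "SAMTable":
        long = pd.read_csv(path_or_buf)
        keys = sorted(
            set(long["account_row"]) | set(long["account_col"]),
            key=lambda k: tuple(k.split("|")),
        )
        idx = pd.MultiIndex.from_tuples(
            [tuple(k.split("|")) for k in keys], names=["region", "kind", "name"]
        )
        m = pd.DataFrame(0.0, index=idx, columns=idx)
        for _, rec in long.iterrows():
            m.loc[tuple(rec["account_row"].split("|")), tuple(rec["account_col"].split("|"))] = rec[
                "value"
            ]
        return cls(table=m, meta=meta, year=year)


# ---------------------------------------------------------------------------
# SAM generation
# ---------------------------------------------------------------------------


def _het(rng: np.random.Generator, spread: float, shape) -> np.ndarray:
    """Multiplicative regional heterogeneity factors; all ones at spread 0."""
    if spread == 0:
        return np.ones(shape)
    return np.exp(spread * rng.standard_normal(shape))


def generate_sam(spec: WorldSpec) -> SAMTable:
    """Assemble a balanced SAM from a constructed unit-price benchmark.

    All accounting identities hold exactly by construction; infeasible
    draws (negative domestic absorption, negative investment) raise
    :class:`InfeasibleWorldError` naming the offending account.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    R, S = len(spec.regions), len(spec.sectors)
    regions, sectors = list(spec.regions), list(spec.sectors)

    # sector-level structure shared across regions, modulated by heterogeneity
    sector_base = np.exp(0.3 * rng.standard_normal(S))
    int_share_base = rng.uniform(0.2, 0.4, size=S)  # intermediate cost share
    ax_pattern = rng.uniform(0.2, 1.0, size=(S, S))  # input mix, rows=input
    labor_share_base = rng.uniform(0.35, 0.65, size=S)

    Z = spec.scale * sector_base[None, :] * _het(rng, spec.heterogeneity, (R, S))
    for (r_name, s_name), factor in spec.output_overrides.items():
        if factor <= 0:
            raise InfeasibleWorldError(f"output override {(r_name, s_name)} must be positive")
        Z[regions.index(r_name), sectors.index(s_name)] *= factor

    int_share = np.clip(
        int_share_base[None, :] * _het(rng, spec.heterogeneity * 0.5, (R, S)), 0.05, 0.5
    )
    ax = np.empty((R, S, S))  # ax[r, s_in, s_out]
    for r in range(R):
        pat = ax_pattern * _het(rng, spec.heterogeneity * 0.5, (S, S))
        ax[r] = pat / pat.sum(axis=0, keepdims=True) * int_share[r][None, :]
    va_value = (1.0 - int_share) * Z
    labor_share = np.clip(
        labor_share_base[None, :] * _het(rng, spec.heterogeneity * 0.5, (R, S)), 0.1, 0.9
    )
    labor_pay = labor_share * va_value
    capital_pay = va_value - labor_pay

    # trade: export side first, imports follow from bilateral consistency
    xsh_base = np.array([spec.export_shares()[s] for s in sectors])
    xsh = np.clip(xsh_base[None, :] * _het(rng, spec.heterogeneity * 0.5, (R, S)), 0.0, 0.9)
    for (r_name, s_name), v in spec.export_share_overrides.items():
        xsh[regions.index(r_name), sectors.index(s_name)] = v
    E = xsh * Z
    D = Z - E

    T = np.zeros((R, R, S))  # exporter, importer, sector
    for r in range(R):
        for s in range(S):
            if E[r, s] <= 0:
                continue
            w = np.zeros(R)
            for rp in range(R):
                if rp == r:
                    continue
                if spec.import_weights is not None:
                    w[rp] = spec.import_weights.get((regions[rp], regions[r]), 0.0)
                else:
                    w[rp] = Z[rp, s]
            if w.sum() <= 0:
                raise InfeasibleWorldError(
                    f"no import destination for exports of {sectors[s]!r} from {regions[r]!r}"
                )
            T[r, :, s] = E[r, s] * w / w.sum()
    M = T.sum(axis=0)
    Q = D + M

    X_use = np.einsum("ris,rs->ri", ax, Z)  # composite input demand by input sector
    avail = Q - X_use
    for r in range(R):
        for s in range(S):
            if avail[r, s] <= 1e-9 * max(Q[r, s], 1.0):
                raise InfeasibleWorldError(
                    f"region {regions[r]!r}, sector {sectors[s]!r}: intermediate demand"
                    f" exhausts composite supply (available {avail[r, s]:.4g})"
                )

    sav_rate = np.array([spec.savings_rates()[r] for r in regions])
    Y = va_value.sum(axis=1)
    Shh = sav_rate * Y
    Sf = M.sum(axis=1) - E.sum(axis=1)  # foreign savings = trade deficit
    I_exp = Shh + Sf
    for r in range(R):
        if I_exp[r] <= 0:
            raise InfeasibleWorldError(
                f"region {regions[r]!r}: savings {Shh[r]:.4g} plus foreign savings"
                f" {Sf[r]:.4g} imply nonpositive investment; raise the savings rate"
            )
    C = avail * ((Y - Shh) / (avail.sum(axis=1)))[:, None]
    INV = avail * (I_exp / (avail.sum(axis=1)))[:, None]

    # ---- assemble accounts ------------------------------------------------
    acc: list[tuple[str, str, str]] = []
    for r in regions:
        acc += [(r, "activity", s) for s in sectors]
        acc += [(r, "commodity", s) for s in sectors]
        acc += [(r, "factor", f) for f in spec.factors]
        acc += [(r, "household", "household"), (r, "savings", "savings")]
    for r in range(R):
        for rp in range(R):
            if rp != r and T[r, rp].sum() > 0:
                acc.append((regions[r], "trade", regions[rp]))
    acc.append((GLOBAL_REGION, "world", "world"))
    idx = pd.MultiIndex.from_tuples(sorted(acc), names=["region", "kind", "name"])
    m = pd.DataFrame(0.0, index=idx, columns=idx)

    mobile = spec.mobile_factor
    specific = next(f for f in spec.factors if f != mobile)
    for r in range(R):
        rn = regions[r]
        for s in range(S):
            sn = sectors[s]
            m.loc[(rn, "activity", sn), (rn, "commodity", sn)] = D[r, s]
            for si in range(S):
                m.loc[(rn, "commodity", sectors[si]), (rn, "activity", sn)] = ax[r, si, s] * Z[r, s]
            m.loc[(rn, "factor", mobile), (rn, "activity", sn)] = labor_pay[r, s]
            m.loc[(rn, "factor", specific), (rn, "activity", sn)] = capital_pay[r, s]
            m.loc[(rn, "commodity", sn), (rn, "household", "household")] = C[r, s]
            m.loc[(rn, "commodity", sn), (rn, "savings", "savings")] = INV[r, s]
        for f in spec.factors:
            m.loc[(rn, "household", "household"), (rn, "factor", f)] = float(
                m.loc[(rn, "factor", f)].sum()
            )
        m.loc[(rn, "savings", "savings"), (rn, "household", "household")] = Shh[r]
        if Sf[r] > 0:
            m.loc[(rn, "savings", "savings"), (GLOBAL_REGION, "world", "world")] = Sf[r]
        elif Sf[r] < 0:
            m.loc[(GLOBAL_REGION, "world", "world"), (rn, "savings", "savings")] = -Sf[r]
        for rp in range(R):
            if rp == r:
                continue
            tot = T[r, rp].sum()
            if tot <= 0:
                continue
            trd = (regions[r], "trade", regions[rp])
            for s in range(S):
                if T[r, rp, s] > 0:
                    m.loc[trd, (regions[rp], "commodity", sectors[s])] = T[r, rp, s]
                    m.loc[(regions[r], "activity", sectors[s]), trd] = T[r, rp, s]

    meta = {
        "regions": regions,
        "sectors": sectors,
        "wheat_sector": spec.wheat_sector,
        "food_sectors": list(spec.food_sectors),
        "factors": list(spec.factors),
        "mobile_factor": mobile,
        "seed": spec.seed,
    }
    sam = SAMTable(table=m, meta=meta, year=spec.reference_year)
    sam.validate()
    return sam


# ---------------------------------------------------------------------------
# Yield series
# ---------------------------------------------------------------------------


@dataclass
class YieldSeries:
    """Annual productivity (production per harvested area) for one region."""

    region: str
    years: np.ndarray
    values: np.ndarray
    reference_year: int

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ValueError("years and values must have equal length")
        if np.any(self.values <= 0):
            raise ValueError("productivity values must be strictly positive")
        if self.reference_year not in self.years:
            raise ValueError(f"reference year {self.reference_year} missing from series")

    @property
    def reference_value(self) -> float:
        return float(self.values[np.where(self.years == self.reference_year)[0][0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": self.region, "year": self.years, "productivity": self.values}
        )


def _check_poly(coefs, label: str) -> None:
    """Reject AR/MA polynomials with roots on or inside the unit circle."""
    c = np.asarray(coefs, dtype=float)
    if c.size == 0:
        return
    # polynomial 1 - c1 L - ... (AR) or 1 + c1 L + ... (MA) -- caller passes
    # the lag-polynomial coefficients directly.
    roots = np.roots(c[::-1])
    # stationarity/invertibility: every root of the lag polynomial must lie
    # strictly outside the unit circle
    if np.any(np.abs(roots) <= 1.0 + 1e-10):
        raise ValueError(f"{label} polynomial has a root on/inside the unit circle")


def generate_yield_series(
    region: str,
    arma_params: tuple = ((), ()),
    innovation_sd: float = 0.05,
    n_years: int = 25,
    seed: int = 0,
    *,
    d: int = 0,
    base_level: float = 1.0,
    reference_year: int = 2014,
    center_at_reference: bool = False,
    floor: float = 0.05,
) -> YieldSeries:
    """Simulate a yield series with a known ARMA data-generating process.

    The standardised deviation process ``x_t`` follows an ARMA(p, q) with
    i.i.d. normal innovations of standard deviation ``innovation_sd``.
    With ``d = 0`` the series is ``base * (1 + x_t)`` (stationary level);
    with ``d = 1`` the deviations are integrated so the *first difference*
    of the standardised series is the ARMA process.  The last year is the
    reference year; ``center_at_reference`` forces the reference-year
    value to ``base_level`` exactly (a clean-DGP knob for recovery tests).
    """
    ar, ma = (tuple(arma_params[0]), tuple(arma_params[1]))
    if innovation_sd < 0:
        raise ValueError("innovation_sd must be nonnegative")
    if n_years < 3:
        raise ValueError("need at least three years")
    if d not in (0, 1):
        raise ValueError("d must be 0 or 1")
    _check_poly([1.0] + [-a for a in ar], "AR")
    _check_poly([1.0] + list(ma), "MA")

    rng = np.random.default_rng(seed)
    burn = 200
    eps = rng.standard_normal(n_years + burn) * innovation_sd
    x = signal.lfilter([1.0] + list(ma), [1.0] + [-a for a in ar], eps)[burn:]
    if d == 1:
        x = np.cumsum(x)
    z = 1.0 + x
    if center_at_reference:
        z = z - (z[-1] - 1.0)
    z = np.maximum(z, floor)
    years = np.arange(reference_year - n_years + 1, reference_year + 1)
    return YieldSeries(
        region=region, years=years, values=base_level * z, reference_year=reference_year
    )


# ---------------------------------------------------------------------------
# Nutrition tables
# ---------------------------------------------------------------------------

def toy_trade_world(seed: int = 0, *, heterogeneity: float = 0.15) -> WorldSpec:
    """Three-region world with a dominant wheat exporter.

    ``exporter`` produces most of the world's wheat and exports half of
    it; ``importer`` produces little wheat and covers most of its use
    through imports; ``third`` is roughly self-sufficient.  This is the
    configuration the directional mechanism tests (exporter shock ->
    importer price up, consumption down; quota -> worse importer tail)
    are run on.
    """
    return WorldSpec(
        regions=("exporter", "importer", "third"),
        heterogeneity=heterogeneity,
        export_share_overrides={
            ("exporter", "wheat"): 0.5,
            ("importer", "wheat"): 0.01,
            ("third", "wheat"): 0.05,
        },
        output_overrides={
            ("exporter", "wheat"): 3.0,
            ("importer", "wheat"): 0.25,
        },
        # the exporter runs a large trade surplus; it must save enough to
        # keep savings-driven investment positive
        savings_rate={"exporter": 0.45, "importer": 0.12, "third": 0.18},
        seed=seed,
    )


#: Daily recommended intakes per (age band, sex) stratum.  Magnitudes are
#: in the unit of the matching nutrient content entry (g, kcal, mg, ug).
_BASE_RNI = {
    "protein": {"0-9": 20.0, "10-19": 45.0, "20-39": 52.0, "40-59": 50.0, "60+": 47.0},
    "energy": {"0-9": 1400.0, "10-19": 2300.0, "20-39": 2400.0, "40-59": 2250.0, "60+": 1950.0},
    "folate": {"0-9": 220.0, "10-19": 390.0, "20-39": 400.0, "40-59": 400.0, "60+": 400.0},
    "magnesium": {"0-9": 110.0, "10-19": 235.0, "20-39": 240.0, "40-59": 235.0, "60+": 225.0},
}

#: Tiered intakes: absorption assumptions change the requirement.
_TIERED_RNI = {
    "iron": {
        "15%": {"0-9": 7.0, "10-19": 18.0, "20-39": 16.0, "40-59": 12.0, "60+": 9.0},
        "10%": {"0-9": 10.0, "10-19": 26.0, "20-39": 24.0, "40-59": 18.0, "60+": 14.0},
        "5%": {"0-9": 20.0, "10-19": 52.0, "20-39": 48.0, "40-59": 37.0, "60+": 27.0},
    },
    "zinc": {
        "high": {"0-9": 3.0, "10-19": 5.0, "20-39": 4.5, "40-59": 4.5, "60+": 4.0},
        "moderate": {"0-9": 5.0, "10-19": 9.0, "20-39": 8.0, "40-59": 8.0, "60+": 7.0},
        "low": {"0-9": 10.0, "10-19": 17.0, "20-39": 15.0, "40-59": 15.0, "60+": 13.0},
    },
    "energy_activity": {"light": 0.9, "moderate": 1.0, "heavy": 1.15},
}

#: Daily pregnancy increments per birth (proxy for one pregnant woman-year).
_PREGNANCY_INCREMENT = {
    "protein": 6.0,
    "energy": 280.0,
    "iron": 9.0,
    "zinc": 2.5,
    "folate": 200.0,
    "magnesium": 30.0,
}

#: Female/male intake ratio applied to the sex-neutral base values.
_SEX_FACTOR = {"F": 0.92, "M": 1.08}


@dataclass
class NutritionTables:
    """Wheat nutrient profile, population structure and requirements.

    ``rni`` rows are strata ``"age|sex"``, columns nutrients; iron, zinc
    and energy entries are already resolved at the configured
    bioavailability/activity tier.  ``pregnancy_increment`` is the daily
    per-birth extra intake.  ``wheat_supply_kg`` is the annual wheat food
    supply per region.
    """

    nutrient_content: dict[str, float]
    pyramid: dict[str, pd.Series]  # region -> counts indexed by "age|sex"
    births: dict[str, float]
    rni: pd.DataFrame
    pregnancy_increment: dict[str, float]
    wheat_supply_kg: dict[str, float]
    tiers: dict[str, str]
    biomass_adjustment: float = 1.0

    def validate(self) -> None:
        for n in NUTRIENTS:
            if n not in self.nutrient_content:
                raise ValueError(f"missing nutrient content for {n!r}")
            if n not in self.rni.columns:
                raise ValueError(f"missing recommended intake column for {n!r}")
        if (self.rni.to_numpy() < 0).any():
            raise ValueError("recommended intakes must be nonnegative")
        for r, counts in self.pyramid.items():
            if (counts < 0).any():
                raise ValueError(f"negative population count in region {r!r}")
            missing = set(counts.index) - set(self.rni.index)
            if missing:
                raise ValueError(f"strata without intake values: {sorted(missing)}")


def build_rni_table(
    spec: NutritionSpec,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Resolve the tiered recommended-intake table for a nutrition spec."""
    strata = [f"{a}|{x}" for a in spec.age_bands for x in spec.sexes]
    cols = {}
    for n in NUTRIENTS:
        vals = []
        for st in strata:
            age, sex = st.split("|")
            if n == "iron":
                base = _TIERED_RNI["iron"][spec.iron_tier][age]
            elif n == "zinc":
                base = _TIERED_RNI["zinc"][spec.zinc_tier][age]
            else:
                base = _BASE_RNI[n][age]
                if n == "energy":
                    base *= _TIERED_RNI["energy_activity"][spec.energy_tier]
            vals.append(base * _SEX_FACTOR[sex])
        cols[n] = vals
    rni = pd.DataFrame(cols, index=pd.Index(strata, name="stratum"))
    return rni, dict(_PREGNANCY_INCREMENT)


def generate_nutrition_tables(spec: WorldSpec) -> NutritionTables:
    """Generate internally consistent nutrition tables for every region.

    The wheat food supply of each region is back-solved so that the
    contribution share of the anchor nutrient (configurable per region)
    matches its target exactly -- the knob that lets tests emulate
    high-dependence regions.
    """
    spec.validate()
    ns = spec.nutrition
    rng = np.random.default_rng(spec.seed + 1)
    rni, preg = build_rni_table(ns)
    strata = list(rni.index)

    pyramid: dict[str, pd.Series] = {}
    births: dict[str, float] = {}
    supply: dict[str, float] = {}
    content = dict(DEFAULT_WHEAT_CONTENT)

    # deferred import: requirement arithmetic lives in nutrition_risk
    from .nutrition_risk import population_requirement

    for r in spec.regions:
        weights = rng.dirichlet(np.full(len(strata), 8.0))
        pop = ns.base_population * float(
            np.exp(spec.heterogeneity * rng.standard_normal())
        )
        counts = pd.Series(weights * pop, index=rni.index)
        pyramid[r] = counts
        births[r] = ns.birth_rate * pop
        req = population_requirement(
            counts, rni, births[r], biomass_adjustment=ns.biomass_adjustment, pregnancy_increment=preg
        )
        nutrient, share = ns.wheat_contribution.get(r, (ns.anchor_nutrient, ns.default_share))
        if nutrient not in content:
            raise ValueError(f"unknown anchor nutrient {nutrient!r} for region {r!r}")
        supply[r] = share * req[nutrient] / content[nutrient]

    tables = NutritionTables(
        nutrient_content=content,
        pyramid=pyramid,
        births=births,
        rni=rni,
        pregnancy_increment=preg,
        wheat_supply_kg=supply,
        tiers={"iron": ns.iron_tier, "zinc": ns.zinc_tier, "energy": ns.energy_tier},
        biomass_adjustment=ns.biomass_adjustment,
    )
    tables.validate()
    return tables
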