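"""Nutrition-at-risk statistics.

Converts wheat supplies into nutrient supplies, computes age- and
sex-adjusted population requirements, extracts worst-tail consumption
losses (value at risk) from Monte Carlo consumption distributions, and
expresses them as percentages of annual population nutrient requirements
(NAR).  Also measures how an export-quota scenario shifts the return
period of a given tail loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ContributionShare",
    "NARResult",
    "nutrient_supply",
    "population_requirement",
    "contribution_share",
    "value_at_risk",
    "nar",
    "return_period_amplification",
    "nar_table",
]


@dataclass(frozen=True)
class ContributionShare:
    """Wheat-based annual nutrient supply over annual population requirement.

    ``shares[region][nutrient]`` is dimensionless and may exceed 1 where
    wheat alone supplies more than the recommended intake.
    """

    shares: Mapping[str, Mapping[str, float]]

    def __post_init__(self):
        for region, by_nutrient in self.shares.items():
            for nutrient, v in by_nutrient.items():
                if v < 0:
                    raise ValueError(
                        f"contribution share must be nonnegative ({region}/{nutrient})"
                    )

    def of(self, region: str, nutrient: str) -> float:
        return float(self.shares[region][nutrient])

    def region(self, region: str) -> Mapping[str, float]:
        return self.shares[region]


@dataclass(frozen=True)
class NARResult:
    region: str
    nutrient: str
    tail_probability: float
    var_pct: float  # tail consumption change, % of reference consumption
    nar_pct: float  # % of annual population requirement
    scenario: str


def nutrient_supply(wheat_supply_kg: float, profile: Mapping[str, float]) -> dict[str, float]:
    """Annual nutrient supply = wheat food supply (kg) x unit content (per kg)."""
    if wheat_supply_kg < 0:
        raise ValueError("wheat supply must be nonnegative")
    if not profile:
        raise ValueError("empty nutrient profile")
    return {n: wheat_supply_kg * float(c) for n, c in profile.items()}


def population_requirement(
    pyramid: pd.Series,
    rni_table: pd.DataFrame,
    births: float = 0.0,
    *,
    biomass_adjustment: float = 1.0,
    pregnancy_increment: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Annual population requirement per nutrient.

    ``requirement = sum_strata(count * daily intake * 365)
    + births * daily pregnancy increment * 365``.  Energy and protein are
    scaled by the regional biomass adjustment factor.  The births count
    proxies the number of pregnant women.
    """
    if (pyramid < 0).any():
        raise ValueError("population counts must be nonnegative")
    if births < 0:
        raise ValueError("births must be nonnegative")
    missing = set(pyramid.index) - set(rni_table.index)
    if missing:
        raise ValueError(f"strata without intake values: {sorted(missing)}")
    counts = pyramid.reindex(rni_table.index).fillna(0.0)
    out: dict[str, float] = {}
    for nutrient in rni_table.columns:
        daily = float(counts @ rni_table[nutrient])
        if pregnancy_increment is not None and nutrient in pregnancy_increment:
            daily += births * float(pregnancy_increment[nutrient])
        if nutrient in ("energy", "protein"):
            daily *= biomass_adjustment
        out[nutrient] = daily * 365.0
    return out


def contribution_share(
    supply: Mapping[str, float], requirement: Mapping[str, float]
) -> dict[str, float]:
    """Per-nutrient supply/requirement ratio; requires positive requirements."""
    out = {}
    for nutrient, s in supply.items():
        req = requirement.get(nutrient, 0.0)
        if req <= 0:
            raise ValueError(f"requirement for {nutrient!r} must be positive")
        out[nutrient] = s / req
    return out


def _values(dist) -> np.ndarray:
    v = getattr(dist, "values", dist)
    return np.asarray(v, dtype=float)


def value_at_risk(dist, p: float) -> float:
    """Worst-tail order statistic: the ceil(p*n)-th smallest value.

    No interpolation -- for 1000 draws at p = 0.05 this is the 50th
    smallest consumption change.
    """
    if not 0.0 < p < 0.5:
        raise ValueError("tail probability must lie in (0, 0.5)")
    v = _values(dist)
    if v.size == 0:
        raise ValueError("empty distribution")
    k = math.ceil(p * v.size)
    return float(np.sort(v)[k - 1])


def nar(
    var_value: float,
    shares: Mapping[str, float],
    *,
    region: str = "",
    tail_probability: float = 0.05,
    scenario: str = "Y",
) -> list[NARResult]:
    """Convert a tail consumption change (%) into per-nutrient NAR records.

    ``NAR% = VaR% x contribution share``, sign preserving.
    """
    return [
        NARResult(
            region=region,
            nutrient=nutrient,
            tail_probability=tail_probability,
            var_pct=float(var_value),
            nar_pct=float(var_value) * float(share),
            scenario=scenario,
        )
        for nutrient, share in shares.items()
    ]


def return_period_amplification(dist_y, dist_yq, p_ref: float = 0.01) -> dict[str, float]:
    """Locate scenario Y's ``p_ref`` tail value inside the YQ distribution.

    Returns the empirical probability that the (paired) quota scenario
    falls at or below Y's ``p_ref``-tail value, plus the implied return
    period in years (1 draw = 1 year).  Distributions must be paired:
    identical draw counts and, when metadata is available, identical
    seeds.
    """
    if not 0.0 < p_ref < 0.5:
        raise ValueError("tail probability must lie in (0, 0.5)")
    vy, vq = _values(dist_y), _values(dist_yq)
    if vy.size != vq.size:
        raise ValueError("unpaired distributions: draw counts differ")
    seed_y, seed_q = getattr(dist_y, "seed", None), getattr(dist_yq, "seed", None)
    if seed_y is not None and seed_q is not None and seed_y != seed_q:
        raise ValueError("unpaired distributions: seeds differ")
    v = value_at_risk(vy, p_ref)
    prob = float(np.mean(vq <= v))
    period = float("inf") if prob == 0 else 1.0 / prob
    return {"threshold": v, "probability": prob, "return_period_years": period}


def nar_table(results: Iterable[NARResult], flag_threshold: float = 5.0) -> pd.DataFrame:
    """Pivot NAR records into a region x nutrient table of percentages.

    Adds a ``flagged`` column listing nutrients whose loss exceeds the
    threshold (in percent of requirement).
    """
    rows = list(results)
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame([r.__dict__ for r in rows])
    wide = df.pivot_table(index="region", columns="nutrient", values="nar_pct", aggfunc="first")
    order = [n for n in ("protein", "energy", "iron", "zinc", "folate", "magnesium") if n in wide]
    wide = wide[order + [c for c in wide.columns if c not in order]]
    nutrient_cols = list(wide.columns)
    wide["flagged"] = [
        ";".join(n for n in nutrient_cols if wide.loc[r, n] <= -flag_threshold)
        for r in wide.index
    ]
    return wide
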