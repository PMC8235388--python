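"""Monte Carlo shock generation and scenario batches.

Draws seeded matrices of multiplicative wheat-productivity shifters
(i.i.d. normal around 1 with regional standard deviations sigma_r,
clamped at a floor, default 0.3), and runs the equilibrium model once
per draw, collecting each region's household wheat-consumption change
relative to the benchmark.  The quota scenario (YQ) is run on the same
shock matrix as the yield-only scenario (Y) so the two distributions
are coupled draw by draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cge_core
from .errors import BatchError, SolverError
from .sam_calibration import CalibratedParams, QuotaSet

__all__ = ["ShockMatrix", "ConsumptionDistribution", "draw_shocks", "run_batch"]

log = logging.getLogger(__name__)

SCENARIOS = ("Reference", "Y", "YQ")


@dataclass(frozen=True)
class ShockMatrix:
    """draws x regions grid of multiplicative wheat TFP shifters."""

    values: np.ndarray  # (n_draws, n_regions), clamped at floor
    regions: tuple[str, ...]
    sigmas: np.ndarray  # (n_regions,)
    floor: float
    seed: int
    truncation_counts: np.ndarray  # raw draws below the floor, per region

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[1] != len(self.regions):
            raise ValueError("shock matrix shape does not match region labels")
        if np.any(self.values < self.floor - 1e-12):
            raise ValueError("shock matrix contains entries below the floor")

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# seed={self.seed} floor={self.floor} "
                f"sigmas={','.join(f'{s:.6g}' for s in self.sigmas)}\n"
            )
            pd.DataFrame(self.values, columns=list(self.regions)).to_csv(fh, index_label="draw")


@dataclass(frozen=True)
class ConsumptionDistribution:
    """Per-region household wheat-consumption changes over a shock batch.

    Values are percent changes from the benchmark (reference-year)
    consumption; failed solves are excluded and counted.
    """

    region: str
    values: np.ndarray
    scenario: str
    seed: int
    n_draws: int
    n_failed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.values.size > self.n_draws:
            raise ValueError("more values than draws")


def draw_shocks(
    sigmas, n_draws: int, floor: float = 0.3, seed: int = 0, regions=None
) -> ShockMatrix:
    """Draw ``max(floor, N(1, sigma_r))`` shifters, i.i.d. across draws and regions.

    Regions with ``sigma_r = 0`` get a column identically equal to 1.
    The floor is applied by clamping (not redrawing); clamped counts are
    recorded per region.
    """
    if isinstance(sigmas, dict):
        regions = tuple(sigmas.keys()) if regions is None else tuple(regions)
        sig = np.array([float(sigmas[r]) for r in regions])
    else:
        sig = np.asarray(sigmas, dtype=float)
        regions = (
            tuple(regions) if regions is not None else tuple(f"r{i}" for i in range(sig.size))
        )
    if np.any(sig < 0):
        raise ValueError("sigma_r must be nonnegative")
    if n_draws < 1:
        raise ValueError("need at least one draw")
    if not 0.0 <= floor < 1.0:
        raise ValueError("floor must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    raw = 1.0 + rng.standard_normal((n_draws, sig.size)) * sig[None, :]
    trunc = (raw < floor).sum(axis=0)
    values = np.maximum(raw, floor)
    values[:, sig == 0] = 1.0
    trunc[sig == 0] = 0
    return ShockMatrix(
        values=values,
        regions=regions,
        sigmas=sig,
        floor=floor,
        seed=seed,
        truncation_counts=trunc,
    )


def run_batch(
    params: CalibratedParams,
    shocks: ShockMatrix,
    scenario: str,
    quotas: QuotaSet | None = None,
    *,
    max_failure_rate: float = 0.05,
    solver_tol: float = 1e-9,
) -> dict[str, ConsumptionDistribution]:
    """Solve the model once per draw and collect consumption changes.

    ``Reference`` runs nothing (all changes are zero by definition);
    ``Y`` runs without quotas; ``YQ`` requires a quota set.  Draws whose
    solve fails are excluded and counted; a failure rate above
    ``max_failure_rate`` raises :class:`BatchError`.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if tuple(shocks.regions) != tuple(params.regions):
        raise ValueError("shock matrix regions do not match calibrated regions")
    if scenario == "YQ" and quotas is None:
        raise ValueError("scenario YQ requires a quota set")
    if scenario != "YQ":
        quotas = None

    n = shocks.n_draws
    if scenario == "Reference":
        return {
            r: ConsumptionDistribution(
                region=r,
                values=np.zeros(n),
                scenario=scenario,
                seed=shocks.seed,
                n_draws=n,
            )
            for r in params.regions
        }

    wheat = params.sector_index(params.wheat_sector)
    base = params.benchmark["C"][:, wheat]
    changes: list[np.ndarray] = []
    n_failed = 0
    warm = None
    for k in range(n):
        shock = cge_core.ShockVector(shocks.values[k], floor=shocks.floor)
        system = cge_core.build_system(params, shock, quotas)
        try:
            sol = cge_core.solve(system, tol=solver_tol, warm_start=warm)
        except SolverError as err:
            n_failed += 1
            log.warning(
                "draw %d failed (scenario %s): best residual %.3e",
                k,
                scenario,
                err.best_residual,
            )
            changes.append(None)
            continue
        changes.append(100.0 * (sol.consumption[:, wheat] / base - 1.0))
        log.debug("draw %d: %d iterations, residual %.2e", k, sol.iterations, sol.max_residual)
    if n_failed > max_failure_rate * n:
        raise BatchError(
            f"{n_failed}/{n} solves failed in scenario {scenario};"
            " distribution deemed unreliable"
        )
    kept = np.array([c for c in changes if c is not None])
    return {
        r: ConsumptionDistribution(
            region=r,
            values=kept[:, ri].copy(),
            scenario=scenario,
            seed=shocks.seed,
            n_draws=n,
            n_failed=n_failed,
        )
        for ri, r in enumerate(params.regions)
    }


def distributions_to_frame(dists: dict[str, ConsumptionDistribution]) -> pd.DataFrame:
    """Long-format frame of consumption changes (one row per draw x region)."""
    frames = []
    for r, d in dists.items():
        frames.append(
            pd.DataFrame(
                {
                    "region": r,
                    "scenario": d.scenario,
                    "draw": np.arange(d.values.size),
                    "consumption_change_pct": d.values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
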