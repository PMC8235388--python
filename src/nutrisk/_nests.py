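"""Constant-elasticity aggregator nests (CES, CET, Cobb-Douglas limit).

A single primitive backs every nest in the equilibrium model: value-added
CES, Armington domestic/import CES, bilateral import sourcing CES, the
household food nest, and -- via a negative elasticity -- the CET output
transformation nests.  Conventions:

* ``sigma > 0`` is a CES substitution elasticity (cost minimisation);
* ``sigma < 0`` encodes a CET nest with transformation elasticity
  ``psi = -sigma`` (revenue maximisation); the dual formulas coincide;
* ``|sigma - 1| < 1e-6`` falls back to the Cobb-Douglas limiting form.

Nests are calibrated from benchmark quantities under the unit-price
convention: at ``p = 1`` the unit cost (or unit revenue) is 1 and the
per-unit demand (supply) coefficients reproduce the benchmark shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_CD_TOL = 1e-6


@dataclass(frozen=True)
class Nest:
    """A calibrated constant-elasticity aggregator over ``m`` components."""

    sigma: float
    delta: np.ndarray  # share parameters, sum to 1
    scale: float  # efficiency/scale parameter
    benchmark: np.ndarray = field(repr=False)  # component quantities at p=1

    @property
    def is_cobb_douglas(self) -> bool:
        return abs(self.sigma - 1.0) < _CD_TOL

    @classmethod
    def calibrate(cls, quantities, sigma: float) -> "Nest":
        """Calibrate shares and scale from benchmark quantities at unit prices.

        ``quantities`` must be strictly positive; the benchmark aggregate
        quantity is their sum (zero-profit at unit prices).
        """
        x = np.asarray(quantities, dtype=float)
        if x.ndim != 1 or x.size == 0:
            raise ValueError("benchmark quantities must be a non-empty 1-d array")
        if np.any(x <= 0):
            raise ValueError("benchmark quantities must be strictly positive")
        if sigma == 0:
            raise ValueError("elasticity must be nonzero")
        q = x.sum()
        if abs(sigma - 1.0) < _CD_TOL:
            alpha = x / q
            scale = q / np.prod(x**alpha)
            return cls(sigma=1.0, delta=alpha, scale=scale, benchmark=x)
        rho = (sigma - 1.0) / sigma
        raw = x ** (1.0 / sigma)
        delta = raw / raw.sum()
        scale = q / (delta @ x**rho) ** (1.0 / rho)
        return cls(sigma=sigma, delta=delta, scale=scale, benchmark=x)

    def price(self, p) -> float:
        """Unit cost (CES) or unit revenue (CET) at component prices ``p``."""
        p = np.asarray(p, dtype=float)
        if self.is_cobb_douglas:
            return float(np.prod((p / self.delta) ** self.delta) / self.scale)
        s = self.sigma
        val = self.delta**s @ p ** (1.0 - s)
        return float(val ** (1.0 / (1.0 - s)) / self.scale)

    def coefs(self, p) -> np.ndarray:
        """Per-unit-of-aggregate component demands (CES) / supplies (CET)."""
        p = np.asarray(p, dtype=float)
        c = self.price(p)
        if self.is_cobb_douglas:
            return self.delta * c / p
        s = self.sigma
        return self.scale ** (s - 1.0) * c**s * (self.delta / p) ** s

    def quantities(self, aggregate: float, p) -> np.ndarray:
        """Component quantities for a given aggregate at prices ``p``."""
        return aggregate * self.coefs(p)

    def aggregate(self, quantities) -> float:
        """Evaluate the aggregator at component quantities."""
        x = np.asarray(quantities, dtype=float)
        if self.is_cobb_douglas:
            return float(self.scale * np.prod(x**self.delta))
        rho = (self.sigma - 1.0) / self.sigma
        return float(self.scale * (self.delta @ x**rho) ** (1.0 / rho))


def cet(quantities, psi: float) -> Nest:
    """Calibrate a CET nest with transformation elasticity ``psi > 0``."""
    if psi <= 0:
        raise ValueError("CET transformation elasticity must be positive")
    return Nest.calibrate(quantities, sigma=-psi)
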