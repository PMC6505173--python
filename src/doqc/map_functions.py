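"""Genetic map functions.

Conversions between genetic distance (centiMorgans) and recombination
fraction under the Carter-Falconer map function, which models strong
positive crossover interference, with the Haldane (no-interference) map
function kept as a cross-check baseline.

The Carter-Falconer function is defined in the distance direction,

    d(r) = 25 * [atanh(2r) + atan(2r)]   (d in cM, r in [0, 0.5)),

and inverted numerically for the distance -> recombination direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

#: Largest representable recombination fraction (map functions diverge at 0.5).
R_MAX = 0.5 - 1e-12

#: Floor applied to inter-marker recombination fractions so that transition
#: matrices built from co-located markers (d = 0) remain irreducible.
R_FLOOR = 1e-8


def _check_r(r: np.ndarray) -> None:
    if np.any(r < 0.0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must satisfy 0 <= r < 0.5")


def carter_falconer_dist(r):
    """Genetic distance (cM) for recombination fraction ``r`` (Carter-Falconer).

    Accepts scalars or arrays; raises ``ValueError`` outside [0, 0.5).
    """
    arr = np.asarray(r, dtype=float)
    _check_r(arr)
    d = 25.0 * (np.arctanh(2.0 * arr) + np.arctan(2.0 * arr))
    return float(d) if np.ndim(r) == 0 else d


def haldane_dist(r):
    """Genetic distance (cM) for recombination fraction ``r`` (Haldane)."""
    arr = np.asarray(r, dtype=float)
    _check_r(arr)
    d = -50.0 * np.log1p(-2.0 * arr)
    return float(d) if np.ndim(r) == 0 else d


def haldane_rf(d):
    """Recombination fraction for distance ``d`` cM (Haldane)."""
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0.0):
        raise ValueError("distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-arr / 50.0))
    return float(r) if np.ndim(d) == 0 else r


# Distance beyond which the Carter-Falconer inverse saturates at R_MAX.
_CF_D_MAX = carter_falconer_dist(R_MAX)


def carter_falconer_rf(d, tol: float = 1e-12):
    """Recombination fraction for distance ``d`` cM (Carter-Falconer).

    The unique root of ``carter_falconer_dist(r) = d`` on [0, 0.5), found by
    bracketed root finding (``tol`` is the convergence tolerance in r units).
    Very large distances saturate toward 0.5.
    """
    if np.ndim(d) != 0:
        return np.array([carter_falconer_rf(x, tol) for x in np.asarray(d, dtype=float)])
    d = float(d)
    if d < 0.0:
        raise ValueError("distance must be non-negative")
    if d == 0.0:
        return 0.0
    if d >= _CF_D_MAX:
        return R_MAX
    return brentq(lambda r: carter_falconer_dist(r) - d, 0.0, R_MAX, xtol=tol)


_FORWARD = {"carter_falconer": carter_falconer_rf, "haldane": haldane_rf}
_INVERSE = {"carter_falconer": carter_falconer_dist, "haldane": haldane_dist}


@dataclass(frozen=True)
class MapFunctionSpec:
    """Named map function plus the root-finding tolerance for its inversion."""

    name: str = "carter_falconer"
    tolerance: float = 1e-12

    def __post_init__(self):
        if self.name not in _FORWARD:
            raise ValueError(f"unknown map function: {self.name!r}")
        if not (0.0 < self.tolerance <= 1e-8):
            raise ValueError("tolerance must be positive and at most 1e-8")

    def rf(self, d):
        """Distance (cM) -> recombination fraction."""
        if self.name == "carter_falconer":
            return carter_falconer_rf(d, tol=self.tolerance)
        return haldane_rf(d)

    def dist(self, r):
        """Recombination fraction -> distance (cM)."""
        return _INVERSE[self.name](r)


def interval_rf(d_cM: float, spec: MapFunctionSpec | None = None) -> float:
    """Recombination fraction for a marker interval, floored at ``R_FLOOR``.

    The floor keeps zero-length intervals (duplicate map positions) from
    producing degenerate all-or-nothing transition matrices.
    """
    spec = spec or MapFunctionSpec()
    return max(float(spec.rf(d_cM)), R_FLOOR)


def map_expansion_rate(n_gen_eff: float, n_founders: int = 8) -> float:
    """Exchange-point density ``a`` (per Morgan) of the founder mosaic.

    Under the exchangeable-founder mosaic model, exchange points occur at
    rate ``a = n_gen_eff * n_founders / (n_founders - 1)`` per Morgan; at
    each exchange the founder is redrawn uniformly (self allowed), so the
    density of *visible* founder switches is ``n_gen_eff`` per Morgan.
    """
    if n_gen_eff <= 0:
        raise ValueError("n_gen_eff must be positive")
    return n_gen_eff * n_founders / (n_founders - 1)


__all__ = [
    "R_MAX",
    "R_FLOOR",
    "MapFunctionSpec",
    "carter_falconer_dist",
    "carter_falconer_rf",
    "haldane_dist",
    "haldane_rf",
    "interval_rf",
    "map_expansion_rate",
]
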