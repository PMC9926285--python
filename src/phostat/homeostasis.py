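"""Internal phosphate concentration at a fixed consumption demand.

Growth at constant rate implies a constant phosphate consumption rate
``J_demand``.  The internal concentration then settles where net import
exactly balances consumption: ``flux(s_out, s_in) = J_demand``.  Because
every flux law here is strictly decreasing in ``s_in``, that balance point
is unique and stable (an excess of internal substrate lowers net import,
a deficit raises it).

Below a critical external concentration even an empty cell cannot import
fast enough; the internal level then drains to zero.  That regime is
reported explicitly as *starvation* rather than raised as an error, since
downstream regulon logic consumes it as ``s_in = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .transport import FluxQuery, TransporterParams, carrier_flux, mm_flux

__all__ = [
    "DemandQuery",
    "HomeostasisResult",
    "solve_internal",
    "critical_external",
    "internal_curve",
    "robustness_index",
]

_MODELS = ("carrier", "mm")


@dataclass(frozen=True)
class DemandQuery:
    """A fixed consumption demand to be met by one flux law."""

    j_demand: float
    model: str
    params: TransporterParams

    def __post_init__(self) -> None:
        if not np.isfinite(self.j_demand) or self.j_demand <= 0:
            raise ValueError("j_demand must be finite and > 0")
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}, got {self.model!r}")

    def flux(self, s_out: float, s_in: float) -> float:
        q = FluxQuery(s_out=s_out, s_in=s_in)
        if self.model == "carrier":
            return carrier_flux(self.params, q)
        return mm_flux(self.params, q)

    def flux_supremum(self) -> float:
        """Largest attainable import rate (s_out -> inf, s_in = 0)."""
        p = self.params
        if self.model == "carrier":
            return p.et * p.k2 * p.k4 / (p.k2 + p.k4)
        return p.et * p.k2


@dataclass(frozen=True)
class HomeostasisResult:
    """Either a balance concentration or an explicit starvation flag."""

    s_in: float | None
    starved: bool


def solve_internal(d: DemandQuery, s_out: float) -> HomeostasisResult:
    """Internal concentration at which import balances ``j_demand``.

    Returns a starved result when even ``s_in = 0`` cannot supply the
    demand.  Otherwise the unique root of ``flux(s_out, .) - j_demand`` in
    ``[0, s_out]`` is bracketed and found by Brent's method; uniqueness and
    bracket validity follow from strict monotonicity of the flux in
    ``s_in`` (the flux vanishes at ``s_in = s_out`` for the carrier and is
    non-positive there for the symmetric-rate comparator).
    """
    if not np.isfinite(s_out) or s_out < 0:
        raise ValueError("s_out must be finite and >= 0")
    f0 = d.flux(s_out, 0.0) - d.j_demand
    if f0 < 0:
        return HomeostasisResult(s_in=None, starved=True)
    if f0 == 0.0 or s_out == 0.0:
        return HomeostasisResult(s_in=0.0, starved=False)

    def g(s_in: float) -> float:
        return d.flux(s_out, s_in) - d.j_demand

    hi = s_out
    if g(hi) > 0:  # mm with k2 > k4 can stay positive at s_in = s_out
        while g(hi) > 0:
            hi *= 10.0
            if hi > 1e12 * max(s_out, d.params.Kd):
                raise RuntimeError("failed to bracket the balance point")
    root = brentq(g, 0.0, hi, xtol=1e-14 * max(1.0, hi), rtol=1e-12)
    return HomeostasisResult(s_in=float(root), starved=False)


def critical_external(d: DemandQuery) -> float | None:
    """Smallest ``s_out`` at which an empty cell can meet the demand.

    Returns ``None`` (unattainable) when ``j_demand`` meets or exceeds the
    supremum of ``flux(., 0)``, which is only approached in the limit of
    infinite external substrate.
    """
    if d.j_demand >= d.flux_supremum():
        return None

    def g(s_out: float) -> float:
        return d.flux(s_out, 0.0) - d.j_demand

    hi = d.params.Kd
    while g(hi) < 0:
        hi *= 10.0
    root = brentq(g, 0.0, hi, xtol=1e-14 * max(1.0, hi), rtol=1e-12)
    return float(root)


def internal_curve(d: DemandQuery, s_out_grid) -> pd.DataFrame:
    """Vectorised :func:`solve_internal` over a grid, preserving order.

    Returns a frame with columns ``s_out``, ``s_in`` (NaN when starved)
    and ``starved`` (bool).
    """
    rows = []
    for s_out in s_out_grid:
        res = solve_internal(d, float(s_out))
        rows.append(
            {
                "s_out": float(s_out),
                "s_in": np.nan if res.starved else res.s_in,
                "starved": res.starved,
            }
        )
    return pd.DataFrame(rows, columns=["s_out", "s_in", "starved"])


def robustness_index(d: DemandQuery, lo_factor: float, hi_factor: float) -> float:
    """Fold-change of ``s_in`` across a stated multiple of the critical point.

    Evaluates ``s_in`` at ``lo_factor * c`` and ``hi_factor * c`` where
    ``c = critical_external(d)`` and returns their ratio.  Anchoring the
    range to the model's own critical threshold compares carrier and
    Michaelis–Menten laws over equivalent operating ranges; values near 1
    mean the internal level barely moves, i.e. robust homeostasis.
    """
    if lo_factor < 1 or hi_factor < 1 or hi_factor < lo_factor:
        raise ValueError("factors must satisfy 1 <= lo_factor <= hi_factor")
    c = critical_external(d)
    if c is None:
        raise ValueError("demand is unattainable for this model/parameter set")
    if lo_factor == hi_factor:
        return 1.0
    lo = solve_internal(d, lo_factor * c)
    hi = solve_internal(d, hi_factor * c)
    if lo.starved or hi.starved or lo.s_in == 0.0:
        raise ValueError("starvation (or zero internal level) inside the range")
    return float(hi.s_in / lo.s_in)
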