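"""Steady-state flux laws for membrane phosphate transporters.

Two kinetic pictures of a saturable uniporter are implemented side by side:

* :func:`carrier_flux` — a symmetric alternating-access *carrier*: a single
  pool of transporters cycles between outward- and inward-facing
  conformations, so influx and efflux compete for the same protein.  The
  hallmark of this law is that the import rate becomes independent of the
  external substrate concentration once the outer face is saturated, which
  is what lets a cell hold its internal phosphate level constant over
  decades of external concentration.

* :func:`mm_flux` — an uncoupled Michaelis–Menten comparator in which
  influx and efflux saturate independently.  Under this law the internal
  concentration tracks the external one, the behaviour the carrier model
  is contrasted against.

All quantities are in arbitrary model units (concentrations share the unit
of ``Kd``, amounts the unit of ``et``, time the inverse of ``k2``/``k4``).
:func:`carrier_ode_flux` integrates the mass-action scheme numerically and
serves as an independent brute-force oracle for the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "TransporterParams",
    "FluxQuery",
    "CarrierMicrostate",
    "ConvergenceError",
    "DEFAULT_PARAMS",
    "occupancy",
    "carrier_flux",
    "mm_flux",
    "carrier_ode_flux",
    "carrier_steady_microstate",
]


class ConvergenceError(RuntimeError):
    """The ODE oracle failed to reach stationarity within ``t_end``."""


@dataclass(frozen=True)
class TransporterParams:
    """Kinetic constants of one transporter species.

    Parameters
    ----------
    k2
        Translocation rate of the loaded carrier (per unit time), the same
        in both directions.
    k4
        Translocation rate of the empty carrier (per unit time), the same
        in both directions.
    Kd
        Substrate dissociation constant, identical on both membrane faces
        (concentration units).
    et
        Total transporter amount (arbitrary amount units).
    """

    k2: float
    k4: float
    Kd: float
    et: float

    def __post_init__(self) -> None:
        for name in ("k2", "k4", "Kd", "et"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")


#: Reference parameter set used throughout the package's worked examples.
DEFAULT_PARAMS = TransporterParams(k2=4.0, k4=4.0, Kd=10.0, et=10.0)


@dataclass(frozen=True)
class FluxQuery:
    """External and internal substrate concentrations for a flux evaluation."""

    s_out: float
    s_in: float

    def __post_init__(self) -> None:
        for name in ("s_out", "s_in"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class CarrierMicrostate:
    """Occupancy of the four carrier conformations (amount units).

    Internal state of the ODE oracle.  The four occupancies always sum to
    the total transporter amount ``et``.
    """

    outward_empty: float
    outward_loaded: float
    inward_empty: float
    inward_loaded: float

    @property
    def total(self) -> float:
        return (
            self.outward_empty
            + self.outward_loaded
            + self.inward_empty
            + self.inward_loaded
        )


def occupancy(s, Kd):
    """Rapid-equilibrium binding fraction ``s / (Kd + s)``.

    Accepts scalars or arrays for ``s``; monotone increasing in ``s`` and
    bounded in ``[0, 1)``.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or not np.all(np.isfinite(s)):
        raise ValueError("substrate concentration must be finite and >= 0")
    if not np.isfinite(Kd) or Kd <= 0:
        raise ValueError("Kd must be finite and > 0")
    out = s / (Kd + s)
    return float(out) if out.ndim == 0 else out


def _carrier_flux_raw(k2, k4, Kd, et, s_out, s_in):
    """Closed-form carrier flux on raw floats/arrays (no validation).

    Derivation (two-pool reduction of the four-state cycle): with rapid
    equilibrium binding on each face, the outward-facing pool Eo carries a
    loaded fraction th_o = s_out/(Kd+s_out) and the inward-facing pool Ei a
    fraction th_i.  Pool exchange rates are r_o = k2*th_o + k4*(1-th_o)
    (outward -> inward) and r_i = k2*th_i + k4*(1-th_i) (inward -> outward).
    At steady state r_o*Eo = r_i*Ei with Eo + Ei = et, and the net import
    rate is J = k2*(th_o*Eo - th_i*Ei), which simplifies to

        J = et*k2*k4*(th_o - th_i) / (k2*(th_o + th_i) + k4*(2 - th_o - th_i)).
    """
    th_o = s_out / (Kd + s_out)
    th_i = s_in / (Kd + s_in)
    num = et * k2 * k4 * (th_o - th_i)
    den = k2 * (th_o + th_i) + k4 * (2.0 - th_o - th_i)
    return num / den


def carrier_flux(p: TransporterParams, q: FluxQuery) -> float:
    """Steady-state net import rate of the alternating-access carrier.

    Positive values are net import.  The flux is antisymmetric under
    exchange of ``s_out`` and ``s_in`` and bounded in magnitude by
    ``et*k2*k4/(k2+k4)``.
    """
    return float(_carrier_flux_raw(p.k2, p.k4, p.Kd, p.et, q.s_out, q.s_in))


def _mm_flux_raw(k2, k4, Kd, et, s_out, s_in):
    th_o = s_out / (Kd + s_out)
    th_i = s_in / (Kd + s_in)
    return et * (k2 * th_o - k4 * th_i)


def mm_flux(p: TransporterParams, q: FluxQuery) -> float:
    """Uncoupled Michaelis–Menten comparator flux.

    Influx ``et*k2*occupancy(s_out)`` and efflux ``et*k4*occupancy(s_in)``
    saturate independently; there is no shared carrier pool.
    """
    return float(_mm_flux_raw(p.k2, p.k4, p.Kd, p.et, q.s_out, q.s_in))


def _pool_rates(p: TransporterParams, q: FluxQuery):
    th_o = occupancy(q.s_out, p.Kd)
    th_i = occupancy(q.s_in, p.Kd)
    r_o = p.k2 * th_o + p.k4 * (1.0 - th_o)  # outward pool -> inward pool
    r_i = p.k2 * th_i + p.k4 * (1.0 - th_i)  # inward pool -> outward pool
    return th_o, th_i, r_o, r_i


def carrier_steady_microstate(
    p: TransporterParams,
    q: FluxQuery,
    t_end: float | None = None,
    tol: float = 1e-12,
) -> CarrierMicrostate:
    """Integrate the carrier mass-action ODE to stationarity.

    The rapid-equilibrium reduction leaves a single dynamical variable, the
    outward-facing pool Eo (the inward pool is et - Eo, so conservation is
    exact by construction):

        dEo/dt = -r_o * Eo + r_i * (et - Eo)

    with the pool-exchange rates of :func:`_carrier_flux_raw`.  Loaded and
    empty occupancies within each pool follow the equilibrium fractions.

    Raises
    ------
    ConvergenceError
        If ``max |dEo/dt| < tol * et`` is not reached by ``t_end``.
    """
    th_o, th_i, r_o, r_i = _pool_rates(p, q)
    lam = r_o + r_i  # relaxation rate of the single eigenmode
    if t_end is None:
        t_end = 80.0 / lam

    def rhs(_t, y):
        return [-r_o * y[0] + r_i * (p.et - y[0])]

    # Stiff-capable implicit integrator; tolerances well below the 1e-8
    # relative agreement demanded of the oracle.
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [0.5 * p.et],
        method="Radau",
        rtol=1e-12,
        atol=1e-13 * p.et,
    )
    if not sol.success:
        raise ConvergenceError(f"carrier ODE integration failed: {sol.message}")
    e_o = float(sol.y[0, -1])
    if abs(rhs(0.0, [e_o])[0]) >= tol * p.et * max(lam, 1.0):
        raise ConvergenceError(
            "carrier ODE did not reach stationarity within t_end="
            f"{t_end!r} (residual {rhs(0.0, [e_o])[0]!r})"
        )
    e_i = p.et - e_o
    return CarrierMicrostate(
        outward_empty=(1.0 - th_o) * e_o,
        outward_loaded=th_o * e_o,
        inward_empty=(1.0 - th_i) * e_i,
        inward_loaded=th_i * e_i,
    )


def carrier_ode_flux(
    p: TransporterParams,
    q: FluxQuery,
    t_end: float | None = None,
    tol: float = 1e-12,
) -> float:
    """Brute-force oracle for :func:`carrier_flux` via ODE integration.

    Integrates the four-state scheme to stationarity and reports the net
    loaded-translocation flux ``k2*(th_o*Eo - th_i*Ei)``.
    """
    ms = carrier_steady_microstate(p, q, t_end=t_end, tol=tol)
    th_o = occupancy(q.s_out, p.Kd)
    th_i = occupancy(q.s_in, p.Kd)
    e_o = ms.outward_empty + ms.outward_loaded
    e_i = ms.inward_empty + ms.inward_loaded
    return float(p.k2 * (th_o * e_o - th_i * e_i))
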