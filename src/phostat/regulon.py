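"""Dynamical model of the dual-transporter Pho regulon.

The model couples two carrier-type phosphate transporters to a small gene
circuit:

* a **low-affinity** system (large ``Kd``), constitutively present at
  amount ``et_L`` but post-translationally inactivated by Spl2;
* a **high-affinity** system (small ``Kd``) whose expression level ``e_H``
  is induced, like Spl2 and the reporters, by nuclear Pho4.

Internal phosphate ``s_in`` is a fast variable: at every instant it sits
where total import balances the constant consumption demand (zero when
demand cannot be met).  The Pho80/Pho85 kinase read-out is abstracted into
a three-level transfer function: nuclear Pho4 is 0 when ``s_in`` is above
``phi_plateau``, an intermediate level ``n_mid`` between the two
thresholds, and 1 (fully nuclear) below ``phi_full``.  Promoters come in
two classes distinguished only by their activation midpoint: *plateau*
promoters (midpoint below ``n_mid``) respond to intermediate nuclear Pho4,
*decoupled* promoters (midpoint above ``n_mid``) only to full
localization.

This wiring yields three stationary programs — off, plateau, on — plus a
bistable transition: once Spl2 has shut the low-affinity carriers off, the
high-affinity system pins ``s_in`` at its own set point regardless of how
rich the medium is, so a cell that has entered the plateau state stays
committed there (hysteresis).  None of the regulon-level parameters are
measured quantities; the defaults are model units chosen so that the
low-affinity set point lies far above ``phi_plateau`` and the
high-affinity set point falls between the two thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .transport import TransporterParams

__all__ = [
    "RegulonParams",
    "CellTrajectory",
    "StateLabel",
    "NotConvergedError",
    "IntegrationError",
    "DEFAULT_SOUT_GRID",
    "default_params",
    "pho4_nuclear",
    "quasi_steady_internal",
    "simulate",
    "classify_state",
    "sweep",
    "bistable_window",
    "population_sweep",
    "plateau_like_init",
]


class NotConvergedError(RuntimeError):
    """Trajectory tail is non-stationary or sits between state definitions."""


class IntegrationError(RuntimeError):
    """Fixed-step integration went unstable (negative levels)."""


class StateLabel(str, Enum):
    OFF = "OFF"
    PLATEAU = "PLATEAU"
    ON = "ON"
    MIXED = "MIXED"  # population summaries only


@dataclass(frozen=True)
class RegulonParams:
    """Free parameters of the dual-transporter regulon model.

    ``params_H.et`` is the flux per unit of high-affinity expression; the
    instantaneous capacity is ``e_H(t) * params_H.et``.  Rates are per
    unit time with time measured in units of ``1/delta``.
    """

    params_L: TransporterParams = field(
        default_factory=lambda: TransporterParams(k2=4.0, k4=4.0, Kd=100.0, et=10.0)
    )
    params_H: TransporterParams = field(
        default_factory=lambda: TransporterParams(k2=4.0, k4=4.0, Kd=1.0, et=1.0)
    )
    j_demand: float = 15.0
    alpha_H: float = 10.0  # max high-affinity synthesis rate
    alpha_S: float = 10.0  # max Spl2 synthesis rate
    alpha_P: float = 100.0  # max reporter synthesis rate
    beta_P: float = 1.0  # basal reporter synthesis rate (basal level beta_P/delta)
    delta: float = 1.0  # dilution/degradation rate
    K_S: float = 1.0  # Spl2 level at half-inactivation of low-affinity carriers
    m: float = 2.0  # Hill coefficient of Spl2 inactivation
    phi_plateau: float = 5.0  # s_in below which Pho4 is partially nuclear
    phi_full: float = 0.05  # s_in below which Pho4 is fully nuclear
    n_mid: float = 0.4  # intermediate nuclear Pho4 level
    K_p: float = 0.15  # plateau-promoter activation midpoint (on n)
    K_d_prom: float = 0.75  # decoupled-promoter activation midpoint (on n)
    h: float = 8.0  # promoter Hill coefficient
    pho4_hill: float = 8.0  # steepness of the smoothed three-level transfer

    def __post_init__(self) -> None:
        if not self.params_H.Kd < self.params_L.Kd:
            raise ValueError("high-affinity Kd must be below low-affinity Kd")
        if not 0 < self.phi_full < self.phi_plateau:
            raise ValueError("need 0 < phi_full < phi_plateau")
        if not 0 < self.K_p < self.n_mid < self.K_d_prom <= 1:
            raise ValueError("need 0 < K_p < n_mid < K_d_prom <= 1")
        for name in ("j_demand", "alpha_H", "alpha_S", "alpha_P", "beta_P",
                     "delta", "m", "h", "pho4_hill"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.K_S <= 0:  # K_S = inf (no Spl2 inhibition) is allowed
            raise ValueError("K_S must be > 0")
        if self.pho4_hill < 8:
            raise ValueError("pho4_hill must be >= 8 for a crisp three-level map")

    @property
    def basal_reporter(self) -> float:
        return self.beta_P / self.delta


def default_params() -> RegulonParams:
    """Default parameter set (model units, high-affinity Kd = 1)."""
    return RegulonParams()


#: Default external-concentration grid for state-diagram sweeps.  The
#: points span the three regimes (on below ~3, plateau up to a few hundred,
#: off above ~400 on the downward path) while staying clear of the narrow
#: transition zones, where the smoothed transfer function produces
#: intermediate nuclear levels that the classifier deliberately refuses to
#: label.
DEFAULT_SOUT_GRID = (1.0, 2.0, 20.0, 40.0, 100.0, 600.0, 1500.0, 4000.0)


@dataclass
class CellTrajectory:
    """Time series of one simulated cell; arrays share the time grid."""

    time: np.ndarray
    s_in: np.ndarray
    e_H: np.ndarray
    spl2: np.ndarray
    a_L: np.ndarray
    n: np.ndarray
    p_plateau: np.ndarray
    p_decoupled: np.ndarray
    params: RegulonParams | None = None
    label: StateLabel | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "s_in": self.s_in,
                "e_H": self.e_H,
                "spl2": self.spl2,
                "a_L": self.a_L,
                "n": self.n,
                "p_plateau": self.p_plateau,
                "p_decoupled": self.p_decoupled,
            }
        )


# ---------------------------------------------------------------------------
# algebraic (fast) layer


def pho4_nuclear(s_in, p: RegulonParams):
    """Three-level nuclear Pho4 transfer function of internal phosphate.

    Smoothed as the sum of two steep descending Hill functions,

        n(s) = n_mid * H(s; phi_plateau) + (1 - n_mid) * H(s; phi_full),
        H(s; phi) = 1 / (1 + (s/phi)**c),

    so that n(0) = 1 exactly, n ~ n_mid between the thresholds and n ~ 0
    far above ``phi_plateau``, while remaining continuous.
    """
    s = np.asarray(s_in, dtype=float)
    if np.any(s < 0) or not np.all(np.isfinite(s)):
        raise ValueError("s_in must be finite and >= 0")
    c = p.pho4_hill
    h_plat = 1.0 / (1.0 + (s / p.phi_plateau) ** c)
    h_full = 1.0 / (1.0 + (s / p.phi_full) ** c)
    out = p.n_mid * h_plat + (1.0 - p.n_mid) * h_full
    return float(out) if out.ndim == 0 else out


def _total_flux(s_in, s_out, e_H, a_L, et_L, p: RegulonParams):
    """Total import through both transporter systems (array-safe)."""
    pL, pH = p.params_L, p.params_H
    to_L = s_out / (pL.Kd + s_out)
    ti_L = s_in / (pL.Kd + s_in)
    j_L = (
        et_L * pL.k2 * pL.k4 * (to_L - ti_L)
        / (pL.k2 * (to_L + ti_L) + pL.k4 * (2.0 - to_L - ti_L))
    )
    to_H = s_out / (pH.Kd + s_out)
    ti_H = s_in / (pH.Kd + s_in)
    j_H = (
        e_H * pH.et * pH.k2 * pH.k4 * (to_H - ti_H)
        / (pH.k2 * (to_H + ti_H) + pH.k4 * (2.0 - to_H - ti_H))
    )
    return a_L * j_L + j_H


def _quasi_steady_vec(e_H, a_L, s_out, et_L, p: RegulonParams, iters: int = 60):
    """Vectorised bisection for the fast internal-phosphate balance.

    The total flux is strictly decreasing in ``s_in`` and vanishes at
    ``s_in = s_out``, so the balance point (if any) lies in ``[0, s_out]``
    and plain bisection is safe.  Cells whose maximal import at
    ``s_in = 0`` falls short of demand are starved and pinned at 0.
    """
    e_H, a_L, et_L, s_out_b = np.broadcast_arrays(
        np.asarray(e_H, dtype=float),
        np.asarray(a_L, dtype=float),
        np.asarray(et_L, dtype=float),
        np.asarray(s_out, dtype=float),
    )
    lo = np.zeros(e_H.shape)
    hi = s_out_b.astype(float).copy()
    starved = _total_flux(lo, s_out_b, e_H, a_L, et_L, p) < p.j_demand
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        above = _total_flux(mid, s_out_b, e_H, a_L, et_L, p) >= p.j_demand
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    return np.where(starved, 0.0, 0.5 * (lo + hi))


def quasi_steady_internal(e_H: float, a_L: float, s_out: float, p: RegulonParams) -> float:
    """Internal phosphate at which total import balances the demand.

    Starvation collapses to ``s_in = 0`` here (no explicit flag), because
    a starved cell's internal pool drains and the regulon only sees the
    resulting zero level.
    """
    if e_H < 0:
        raise ValueError("e_H must be >= 0")
    if not 0 <= a_L <= 1:
        raise ValueError("a_L must lie in [0, 1]")
    if not np.isfinite(s_out) or s_out < 0:
        raise ValueError("s_out must be finite and >= 0")
    return float(
        _quasi_steady_vec(
            np.array([e_H]), np.array([a_L]), np.array([s_out]),
            np.array([p.params_L.et]), p,
        )[0]
    )


def _hill(n, K, h):
    return n**h / (n**h + K**h)


def _algebraic(state: dict, s_out, et_L, p: RegulonParams):
    """Fast variables (a_L, s_in, n) and promoter drives from slow state."""
    with np.errstate(over="ignore"):
        a_L = 1.0 / (1.0 + (state["spl2"] / p.K_S) ** p.m)
    s_in = _quasi_steady_vec(state["e_H"], a_L, s_out, et_L, p)
    n = pho4_nuclear(s_in, p)
    n = np.asarray(n, dtype=float)
    return a_L, s_in, n, _hill(n, p.K_p, p.h), _hill(n, p.K_d_prom, p.h)


def _step(state: dict, s_out, et_L, p: RegulonParams, dt: float):
    a_L, s_in, n, g_p, g_d = _algebraic(state, s_out, et_L, p)
    new = {
        "e_H": state["e_H"] + dt * (p.alpha_H * g_p - p.delta * state["e_H"]),
        "spl2": state["spl2"] + dt * (p.alpha_S * g_p - p.delta * state["spl2"]),
        "p_plateau": state["p_plateau"]
        + dt * (p.alpha_P * g_p + p.beta_P - p.delta * state["p_plateau"]),
        "p_decoupled": state["p_decoupled"]
        + dt * (p.alpha_P * g_d + p.beta_P - p.delta * state["p_decoupled"]),
    }
    for key, value in new.items():
        if np.any(value < 0) or not np.all(np.isfinite(value)):
            raise IntegrationError(
                f"negative or non-finite {key}; use a smaller dt"
            )
    return new, (a_L, s_in, n)


_SLOW_VARS = ("e_H", "spl2", "p_plateau", "p_decoupled")


def _zero_state(n_cells: int) -> dict:
    return {k: np.zeros(n_cells) for k in _SLOW_VARS}


def _check_dt(p: RegulonParams, dt: float | None) -> float:
    if dt is None:
        dt = 0.01 / p.delta
    if dt <= 0 or dt > 0.05 / p.delta:
        raise ValueError("dt must satisfy 0 < dt <= 0.05/delta")
    return dt


def simulate(
    p: RegulonParams,
    schedule,
    init: dict | None = None,
    dt: float | None = None,
) -> CellTrajectory:
    """Integrate one cell through a sequence of ``(duration, s_out)`` steps.

    Slow variables (``e_H``, ``spl2``, both reporters) follow first-order
    synthesis/dilution kinetics driven by nuclear Pho4; ``s_in`` is
    re-equilibrated instantaneously at every step (quasi-steady fast
    variable).  Deterministic forward-Euler integration with fixed step
    ``dt`` (default ``0.01/delta``).
    """
    dt = _check_dt(p, dt)
    if not schedule:
        raise ValueError("schedule must contain at least one (duration, s_out)")
    for duration, s_out in schedule:
        if duration <= 0 or s_out < 0:
            raise ValueError("durations must be > 0 and s_out >= 0")

    state = _zero_state(1)
    if init:
        for key, value in init.items():
            if key not in _SLOW_VARS:
                raise ValueError(f"unknown init variable {key!r}")
            state[key] = np.array([float(value)])

    et_L = np.array([p.params_L.et])
    rec = {k: [] for k in ("time", "s_in", "e_H", "spl2", "a_L", "n",
                           "p_plateau", "p_decoupled")}
    t = 0.0
    for duration, s_out in schedule:
        steps = max(1, int(round(duration / dt)))
        for _ in range(steps):
            a_L, s_in, n, _, _ = _algebraic(state, s_out, et_L, p)
            rec["time"].append(t)
            rec["s_in"].append(float(s_in[0]))
            rec["a_L"].append(float(a_L[0]))
            rec["n"].append(float(n[0]))
            for key in _SLOW_VARS:
                rec[key].append(float(state[key][0]))
            state, _ = _step(state, s_out, et_L, p, dt)
            t += dt
    # terminal sample
    a_L, s_in, n, _, _ = _algebraic(state, schedule[-1][1], et_L, p)
    rec["time"].append(t)
    rec["s_in"].append(float(s_in[0]))
    rec["a_L"].append(float(a_L[0]))
    rec["n"].append(float(n[0]))
    for key in _SLOW_VARS:
        rec[key].append(float(state[key][0]))

    return CellTrajectory(params=p, **{k: np.asarray(v) for k, v in rec.items()})


# ---------------------------------------------------------------------------
# classification

#: Characteristic scales used to floor relative-drift denominators.
def _scales(p: RegulonParams) -> dict:
    return {
        "n": 1.0,
        "s_in": p.phi_plateau,
        "e_H": p.alpha_H / p.delta,
        "spl2": p.alpha_S / p.delta,
        "p_plateau": (p.alpha_P + p.beta_P) / p.delta,
        "p_decoupled": (p.alpha_P + p.beta_P) / p.delta,
    }


def _drift_ok(first, last, mean, scale, tol=0.01):
    denom = np.maximum(np.abs(mean), 0.01 * scale)
    return np.abs(last - first) / denom < tol


def _label_from_means(n, pp, pd_, p: RegulonParams):
    """Vectorised state labelling from window-averaged observables.

    Returns an object array of :class:`StateLabel` with ``None`` where the
    averages fit no definition (the caller decides whether that is an
    error or a MIXED summary).
    """
    n = np.asarray(n, float)
    pp = np.asarray(pp, float)
    pd_ = np.asarray(pd_, float)
    tol_n = 0.1 * p.n_mid
    induced = 10.0 * p.basal_reporter
    off = (n < tol_n) & (pp < induced) & (pd_ < induced)
    on = (n > 1.0 - tol_n) & (pp >= induced) & (pd_ >= induced)
    plat = (np.abs(n - p.n_mid) <= tol_n) & (pp >= induced) & (pd_ < induced)
    labels = np.full(n.shape, None, dtype=object)
    labels[off] = StateLabel.OFF
    labels[on] = StateLabel.ON
    labels[plat] = StateLabel.PLATEAU
    return labels


def classify_state(traj: CellTrajectory, window: float) -> StateLabel:
    """Label a trajectory by its time-averaged tail.

    The final ``window`` of the trajectory must be stationary (relative
    drift of every observable below 1%); a drifting tail, or averages that
    sit between the state definitions, raise :class:`NotConvergedError`
    rather than guessing.
    """
    t = traj.time
    if window <= 0 or window >= t[-1] - t[0]:
        raise ValueError("window must be positive and shorter than the trajectory")
    sel = t >= t[-1] - window
    if sel.sum() < 2:
        raise ValueError("window contains fewer than two samples")
    p = traj.params if traj.params is not None else default_params()
    scales = _scales(p)
    means = {}
    for key in ("n", "s_in", "e_H", "spl2", "p_plateau", "p_decoupled"):
        x = getattr(traj, key)[sel]
        means[key] = float(np.mean(x))
        if not _drift_ok(x[0], x[-1], means[key], scales[key]):
            raise NotConvergedError(f"{key} drifts over the final window")
    label = _label_from_means(
        np.atleast_1d(means["n"]),
        np.atleast_1d(means["p_plateau"]),
        np.atleast_1d(means["p_decoupled"]),
        p,
    )[0]
    if label is None:
        raise NotConvergedError(
            "window averages fit no state definition "
            f"(n={means['n']:.3g}, p_plateau={means['p_plateau']:.3g}, "
            f"p_decoupled={means['p_decoupled']:.3g})"
        )
    return label


# ---------------------------------------------------------------------------
# population / sweep engine (vectorised over cells)


def _advance(state, s_out, et_L, p, duration, dt):
    steps = max(1, int(round(duration / dt)))
    for _ in range(steps):
        state, _ = _step(state, s_out, et_L, p, dt)
    return state


def _window_stats(state, s_out, et_L, p, window, dt):
    """Integrate one extra window, returning means/endpoints per variable."""
    steps = max(2, int(round(window / dt)))
    sums = {k: 0.0 for k in ("n", "s_in", "e_H", "spl2", "p_plateau", "p_decoupled")}
    first = last = None
    for i in range(steps + 1):
        a_L, s_in, n, _, _ = _algebraic(state, s_out, et_L, p)
        snap = {
            "n": n, "s_in": s_in,
            **{k: state[k].copy() for k in _SLOW_VARS},
        }
        if i == 0:
            first = snap
        last = snap
        for k in sums:
            sums[k] = sums[k] + snap[k]
        if i < steps:
            state, _ = _step(state, s_out, et_L, p, dt)
    means = {k: sums[k] / (steps + 1) for k in sums}
    return state, means, first, last


def _classify_window(means, first, last, p, strict=True):
    scales = _scales(p)
    ok = np.ones(np.shape(means["n"]), dtype=bool)
    for k in means:
        ok &= _drift_ok(first[k], last[k], means[k], scales[k])
    labels = _label_from_means(means["n"], means["p_plateau"], means["p_decoupled"], p)
    if strict:
        if not ok.all():
            raise NotConvergedError("non-stationary tail during sweep")
        if any(l is None for l in labels.ravel()):
            raise NotConvergedError("ambiguous state during sweep")
    return labels, ok


def plateau_like_init(p: RegulonParams) -> dict:
    """Slow-variable levels of a settled plateau-state cell."""
    g_p = _hill(p.n_mid, p.K_p, p.h)
    g_d = _hill(p.n_mid, p.K_d_prom, p.h)
    return {
        "e_H": p.alpha_H * g_p / p.delta,
        "spl2": p.alpha_S * g_p / p.delta,
        "p_plateau": (p.alpha_P * g_p + p.beta_P) / p.delta,
        "p_decoupled": (p.alpha_P * g_d + p.beta_P) / p.delta,
    }


def _run_point(state, s_out, et_L, p, dt, duration, window):
    state = _advance(state, s_out, et_L, p, duration - window, dt)
    return _window_stats(state, s_out, et_L, p, window, dt)


def sweep(
    p: RegulonParams,
    s_out_grid=DEFAULT_SOUT_GRID,
    direction: str = "down_from_rich",
    dt: float | None = None,
    duration: float | None = None,
    window: float | None = None,
) -> pd.DataFrame:
    """State diagram along a quasi-static sweep of external phosphate.

    The grid is visited in descending order for ``down_from_rich``
    (starting from a naive, unexpressed cell at the richest point) and
    ascending for ``up_from_starved`` (the first point lies in the starved
    regime, so the cell turns fully on by itself).  The terminal state of
    each point seeds the next — path dependence is the point of the
    exercise.  Each point is run for ``duration`` (default ``10/delta``)
    plus a classification window (default ``1/delta``).
    """
    if direction not in ("down_from_rich", "up_from_starved"):
        raise ValueError("direction must be 'down_from_rich' or 'up_from_starved'")
    dt = _check_dt(p, dt)
    duration = 12.0 / p.delta if duration is None else duration
    window = 1.0 / p.delta if window is None else window
    grid = sorted(float(s) for s in s_out_grid)
    order = grid[::-1] if direction == "down_from_rich" else grid

    state = _zero_state(1)
    et_L = np.array([p.params_L.et])
    rows = []
    for s_out in order:
        state, means, first, last = _run_point(
            state, s_out, et_L, p, dt, duration, window
        )
        labels, _ = _classify_window(means, first, last, p, strict=True)
        rows.append(
            {
                "s_out": s_out,
                "direction": direction,
                "label": labels[0].value,
                "n": float(means["n"][0]),
                "s_in": float(means["s_in"][0]),
                "p_plateau": float(means["p_plateau"][0]),
                "p_decoupled": float(means["p_decoupled"][0]),
            }
        )
    return pd.DataFrame(rows)


def bistable_window(
    p: RegulonParams,
    s_out_grid=DEFAULT_SOUT_GRID,
    dt: float | None = None,
) -> tuple[float, float] | None:
    """External-concentration interval where off and plateau states coexist.

    At each grid point the model is run twice, once from a naive (off-like)
    initial condition and once from a settled plateau-like one; points
    where the former stays OFF and the latter stays PLATEAU host two
    coexisting attractors.  Returns the (min, max) of qualifying grid
    points, or ``None`` if there are none.
    """
    dt = _check_dt(p, dt)
    et_L = np.full(2, p.params_L.et)
    duration, window = 12.0 / p.delta, 1.0 / p.delta
    qualifying = []
    plateau_init = plateau_like_init(p)
    for s_out in sorted(float(s) for s in s_out_grid):
        # cell 0: naive/off-like init, cell 1: settled plateau-like init
        state = {k: np.array([0.0, plateau_init[k]]) for k in _SLOW_VARS}
        _, means, first, last = _run_point(state, s_out, et_L, p, dt, duration, window)
        labels, ok = _classify_window(means, first, last, p, strict=False)
        if (
            bool(ok[0]) and labels[0] is StateLabel.OFF
            and bool(ok[1]) and labels[1] is StateLabel.PLATEAU
        ):
            qualifying.append(s_out)
    if not qualifying:
        return None
    return (min(qualifying), max(qualifying))


def _lognormal_et(rng: np.random.Generator, mean: float, cv: float, n: int):
    if cv == 0:
        return np.full(n, mean)
    sigma = np.sqrt(np.log1p(cv**2))
    # mean-preserving lognormal: E[et] = mean
    return mean * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))


def population_sweep(
    p: RegulonParams,
    s_out_grid=DEFAULT_SOUT_GRID,
    cv_etL: float = 0.3,
    n_cells: int = 200,
    seed: int = 0,
    dt: float | None = None,
) -> pd.DataFrame:
    """Fraction of activated cells along a downward sweep.

    Cell-to-cell variability enters only through the low-affinity
    transporter amount, drawn per cell from a mean-preserving lognormal
    with coefficient of variation ``cv_etL``.  All cells are swept down
    from the richest grid point together; a cell counts as activated when
    its tail-window averages are not OFF (commitment makes the fraction
    monotone non-increasing in ``s_out``).  Rows are returned in ascending
    grid order.
    """
    if cv_etL < 0:
        raise ValueError("cv_etL must be >= 0")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    dt = _check_dt(p, dt)
    rng = np.random.default_rng(seed)
    et_L = _lognormal_et(rng, p.params_L.et, cv_etL, n_cells)
    duration, window = 12.0 / p.delta, 1.0 / p.delta

    state = _zero_state(n_cells)
    rows = []
    for s_out in sorted(float(s) for s in s_out_grid)[::-1]:
        state, means, first, last = _run_point(
            state, s_out, et_L, p, dt, duration, window
        )
        tol_n = 0.1 * p.n_mid
        induced = 10.0 * p.basal_reporter
        off = (
            (means["n"] < tol_n)
            & (means["p_plateau"] < induced)
            & (means["p_decoupled"] < induced)
        )
        rows.append({"s_out": s_out, "fraction_activated": float(np.mean(~off))})
    return pd.DataFrame(rows[::-1])
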