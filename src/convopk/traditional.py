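"""Traditional compartmental absorption models used as comparators.

Three structural models historically used for absorption-rate-limited
paliperidone kinetics, implemented here as reference comparators for the
convolution-based model:

* oral extended release (ER): two-compartment disposition with consecutive
  zero-order then first-order absorption and a lag time;
* once-monthly depot (PP1M): one-compartment disposition with a fraction of
  the dose absorbed by a zero-order process and the remainder first-order,
  in parallel;
* three-monthly depot (PP3M): one-compartment disposition with two parallel
  saturable input processes (one fast, one slow), each parameterized as a
  Hill function of time with the slow process' Hill coefficient > 1.

These models are described in the source literature only structurally (their
published estimates are not reproduced here); the parameterizations below
are canonical realizations of those descriptions, with defaults chosen to
produce realistic profile shapes for testing the comparison machinery.
Units follow :mod:`convopk.convolve` (mg, L, L/h, ng/mL).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numpy.typing import ArrayLike
from scipy.integrate import solve_ivp

from .convolve import MG_PER_L_TO_NG_PER_ML, ConcentrationProfile, DoseEvent, _normalize_doses

__all__ = [
    "ERTraditionalParams",
    "PP1MTraditionalParams",
    "PP3MTraditionalParams",
    "simulate_er_traditional",
    "simulate_pp1m_traditional",
    "simulate_pp3m_traditional",
]

_EPS_H = 1e-6  # same dose-instant convention as the convolution engine


@dataclass(frozen=True)
class ERTraditionalParams:
    """Two-compartment model with consecutive zero-/first-order input and lag."""

    CL: float
    V1: float
    Q: float
    V2: float
    Tlag: float = 0.0
    D1: float = 1.0  # zero-order input duration, h
    ka: float = 0.5  # first-order absorption rate, 1/h
    Frz: float = 0.5  # fraction absorbed via the zero-order phase

    def __post_init__(self) -> None:
        for name in ("CL", "V1", "V2", "ka"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.Q < 0:
            raise ValueError(f"Q must be >= 0, got {self.Q}")
        if self.Tlag < 0:
            raise ValueError(f"Tlag must be >= 0, got {self.Tlag}")
        if not 0.0 <= self.Frz <= 1.0:
            raise ValueError(f"Frz must lie in [0, 1], got {self.Frz}")
        if self.Frz > 0 and self.D1 <= 0:
            raise ValueError("D1 must be > 0 when Frz > 0 (zero-order phase active)")
        if self.D1 < 0:
            raise ValueError(f"D1 must be >= 0, got {self.D1}")


@dataclass(frozen=True)
class PP1MTraditionalParams:
    """One-compartment model with parallel zero- and first-order input."""

    CL: float
    V: float
    Frz: float = 0.3  # fraction via the zero-order path
    D1: float = 240.0  # zero-order duration, h
    ka: float = 0.005  # first-order absorption rate, 1/h

    def __post_init__(self) -> None:
        for name in ("CL", "V", "ka"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.Frz <= 1.0:
            raise ValueError(f"Frz must lie in [0, 1], got {self.Frz}")
        if self.Frz > 0 and self.D1 <= 0:
            raise ValueError("D1 must be > 0 when Frz > 0")


@dataclass(frozen=True)
class PP3MTraditionalParams:
    """One-compartment model, dual parallel saturable (Hill-in-time) input.

    The cumulative input of each depot follows t**g / (T50**g + t**g) scaled
    by its dose fraction; the slow process requires a Hill coefficient > 1,
    which produces its characteristic sigmoidal onset.
    """

    CL: float
    V: float
    F_fast: float = 0.3  # fraction of dose through the fast depot
    T50_fast: float = 100.0  # time to 50% of the fast-depot input, h
    gamma_fast: float = 1.0
    T50_slow: float = 900.0
    gamma_slow: float = 2.2

    def __post_init__(self) -> None:
        for name in ("CL", "V", "T50_fast", "T50_slow"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.gamma_fast <= 0 or self.gamma_slow <= 0:
            raise ValueError("Hill coefficients must be > 0")
        if self.gamma_slow <= 1:
            raise ValueError("the slow process requires gamma_slow > 1")
        if not 0.0 <= self.F_fast <= 1.0:
            raise ValueError(f"F_fast must lie in [0, 1], got {self.F_fast}")
        if self.T50_slow <= self.T50_fast:
            raise ValueError("T50_slow must exceed T50_fast")


def _integrate_events(
    rhs: Callable[[float, np.ndarray], list[float]],
    n_state: int,
    breakpoints: Sequence[float],
    jumps: dict[float, np.ndarray],
    grid: np.ndarray,
    rtol: float,
    atol: float,
    t_scale: float = np.inf,
) -> np.ndarray:
    """Piecewise LSODA integration with state jumps at event times.

    ``t_scale`` (h) is the fastest input time scale; it bounds the first
    step of each segment so short input phases are never stepped over.
    Returns the state trajectory sampled on ``grid`` (rows = states).
    """
    y = np.zeros(n_state)
    out = np.full((n_state, grid.size), np.nan)
    t_now = 0.0
    if 0.0 in jumps:
        y = y + jumps[0.0]
    bps = sorted(set(float(b) for b in breakpoints if 0.0 < b <= grid[-1]) | {float(grid[-1])})
    for tb in bps:
        mask = (grid > t_now) & (grid <= tb)
        t_eval = grid[mask]
        # always evaluate the segment endpoint so the handoff state is at tb
        sol = solve_ivp(
            rhs, (t_now, tb), y, method="LSODA",
            t_eval=np.append(t_eval, tb) if (not t_eval.size or t_eval[-1] < tb) else t_eval,
            first_step=max(min(t_scale / 50.0, (tb - t_now) / 2.0), 1e-12),
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed on [{t_now}, {tb}] h: {sol.message}")
        if t_eval.size:
            out[:, mask] = sol.y[:, : t_eval.size]
        y = sol.y[:, -1].copy()
        t_now = tb
        if tb in jumps:
            y = y + jumps[tb]
    out[:, np.isnan(out[0]) & (grid <= 0.0)] = 0.0
    return out


def _check_grid(grid: ArrayLike) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0) or grid[0] < 0:
        raise ValueError("grid must be strictly increasing with t >= 0")
    return grid


def simulate_er_traditional(
    doses: DoseEvent | Sequence[DoseEvent],
    p: ERTraditionalParams,
    grid: ArrayLike,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ConcentrationProfile:
    """ER comparator: lagged zero-order infusion then first-order depot, 2-cpt."""
    doses = _normalize_doses(doses)
    grid = _check_grid(grid)
    k10 = p.CL / p.V1
    k12 = p.Q / p.V1
    k21 = (p.Q / p.V2) if p.V2 else 0.0

    # per-dose zero-order windows and depot-load events
    windows = []  # (t_on, t_off, rate mg/h)
    jumps: dict[float, np.ndarray] = {}
    breakpoints: set[float] = set()
    for e in doses:
        t_on = e.time + p.Tlag
        t_off = t_on + p.D1
        if p.Frz > 0:
            windows.append((t_on, t_off, p.Frz * e.F * e.amount / p.D1))
            breakpoints.update((t_on, t_off))
        load = (1.0 - p.Frz) * e.F * e.amount
        if load > 0:
            t_load = t_off if p.Frz > 0 else t_on
            jumps.setdefault(t_load, np.zeros(3))
            jumps[t_load][0] += load
            breakpoints.add(t_load)

    def rhs(t: float, y: np.ndarray) -> list[float]:
        zo = sum(r for (a, b, r) in windows if a <= t < b)
        depot, central, periph = y
        return [
            -p.ka * depot,
            zo + p.ka * depot - (k10 + k12) * central + k21 * periph,
            k12 * central - k21 * periph,
        ]

    traj = _integrate_events(rhs, 3, sorted(breakpoints), jumps, grid, rtol, atol,
                         t_scale=min(p.D1 if p.Frz > 0 else np.inf, 1.0 / p.ka))
    conc = traj[1] / p.V1 * MG_PER_L_TO_NG_PER_ML
    return ConcentrationProfile(grid, conc, {"model": "er-traditional"})


def simulate_pp1m_traditional(
    doses: DoseEvent | Sequence[DoseEvent],
    p: PP1MTraditionalParams,
    grid: ArrayLike,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ConcentrationProfile:
    """Monthly-depot comparator: parallel zero-/first-order input, 1-cpt."""
    doses = _normalize_doses(doses)
    grid = _check_grid(grid)
    kel = p.CL / p.V

    windows = []
    jumps: dict[float, np.ndarray] = {}
    breakpoints: set[float] = set()
    for e in doses:
        if p.Frz > 0:
            windows.append((e.time, e.time + p.D1, p.Frz * e.F * e.amount / p.D1))
            breakpoints.update((e.time, e.time + p.D1))
        load = (1.0 - p.Frz) * e.F * e.amount
        if load > 0:
            jumps.setdefault(e.time, np.zeros(2))
            jumps[e.time][0] += load
            breakpoints.add(e.time)

    def rhs(t: float, y: np.ndarray) -> list[float]:
        zo = sum(r for (a, b, r) in windows if a <= t < b)
        depot, central = y
        return [-p.ka * depot, zo + p.ka * depot - kel * central]

    traj = _integrate_events(rhs, 2, sorted(breakpoints), jumps, grid, rtol, atol,
                         t_scale=min(p.D1 if p.Frz > 0 else np.inf, 1.0 / p.ka))
    conc = traj[1] / p.V * MG_PER_L_TO_NG_PER_ML
    return ConcentrationProfile(grid, conc, {"model": "pp1m-traditional"})


def _hill_cum(t: np.ndarray | float, t50: float, g: float) -> np.ndarray | float:
    t = np.maximum(np.asarray(t, dtype=float), 0.0)
    with np.errstate(divide="ignore"):
        x = (t / t50) ** g
    return x / (1.0 + x)


def _hill_rate(t: float, t50: float, g: float) -> float:
    # d/dt of t^g/(T50^g + t^g); diverges at 0 when g < 1 (handled by caller)
    if t <= 0:
        return 0.0 if g > 1 else (1.0 / t50 if g == 1 else np.inf)
    x = (t / t50) ** g
    return (g / t) * x / (1.0 + x) ** 2


def simulate_pp3m_traditional(
    doses: DoseEvent | Sequence[DoseEvent],
    p: PP3MTraditionalParams,
    grid: ArrayLike,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ConcentrationProfile:
    """Three-monthly depot comparator: dual Hill-in-time saturable input, 1-cpt."""
    doses = _normalize_doses(doses)
    grid = _check_grid(grid)
    kel = p.CL / p.V

    # mass entering within [0, eps) of each dose handled as a jump, as in the
    # convolution engine, so a fast-process gamma < 1 stays integrable
    h_eps = p.F_fast * _hill_cum(_EPS_H, p.T50_fast, p.gamma_fast) + (
        1.0 - p.F_fast
    ) * _hill_cum(_EPS_H, p.T50_slow, p.gamma_slow)
    jumps: dict[float, np.ndarray] = {}
    breakpoints: set[float] = set()
    for e in doses:
        jumps.setdefault(e.time, np.zeros(1))
        jumps[e.time][0] += e.F * e.amount * h_eps
        breakpoints.add(e.time)

    def rhs(t: float, y: np.ndarray) -> list[float]:
        inp = 0.0
        for e in doses:
            el = t - e.time
            if el >= _EPS_H:
                inp += e.F * e.amount * (
                    p.F_fast * _hill_rate(el, p.T50_fast, p.gamma_fast)
                    + (1.0 - p.F_fast) * _hill_rate(el, p.T50_slow, p.gamma_slow)
                )
        return [inp - kel * y[0]]

    traj = _integrate_events(rhs, 1, sorted(breakpoints), jumps, grid, rtol, atol,
                         t_scale=p.T50_fast)
    conc = traj[0] / p.V * MG_PER_L_TO_NG_PER_ML
    return ConcentrationProfile(grid, conc, {"model": "pp3m-traditional"})
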