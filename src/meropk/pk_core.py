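"""Structural pharmacokinetic model of meropenem with a lung (ELF) compartment.

The model is a mamillary three-compartment linear system: a central plasma
compartment with zero-order infusion input and first-order clearance, one
non-observed peripheral compartment, and the epithelial lining fluid (ELF)
treated as a homogeneous compartment of volume ``V_ELF`` exchanging with
central only.  Amounts (mg) obey

    dA1/dt = R(t) - (CL/V + K12 + K13) A1 + K21 A2 + K31 A3
    dA2/dt = K12 A1 - K21 A2
    dA3/dt = K13 A1 - K31 A3

with ``c_plasma = A1/V`` and ``c_elf = A3/V_ELF``.  ``R(t)`` is the
piecewise-constant infusion rate implied by the dosing schedule.

Profiles are solved exactly per constant-rate segment via the eigen
decomposition of the (time-invariant) system matrix, vectorized over
parameter vectors so that Monte Carlo populations are solved in one pass.
A numerically integrated route (`solve_profile_numeric`) is provided as an
independent cross-check and as a fallback for near-degenerate eigensystems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import InputError, InvalidParameterError, UndefinedRatioError

PARAM_NAMES = ("CL", "V", "K12", "K21", "K13", "K31", "V_ELF")

#: condition-number ceiling for the eigenvector matrix before the
#: eigen route is abandoned for numeric integration
_EIG_COND_MAX = 1e10


@dataclass(frozen=True)
class StructuralParams:
    """One subject's structural parameter vector.

    CL : clearance from central, L/h
    V : central volume, L
    K12, K21, K13, K31 : first-order intercompartmental rate constants, 1/h
    V_ELF : ELF compartment volume, L
    """

    CL: float
    V: float
    K12: float
    K21: float
    K13: float
    K31: float
    V_ELF: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(
                    f"{name} must be strictly positive and finite, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "StructuralParams":
        return cls(*(float(x) for x in theta))


@dataclass(frozen=True)
class InfusionSchedule:
    """Ordered zero-order infusion events.

    events : list of (start_time h, duration h, amount mg); overlapping
        events are permitted (rates add).
    horizon : total simulated time, h.
    """

    events: tuple[tuple[float, float, float], ...]
    horizon: float

    def __init__(self, events, horizon: float):
        events = tuple((float(s), float(d), float(a)) for s, d, a in events)
        for start, duration, amount in events:
            if duration <= 0:
                raise InputError(f"infusion duration must be > 0, got {duration}")
            if amount < 0:
                raise InputError(f"infusion amount must be >= 0, got {amount}")
            if start < 0:
                raise InputError(f"infusion start must be >= 0, got {start}")
        starts = [e[0] for e in events]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise InputError("events must be sorted by start time")
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "horizon", float(horizon))

    def breakpoints(self) -> np.ndarray:
        """Times at which the total infusion rate may change."""
        pts = {0.0, self.horizon}
        for start, duration, _ in self.events:
            pts.add(start)
            pts.add(start + duration)
        return np.array(sorted(t for t in pts if 0.0 <= t <= self.horizon))

    def total_dose(self, until: float | None = None) -> float:
        """Cumulative amount infused by time ``until`` (default: horizon)."""
        t = self.horizon if until is None else float(until)
        dose = 0.0
        for start, duration, amount in self.events:
            frac = np.clip((t - start) / duration, 0.0, 1.0)
            dose += amount * frac
        return dose

    def scaled(self, factor: float) -> "InfusionSchedule":
        """Same schedule with every amount multiplied by ``factor``."""
        return InfusionSchedule(
            [(s, d, a * factor) for s, d, a in self.events], self.horizon
        )


@dataclass(frozen=True)
class ConcentrationProfile:
    """Plasma and ELF concentration-time trajectories for one subject."""

    times: np.ndarray
    c_plasma: np.ndarray
    c_elf: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        cp = np.asarray(self.c_plasma, dtype=float)
        ce = np.asarray(self.c_elf, dtype=float)
        if not (len(t) == len(cp) == len(ce)):
            raise InputError("times, c_plasma and c_elf must have equal length")
        if np.any(np.diff(t) <= 0):
            raise InputError("time grid must be strictly increasing")
        if np.any(cp < 0) or np.any(ce < 0):
            raise InputError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "c_plasma", cp)
        object.__setattr__(self, "c_elf", ce)


def infusion_rate(schedule: InfusionSchedule, t: float) -> float:
    """Total zero-order input rate (mg/h) at time ``t``.

    Each event contributes amount/duration on [start, start+duration).
    """
    if t < 0:
        raise InputError(f"time must be >= 0, got {t}")
    rate = 0.0
    for start, duration, amount in schedule.events:
        if start <= t < start + duration:
            rate += amount / duration
    return rate


def default_grid(horizon: float, step: float = 0.1) -> np.ndarray:
    """Regular simulation grid from 0 to ``horizon`` (default step 0.1 h)."""
    n = int(round(horizon / step))
    return np.linspace(0.0, n * step, n + 1)


def _system_matrices(theta: np.ndarray) -> np.ndarray:
    """Stacked 3x3 system matrices for parameter matrix ``theta`` (n, 7)."""
    CL, V, K12, K21, K13, K31, _ = theta.T
    ke = CL / V
    n = theta.shape[0]
    A = np.zeros((n, 3, 3))
    A[:, 0, 0] = -(ke + K12 + K13)
    A[:, 0, 1] = K21
    A[:, 0, 2] = K31
    A[:, 1, 0] = K12
    A[:, 1, 1] = -K21
    A[:, 2, 0] = K13
    A[:, 2, 2] = -K31
    return A


def _validate_grid(grid: np.ndarray, horizon: float) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise InputError("grid must be a non-empty 1-D array")
    if np.any(np.diff(grid) <= 0):
        raise InputError("grid must be strictly increasing")
    if grid[0] < 0 or grid[-1] > horizon + 1e-9:
        raise InputError("grid must lie within [0, horizon]")
    return grid


def _segment_rates(schedule: InfusionSchedule, times: np.ndarray) -> np.ndarray:
    """Constant rate on each interval [times[i], times[i+1])."""
    mids = 0.5 * (times[:-1] + times[1:])
    return np.array([infusion_rate(schedule, m) for m in mids])


def solve_amounts(
    theta: np.ndarray, schedule: InfusionSchedule, grid: np.ndarray
) -> np.ndarray:
    """Compartment amounts (mg) for a batch of parameter vectors.

    Parameters
    ----------
    theta : (n_subjects, 7) array ordered as PARAM_NAMES.
    schedule : shared dosing schedule.
    grid : strictly increasing output times within [0, horizon].

    Returns
    -------
    (n_subjects, len(grid), 3) array of compartment amounts.

    The state is propagated exactly across each constant-rate interval using
    the eigen decomposition of the system matrix; subjects whose eigenvector
    matrix is ill-conditioned (nearly defective system) are recomputed by
    adaptive numeric integration.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[1] != len(PARAM_NAMES):
        raise InputError(f"theta must have {len(PARAM_NAMES)} columns")
    if np.any(~np.isfinite(theta)) or np.any(theta <= 0):
        raise InvalidParameterError("all parameters must be positive and finite")
    grid = _validate_grid(grid, schedule.horizon)

    merged = np.union1d(grid, schedule.breakpoints())
    merged = merged[(merged >= 0) & (merged <= max(grid[-1], 0.0) + 1e-12)]
    if merged[0] > 0:
        merged = np.concatenate([[0.0], merged])
    rates = _segment_rates(schedule, merged)

    # drop interior breakpoints that neither change the rate nor belong to
    # the output grid (back-to-back infusions collapse to one segment)
    in_grid = np.isin(merged, grid)
    needed = np.ones(len(merged), dtype=bool)
    needed[1:-1] = in_grid[1:-1] | (rates[1:] != rates[:-1])
    merged = merged[needed]
    rates = _segment_rates(schedule, merged)

    A = _system_matrices(theta)
    lam, P = np.linalg.eig(A)
    cond = np.linalg.cond(P)
    ok = np.isfinite(cond) & (cond < _EIG_COND_MAX)

    n, m = theta.shape[0], len(merged)
    out = np.zeros((n, m, 3))
    if np.any(ok):
        out[ok] = _propagate_eigen(lam[ok], P[ok], merged, rates)
    for i in np.where(~ok)[0]:
        out[i] = _amounts_numeric(theta[i], schedule, merged)

    idx = np.searchsorted(merged, grid)
    return out[:, idx, :]


def _propagate_eigen(
    lam: np.ndarray, P: np.ndarray, times: np.ndarray, rates: np.ndarray
) -> np.ndarray:
    """Exact piecewise propagation a(t+dt) = P e^{L dt} P^-1 a + R * int_0^dt e^{As} ds e1."""
    Pinv = np.linalg.inv(P)
    pinv_e1 = Pinv[:, :, 0]  # P^-1 b with b = e1, per unit rate
    n = lam.shape[0]
    a = np.zeros((n, 3), dtype=complex)
    out = np.zeros((n, len(times), 3))
    out[:, 0, :] = 0.0
    for i in range(len(times) - 1):
        dt = times[i + 1] - times[i]
        e = np.exp(lam * dt)
        # phi = (e^{lam dt} - 1)/lam, with the lam->0 limit dt
        small = np.abs(lam) * dt < 1e-12
        phi = np.where(small, dt, (e - 1.0) / np.where(small, 1.0, lam))
        inner = np.einsum("nij,nj->ni", Pinv, a)
        a = np.einsum("nij,nj->ni", P, e * inner + rates[i] * phi * pinv_e1)
        out[:, i + 1, :] = a.real
    return out


def _amounts_numeric(
    theta_row: np.ndarray, schedule: InfusionSchedule, times: np.ndarray
) -> np.ndarray:
    """Adaptive numeric integration of one subject on ``times`` (includes breakpoints)."""
    A = _system_matrices(theta_row[None, :])[0]
    rates = _segment_rates(schedule, times)
    out = np.zeros((len(times), 3))
    y = np.zeros(3)
    for i in range(len(times) - 1):
        r = rates[i]
        sol = solve_ivp(
            lambda t, a: A @ a + np.array([r, 0.0, 0.0]),
            (times[i], times[i + 1]),
            y,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        y = sol.y[:, -1]
        out[i + 1] = y
    return out


def _amounts_to_profile(
    theta_row: np.ndarray, grid: np.ndarray, amounts: np.ndarray
) -> ConcentrationProfile:
    V, V_ELF = theta_row[1], theta_row[6]
    cp = np.clip(amounts[:, 0] / V, 0.0, None)
    ce = np.clip(amounts[:, 2] / V_ELF, 0.0, None)
    return ConcentrationProfile(times=grid, c_plasma=cp, c_elf=ce)


def solve_profile(
    params: StructuralParams, schedule: InfusionSchedule, grid: np.ndarray
) -> ConcentrationProfile:
    """Exact plasma/ELF concentration profile for one subject."""
    theta = params.as_array()[None, :]
    amounts = solve_amounts(theta, schedule, np.asarray(grid, dtype=float))
    return _amounts_to_profile(theta[0], np.asarray(grid, dtype=float), amounts[0])


def solve_profile_numeric(
    params: StructuralParams,
    schedule: InfusionSchedule,
    grid: np.ndarray,
    rtol: float = 1e-10,
) -> ConcentrationProfile:
    """Independent numerically-integrated profile (cross-check route).

    Integrates the ODE system segment-by-segment with LSODA at tight
    tolerance; agrees with `solve_profile` to the solver tolerance.
    """
    grid = _validate_grid(np.asarray(grid, dtype=float), schedule.horizon)
    merged = np.union1d(grid, schedule.breakpoints())
    merged = merged[merged <= grid[-1] + 1e-12]
    if merged[0] > 0:
        merged = np.concatenate([[0.0], merged])
    theta = params.as_array()
    A = _system_matrices(theta[None, :])[0]
    rates = _segment_rates(schedule, merged)
    ys = np.zeros((len(merged), 3))
    y = np.zeros(3)
    for i in range(len(merged) - 1):
        r = rates[i]
        sol = solve_ivp(
            lambda t, a: A @ a + np.array([r, 0.0, 0.0]),
            (merged[i], merged[i + 1]),
            y,
            method="LSODA",
            rtol=rtol,
            atol=1e-12,
        )
        y = sol.y[:, -1]
        ys[i + 1] = y
    idx = np.searchsorted(merged, grid)
    return _amounts_to_profile(theta, grid, ys[idx])


def terminal_half_life(theta: np.ndarray) -> np.ndarray:
    """Terminal (slowest-eigenvalue) half-life, h, for parameter vectors.

    ln(2) divided by the smallest eigenvalue magnitude of the disposition
    matrix; a plausibility metric for fitted parameter combinations.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    A = _system_matrices(theta)
    lam = np.linalg.eigvals(A)
    slowest = np.min(np.abs(lam.real), axis=1)
    return np.log(2.0) / np.maximum(slowest, 1e-12)


def steady_state(params: StructuralParams, rate: float) -> tuple[float, float]:
    """Steady-state plasma and ELF concentrations under a constant infusion.

    css_plasma = rate/CL; at steady state the ELF balance K13*A1 = K31*A3
    gives css_elf = css_plasma * (V*K13)/(K31*V_ELF).
    """
    if rate < 0:
        raise InputError(f"rate must be >= 0, got {rate}")
    css_p = rate / params.CL
    css_e = css_p * (params.V * params.K13) / (params.K31 * params.V_ELF)
    return css_p, css_e


def auc_trapezoid(values: np.ndarray, times: np.ndarray) -> float:
    """Linear trapezoidal AUC (mg.h/L) of ``values`` over ``times``."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.shape[-1] != times.shape[0]:
        raise InputError("values and times must have matching lengths")
    if np.any(np.diff(times) <= 0):
        raise InputError("times must be strictly increasing")
    return np.trapezoid(values, times, axis=-1)


def daily_average_auc(cumulative_auc: float, total_time: float) -> float:
    """Normalize a cumulative AUC to a daily (24 h) average exposure."""
    if total_time <= 0:
        raise InputError(f"total_time must be > 0, got {total_time}")
    return cumulative_auc / total_time * 24.0


def penetration_ratio(auc_elf: float, auc_plasma: float) -> float:
    """Lung penetration, percent: 100 * AUC_ELF / AUC_plasma."""
    if np.any(np.asarray(auc_plasma) <= 0):
        raise UndefinedRatioError("plasma AUC must be > 0")
    return 100.0 * auc_elf / auc_plasma


def steady_state_penetration(params: StructuralParams) -> float:
    """Model-implied steady-state ELF/plasma ratio, percent: 100*(V*K13)/(K31*V_ELF)."""
    return 100.0 * (params.V * params.K13) / (params.K31 * params.V_ELF)
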