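"""Population and individual parameter estimation with fit diagnostics.

The population distribution of the structural parameters is estimated
nonparametrically as a discrete mixture of weighted support points that
maximizes the exact mixture likelihood

    sum_j log sum_k w_k L(subject_j | theta_k),

the estimator family of the nonparametric adaptive grid (NPAG) approach.
`npag_fit` is a simplified NPAG: support candidates are initialized by
low-discrepancy (Sobol) sampling of the search box, mixture weights are
optimized by EM (monotone in the likelihood), the grid is adaptively refined
by perturbing high-weight points and dropping negligible ones, and dominant
points are polished by direct local search.  Residual unexplained noise is
captured by ``gamma``, a multiplicative inflation of the assay SD, profiled
by golden-section search.

Observations are weighted by the inverse of the estimated assay variance:
each observation's SD is ``gamma * sd_assay(prediction)`` with a linear
assay-SD polynomial per analyte.

Diagnostics follow standard pharmacometric practice: mean prediction error
(bias), bias-adjusted mean squared prediction error (imprecision),
observed-vs-predicted regression, visual predictive checks (VPC), and
normalized prediction distribution errors (NPDE).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, ndtri
from scipy.stats import linregress

from .exceptions import InputError, NumericalUnderflowError
from . import pk_core
from .pk_core import PARAM_NAMES, InfusionSchedule, StructuralParams
from .datasets import load_reference_parameters

Analyte = Literal["plasma", "elf"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class Observation:
    """One measured concentration."""

    subject: str
    time: float
    analyte: Analyte
    value: float
    bloq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0 or self.value < 0:
            raise InputError("observation time and value must be >= 0")


@dataclass(frozen=True)
class ErrorModel:
    """Residual error: per-analyte linear assay-SD polynomial and gamma.

    sd(analyte, c) = (c0 + c1 * c); the observation SD used in the
    likelihood is gamma * sd(analyte, prediction).  Defaults anchor the
    intercept at LOQ/2 and the proportional term at the reported 15%
    assay precision bound.
    """

    assay_sd: dict = field(
        default_factory=lambda: {"plasma": (0.25, 0.15), "elf": (0.015, 0.15)}
    )
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 1.0:
            raise InputError("gamma must be >= 1 at initialization")
        for analyte, (c0, c1) in self.assay_sd.items():
            if c0 <= 0 or c1 < 0:
                raise InputError(f"assay SD polynomial for {analyte!r} must be positive")

    def sd(self, analyte: str, c: np.ndarray) -> np.ndarray:
        c0, c1 = self.assay_sd[analyte]
        return c0 + c1 * np.asarray(c, dtype=float)


@dataclass(frozen=True)
class SubjectData:
    """One subject's dosing schedule and (non-censored) observations."""

    subject_id: str
    schedule: InfusionSchedule
    times: np.ndarray
    analytes: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.analytes, dtype=object)
        v = np.asarray(self.values, dtype=float)
        if not (len(t) == len(a) == len(v)) or len(t) == 0:
            raise InputError("times/analytes/values must be equal-length and non-empty")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "analytes", a)
        object.__setattr__(self, "values", v)

    @classmethod
    def from_observations(
        cls, subject_id: str, observations: Sequence[Observation], schedule: InfusionSchedule
    ) -> "SubjectData":
        obs = [o for o in observations if not o.bloq]
        if not obs:
            raise InputError("no quantifiable observations")
        return cls(
            subject_id,
            schedule,
            np.array([o.time for o in obs]),
            np.array([o.analyte for o in obs], dtype=object),
            np.array([o.value for o in obs]),
        )


@dataclass(frozen=True)
class PopulationModel:
    """Discrete support-point/weight mixture over structural parameters."""

    support: np.ndarray       # (K, 7), columns ordered as PARAM_NAMES
    weights: np.ndarray       # (K,), sums to 1
    loglik: float = float("nan")
    gamma: float = 1.0
    converged: bool = True
    cycle_logliks: tuple = ()

    def __post_init__(self) -> None:
        support = np.atleast_2d(np.asarray(self.support, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(support) or len(w) < 1:
            raise InputError("need >= 1 support point with matching weights")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-10:
            raise InputError("weights must be >= 0 and sum to 1")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "weights", w)

    @property
    def support_points(self) -> list[StructuralParams]:
        return [StructuralParams.from_array(row) for row in self.support]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(len(self.weights), size=n, p=self.weights)
        return self.support[idx]

    def weighted_median(self, name: str) -> float:
        """Weighted median of one parameter's marginal."""
        j = PARAM_NAMES.index(name)
        order = np.argsort(self.support[:, j])
        x, w = self.support[order, j], self.weights[order]
        cdf = np.cumsum(w)
        return float(x[np.searchsorted(cdf, 0.5)])

    def weighted_mean(self, name: str) -> float:
        j = PARAM_NAMES.index(name)
        return float(self.support[:, j] @ self.weights)

    def to_dict(self) -> dict:
        return {
            "support": self.support.tolist(),
            "weights": self.weights.tolist(),
            "loglik": self.loglik,
            "gamma": self.gamma,
            "converged": self.converged,
            "param_names": list(PARAM_NAMES),
        }


@dataclass(frozen=True)
class FitDiagnostics:
    bias: float
    imprecision: float
    intercept: float
    slope: float
    r2: float
    npde: np.ndarray | None = None


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _predict_subject(
    theta: np.ndarray, subject: SubjectData
) -> np.ndarray:
    """Predictions (K, n_obs) for a batch of parameter vectors."""
    theta = np.atleast_2d(theta)
    grid = np.unique(subject.times)
    if grid[0] > 0:
        pass  # solver integrates from 0 internally
    amounts = pk_core.solve_amounts(theta, subject.schedule, grid)
    cp = amounts[:, :, 0] / theta[:, 1:2]
    ce = amounts[:, :, 2] / theta[:, 6:7]
    idx = np.searchsorted(grid, subject.times)
    is_elf = np.array([a == "elf" for a in subject.analytes])
    pred = np.where(is_elf[None, :], ce[:, idx], cp[:, idx])
    return np.clip(pred, 0.0, None)


def _loglik_components(
    theta: np.ndarray, subject: SubjectData, error: ErrorModel
) -> tuple[np.ndarray, np.ndarray, int]:
    """Gamma-independent pieces of the Gaussian log-likelihood.

    Returns (S, Q, n) with S_k = sum_i log sd_assay_i, Q_k = sum_i
    ((obs_i - pred_i)/sd_assay_i)^2, so that
    loglik_k(gamma) = -n/2 log(2 pi) - S_k - n log(gamma) - Q_k / (2 gamma^2).
    """
    pred = _predict_subject(theta, subject)
    sd = np.empty_like(pred)
    for analyte in np.unique(subject.analytes):
        cols = subject.analytes == analyte
        sd[:, cols] = error.sd(str(analyte), pred[:, cols])
    resid = (subject.values[None, :] - pred) / sd
    return np.log(sd).sum(axis=1), (resid**2).sum(axis=1), pred.shape[1]


def _loglik_from_components(S, Q, n, gamma: float) -> np.ndarray:
    return -0.5 * n * _LOG2PI - S - n * np.log(gamma) - Q / (2.0 * gamma**2)


def subject_loglik(
    params: StructuralParams,
    observations: Sequence[Observation] | SubjectData,
    schedule: InfusionSchedule | None = None,
    error: ErrorModel | None = None,
) -> float:
    """Gaussian log-likelihood of one subject's data at one parameter vector.

    Per-observation SD is gamma * sd_assay(prediction), i.e. data are
    weighted by the inverse of the estimated assay variance.
    """
    error = error if error is not None else ErrorModel()
    if isinstance(observations, SubjectData):
        subject = observations
    else:
        if schedule is None:
            raise InputError("schedule required with a raw observation list")
        if any(o.bloq for o in observations):
            raise InputError("censored (below-LOQ) observations are not supported here")
        subject = SubjectData.from_observations("_", observations, schedule)
    S, Q, n = _loglik_components(params.as_array()[None, :], subject, error)
    return float(_loglik_from_components(S, Q, n, error.gamma)[0])


def map_estimate(
    prior: PopulationModel,
    observations: Sequence[Observation] | SubjectData,
    schedule: InfusionSchedule | None = None,
    error: ErrorModel | None = None,
) -> tuple[StructuralParams, np.ndarray]:
    """MAP-Bayesian individual estimate over a discrete population prior.

    Posterior weight of support point k is proportional to
    prior_weight_k * exp(subject log-likelihood at point k); returns the
    maximum-posterior point and the full posterior weight vector.
    """
    error = error if error is not None else ErrorModel(gamma=max(1.0, prior.gamma))
    if isinstance(observations, SubjectData):
        subject = observations
    else:
        if schedule is None:
            raise InputError("schedule required with a raw observation list")
        subject = SubjectData.from_observations("_", observations, schedule)
    S, Q, n = _loglik_components(prior.support, subject, error)
    logpost = np.log(np.clip(prior.weights, 1e-300, None)) + _loglik_from_components(
        S, Q, n, error.gamma
    )
    if not np.any(np.isfinite(logpost)):
        raise NumericalUnderflowError(
            "all posterior weights underflowed; compute in log space (log-sum-exp)"
        )
    logpost -= logsumexp(logpost)
    weights = np.exp(logpost)
    weights /= weights.sum()
    best = int(np.argmax(weights))
    return StructuralParams.from_array(prior.support[best]), weights


def default_support_bounds(sd_multiple: float = 4.0, floor: float = 1e-3) -> np.ndarray:
    """(7, 2) search box: reference mean +/- ``sd_multiple`` SD, floored at ``floor``."""
    ref = load_reference_parameters()
    lo = np.maximum(floor, ref["mean"].to_numpy() - sd_multiple * ref["sd"].to_numpy())
    hi = ref["mean"].to_numpy() + sd_multiple * ref["sd"].to_numpy()
    return np.column_stack([lo, hi])


def _em_weights(
    logL: np.ndarray, w0: np.ndarray, tol: float = 1e-8, max_iter: int = 500
) -> tuple[np.ndarray, float, list[float]]:
    """EM for mixture weights given the (J, K) log-likelihood matrix.

    Monotone in sum_j log sum_k w_k L_jk; returns (weights, loglik, trace).
    """
    w = np.clip(w0, 1e-300, None)
    w /= w.sum()
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        a = logL + np.log(np.clip(w, 1e-300, None))[None, :]
        norm = logsumexp(a, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        r = np.exp(a - norm[:, None])
        w = r.mean(axis=0)
        w = np.clip(w, 0.0, None)
        w /= w.sum()
        if ll - prev < tol and np.isfinite(ll):
            break
        prev = ll
    return w, trace[-1], trace


def _golden_section(f, lo: float, hi: float, tol: float = 1e-3) -> float:
    """Maximize a unimodal scalar function on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


class _LikelihoodTable:
    """Caches the gamma-independent likelihood pieces per (subject, point).

    Subjects sharing an `InfusionSchedule` are solved in one vectorized pass
    over a common observation-time grid; predictions are then indexed per
    subject.
    """

    def __init__(self, subjects: Sequence[SubjectData], error: ErrorModel):
        self.subjects = list(subjects)
        self.error = error
        self.n_obs = np.array([len(s.values) for s in self.subjects], dtype=float)
        # group subjects by schedule; each group shares one model solve
        self._groups: dict = {}
        for j, subj in enumerate(self.subjects):
            self._groups.setdefault(subj.schedule, []).append(j)
        self._group_grid = {
            sched: np.unique(np.concatenate([self.subjects[j].times for j in idx]))
            for sched, idx in self._groups.items()
        }
        self.S = None
        self.Q = None

    def _components(self, support: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(J, K) matrices of S and Q for a support batch."""
        support = np.atleast_2d(support)
        J, K = len(self.subjects), len(support)
        S = np.empty((J, K))
        Q = np.empty((J, K))
        for sched, idx in self._groups.items():
            grid = self._group_grid[sched]
            amounts = pk_core.solve_amounts(support, sched, grid)
            cp = np.clip(amounts[:, :, 0] / support[:, 1:2], 0.0, None)
            ce = np.clip(amounts[:, :, 2] / support[:, 6:7], 0.0, None)
            for j in idx:
                subj = self.subjects[j]
                cols = np.searchsorted(grid, subj.times)
                is_elf = np.array([a == "elf" for a in subj.analytes])
                pred = np.where(is_elf[None, :], ce[:, cols], cp[:, cols])
                sd = np.empty_like(pred)
                for analyte in np.unique(subj.analytes):
                    m = subj.analytes == analyte
                    sd[:, m] = self.error.sd(str(analyte), pred[:, m])
                resid = (subj.values[None, :] - pred) / sd
                S[j] = np.log(sd).sum(axis=1)
                Q[j] = (resid**2).sum(axis=1)
        return S, Q

    def build(self, support: np.ndarray) -> None:
        self.S, self.Q = self._components(support)

    def append(self, new_points: np.ndarray) -> None:
        S, Q = self._components(new_points)
        self.S = np.hstack([self.S, S])
        self.Q = np.hstack([self.Q, Q])

    def keep(self, idx: np.ndarray) -> None:
        self.S = self.S[:, idx]
        self.Q = self.Q[:, idx]

    def replace_column(self, k: int, point: np.ndarray) -> None:
        S, Q = self._components(point[None, :])
        self.S[:, k] = S[:, 0]
        self.Q[:, k] = Q[:, 0]

    def logL(self, gamma: float) -> np.ndarray:
        return (
            -0.5 * self.n_obs[:, None] * _LOG2PI
            - self.S
            - self.n_obs[:, None] * np.log(gamma)
            - self.Q / (2.0 * gamma**2)
        )

    def logL_column(self, point: np.ndarray, gamma: float) -> np.ndarray:
        """(J,) log-likelihood of every subject at one candidate point."""
        S, Q = self._components(point[None, :])
        return (
            -0.5 * self.n_obs * _LOG2PI
            - S[:, 0]
            - self.n_obs * np.log(gamma)
            - Q[:, 0] / (2.0 * gamma**2)
        )

    def total_loglik(self, weights: np.ndarray, gamma: float) -> float:
        a = self.logL(gamma) + np.log(np.clip(weights, 1e-300, None))[None, :]
        return float(logsumexp(a, axis=1).sum())


def npag_fit(
    subjects: Sequence[SubjectData],
    error: ErrorModel | None = None,
    bounds: np.ndarray | None = None,
    seed: int = 0,
    n_init: int = 256,
    max_cycles: int = 8,
    tol: float = 1e-4,
    weight_floor: float = 1e-6,
    optimize_gamma: bool = True,
    gamma_bounds: tuple[float, float] = (1.0, 10.0),
    polish: bool = True,
    max_terminal_half_life: float | None = 24.0,
) -> PopulationModel:
    """Simplified nonparametric adaptive-grid population fit.

    1. initialize candidate support points by scrambled-Sobol sampling of the
       log-transformed search box;
    2. optimize mixture weights for the fixed grid by EM (monotone in the
       total log-likelihood);
    3. adaptively refine: perturb high-weight points with a shrinking
       multiplicative kernel, drop points below ``weight_floor``, re-optimize;
    4. interleave a golden-section profile search for gamma and a Nelder-Mead
       polish of dominant points, accepting only likelihood improvements;
    stop when a full cycle gains less than ``tol`` in log-likelihood.

    ``max_terminal_half_life`` (h) restricts the search domain to parameter
    combinations whose slowest disposition half-life is physiologically
    plausible.  A short, nearly flat steady-state sampling window cannot
    distinguish genuine clearance from a no-elimination / huge-volume
    combination that is still accumulating; in a population with conserved
    renal function (meropenem terminal half-life 1-3 h) the default 24 h cap
    excludes only that degenerate corner of the search box.
    """
    if len(subjects) < 2:
        raise InputError("population fit requires >= 2 subjects")
    error = error if error is not None else ErrorModel()
    bounds = default_support_bounds() if bounds is None else np.asarray(bounds, float)
    if np.any(~np.isfinite(bounds)) or np.any(bounds <= 0):
        raise InputError("bounds must be finite and positive")
    log_lo, log_hi = np.log(bounds[:, 0]), np.log(bounds[:, 1])

    n_dim = len(PARAM_NAMES)
    total_obs = sum(len(s.values) for s in subjects)
    if total_obs < len(subjects) * n_dim:
        import warnings

        warnings.warn(
            "fewer observations than identifiable parameter directions; "
            "the support may be under-determined",
            stacklevel=2,
        )

    from scipy.stats import qmc

    cap = max_terminal_half_life

    def feasible(points: np.ndarray) -> np.ndarray:
        if cap is None:
            return np.ones(len(points), dtype=bool)
        return pk_core.terminal_half_life(points) <= cap

    degenerate_box = np.allclose(bounds[:, 0], bounds[:, 1])
    sobol = qmc.Sobol(d=n_dim, scramble=True, seed=seed)
    m = int(np.ceil(np.log2(max(2, n_init)))) + 2
    u = sobol.random_base2(m)
    support = np.exp(log_lo + u * (log_hi - log_lo))
    ok = feasible(support)
    support = np.vstack([support[ok][:n_init], support[~ok][: max(0, n_init - ok.sum())]])
    if degenerate_box:
        support = support[:1]

    rng = np.random.default_rng(seed + 1)
    table = _LikelihoodTable(subjects, error)
    table.build(support)

    gamma = error.gamma
    weights = np.full(len(support), 1.0 / len(support))
    weights, ll, _ = _em_weights(table.logL(gamma), weights)

    def em_and_gamma(weights, gamma, ll):
        weights, ll, _ = _em_weights(table.logL(gamma), weights)
        if optimize_gamma and gamma_bounds[1] > gamma_bounds[0]:
            g = _golden_section(lambda g_: table.total_loglik(weights, g_), *gamma_bounds)
            if table.total_loglik(weights, g) > ll:
                gamma = g
                weights, ll, _ = _em_weights(table.logL(gamma), weights)
        return weights, gamma, ll

    weights, gamma, ll = em_and_gamma(weights, gamma, ll)

    # --- subject-anchored refinement: optimize each subject's best candidate
    # against its own likelihood, then let EM re-weight the enriched grid
    if not degenerate_box:
        anchors = _subject_anchor_points(
            table, support, gamma, log_lo, log_hi, cap
        )
        if len(anchors):
            table.append(anchors)
            support = np.vstack([support, anchors])
            weights = np.concatenate(
                [weights * 0.5, np.full(len(anchors), 0.5 / len(anchors))]
            )
            weights /= weights.sum()
            weights, gamma, ll = em_and_gamma(weights, gamma, ll)

    cycle_logliks = [ll]
    best = (support.copy(), weights.copy(), gamma, ll, table.S.copy(), table.Q.copy())
    scale = 0.25
    converged = False
    for cycle in range(max_cycles):
        ll_start = ll

        # drop negligible points and merge near-duplicates
        keep = weights > weight_floor
        if keep.sum() >= 1:
            support, weights = support[keep], weights[keep] / weights[keep].sum()
            table.keep(keep)
        support, weights, merged_idx = _merge_close(support, weights)
        table.keep(merged_idx)

        # perturb high-weight points (shrinking multiplicative kernel)
        if not degenerate_box:
            heavy = np.where(weights > max(0.01, 1.0 / (4 * len(weights))))[0]
            if heavy.size:
                new_pts = np.vstack(
                    [
                        support[k] * np.exp(scale * rng.standard_normal((2, n_dim)))
                        for k in heavy
                    ]
                )
                new_pts = np.clip(new_pts, bounds[:, 0], bounds[:, 1])
                new_pts = new_pts[feasible(new_pts)]
            if heavy.size and len(new_pts):
                table.append(new_pts)
                support = np.vstack([support, new_pts])
                weights = np.concatenate(
                    [weights * 0.98, np.full(len(new_pts), 0.02 / len(new_pts))]
                )
                weights /= weights.sum()
        weights, gamma, ll = em_and_gamma(weights, gamma, ll)

        # polish dominant points against the mixture likelihood
        if polish and not degenerate_box:
            for k in np.argsort(weights)[::-1][:3]:
                if weights[k] < 0.05:
                    continue
                support, ll_new = _polish_point(
                    table, support, weights, gamma, k, bounds, cap
                )
                if ll_new > ll:
                    weights, gamma, ll = em_and_gamma(weights, gamma, ll)

        scale *= 0.5
        if ll > best[3]:
            best = (
                support.copy(), weights.copy(), gamma, ll,
                table.S.copy(), table.Q.copy(),
            )
        cycle_logliks.append(best[3])
        if abs(ll - ll_start) < tol:
            converged = True
            break

    support, weights, gamma, ll, table.S, table.Q = best
    keep = weights > weight_floor
    support, weights = support[keep], weights[keep] / weights[keep].sum()
    table.keep(keep)
    ll = table.total_loglik(weights, gamma)
    return PopulationModel(
        support=support,
        weights=weights,
        loglik=ll,
        gamma=gamma,
        converged=converged,
        cycle_logliks=tuple(cycle_logliks),
    )


def _merge_close(
    support: np.ndarray, weights: np.ndarray, rtol: float = 1e-3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coalesce support points identical to within ``rtol`` (relative, all axes).

    Returns the retained points, their pooled weights, and the retained
    column indices (for likelihood-table bookkeeping).
    """
    order = np.argsort(weights)[::-1]
    kept: list[int] = []
    pooled = weights.copy()
    for i in order:
        merged = False
        for k in kept:
            if np.all(np.abs(support[i] - support[k]) <= rtol * np.abs(support[k])):
                pooled[k] += pooled[i]
                merged = True
                break
        if not merged:
            kept.append(i)
    kept_idx = np.array(sorted(kept))
    w = pooled[kept_idx]
    return support[kept_idx], w / w.sum(), kept_idx


def _subject_anchor_points(
    table: _LikelihoodTable,
    support: np.ndarray,
    gamma: float,
    log_lo: np.ndarray,
    log_hi: np.ndarray,
    max_terminal_half_life: float | None = None,
) -> np.ndarray:
    """Per-subject candidate points: local maximization of each subject's own
    likelihood, started from that subject's best current grid point."""
    logL = table.logL(gamma)
    anchors = []
    for j, subj in enumerate(table.subjects):
        grid_best = np.log(support[int(np.argmax(logL[j]))])
        moment = _moment_start(subj, log_lo, log_hi)

        def neg(x, subj=subj):
            if np.any(x < log_lo - 1e-12) or np.any(x > log_hi + 1e-12):
                return np.inf
            point = np.exp(x)[None, :]
            if (
                max_terminal_half_life is not None
                and pk_core.terminal_half_life(point)[0] > max_terminal_half_life
            ):
                return np.inf
            S, Q, n = _loglik_components(point, subj, table.error)
            return -float(_loglik_from_components(S, Q, n, gamma)[0])

        best_res = None
        for x0 in (moment, grid_best):
            res = minimize(
                neg, x0, method="Nelder-Mead",
                options={"maxiter": 300, "xatol": 1e-3, "fatol": 1e-6},
            )
            if np.isfinite(res.fun) and (best_res is None or res.fun < best_res.fun):
                best_res = res
        if best_res is not None:
            anchors.append(np.exp(np.clip(best_res.x, log_lo, log_hi)))
    if not anchors:
        return np.empty((0, support.shape[1]))
    return np.vstack(anchors)


def _moment_start(
    subj: SubjectData, log_lo: np.ndarray, log_hi: np.ndarray
) -> np.ndarray:
    """Data-informed starting point (log scale) for a subject's local search.

    Clearance is anchored on the quasi-steady-state balance rate/CL ~= mean
    plasma level; the ELF volume is set so the model's steady-state ELF/plasma
    ratio matches the observed one; remaining parameters start at the middle
    of the search box on the natural scale (the log midpoint is distorted
    whenever the lower bound has collapsed to the positivity floor).
    """
    x0 = np.log(0.5 * (np.exp(log_lo) + np.exp(log_hi)))
    plasma = subj.values[subj.analytes == "plasma"]
    elf = subj.values[subj.analytes == "elf"]
    t_max = float(subj.times.max())
    mean_rate = subj.schedule.total_dose(t_max) / max(t_max, 1e-6)
    if plasma.size and plasma.mean() > 0 and mean_rate > 0:
        x0[0] = np.log(mean_rate / plasma.mean())
        if elf.size and elf.mean() > 0:
            # css_elf/css_plasma = V*K13/(K31*V_ELF)  ->  solve for V_ELF
            ratio = elf.mean() / plasma.mean()
            v, k13, k31 = np.exp(x0[1]), np.exp(x0[4]), np.exp(x0[5])
            x0[6] = np.log(v * k13 / (k31 * ratio))
    return np.clip(x0, log_lo, log_hi)


def _polish_point(table, support, weights, gamma, k, bounds, max_terminal_half_life=None):
    """Nelder-Mead refinement of support point ``k`` in log space."""
    log_lo, log_hi = np.log(bounds[:, 0]), np.log(bounds[:, 1])
    logw = np.log(np.clip(weights, 1e-300, None))

    base_logL = table.logL(gamma)

    def neg_obj(x):
        if np.any(x < log_lo) or np.any(x > log_hi):
            return np.inf
        point = np.exp(x)
        if (
            max_terminal_half_life is not None
            and pk_core.terminal_half_life(point[None, :])[0] > max_terminal_half_life
        ):
            return np.inf
        logL = base_logL.copy()
        logL[:, k] = table.logL_column(point, gamma)
        return -float(logsumexp(logL + logw[None, :], axis=1).sum())

    x0 = np.log(support[k])
    res = minimize(neg_obj, x0, method="Nelder-Mead", options={"maxiter": 200, "xatol": 1e-3, "fatol": 1e-6})
    ll_old = -neg_obj(x0)
    if -res.fun > ll_old:
        support = support.copy()
        support[k] = np.exp(res.x)
        table.replace_column(k, support[k])
        return support, -res.fun
    return support, ll_old


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def bias_imprecision(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """Mean prediction error and bias-adjusted mean squared prediction error.

    bias = mean(pred - obs), mg/L; imprecision = mean((pred - obs)^2) - bias^2,
    mg^2/L^2.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise InputError("observed and predicted must be non-empty and equal-length")
    e = pred - obs
    bias = float(e.mean())
    return bias, float((e**2).mean() - bias**2)


def obs_pred_regression(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float, float]:
    """OLS of observed on predicted: (intercept, slope, R^2)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 3 or obs.shape != pred.shape:
        raise InputError("need >= 3 observed/predicted pairs")
    if np.ptp(pred) == 0:
        raise InputError("predicted values have zero variance; regression is degenerate")
    fit = linregress(pred, obs)
    return float(fit.intercept), float(fit.slope), float(fit.rvalue**2)


@dataclass(frozen=True)
class VpcBands:
    """Simulated 5th/50th/95th percentile bands on a time grid."""

    times: np.ndarray
    p5: np.ndarray
    p50: np.ndarray
    p95: np.ndarray
    site: str = "plasma"

    def coverage(self, times_obs: np.ndarray, values_obs: np.ndarray) -> float:
        """Fraction of observations inside the 5th-95th band."""
        lo = np.interp(times_obs, self.times, self.p5)
        hi = np.interp(times_obs, self.times, self.p95)
        v = np.asarray(values_obs, dtype=float)
        return float(np.mean((v >= lo) & (v <= hi)))


def _simulate_concentrations(
    model: PopulationModel,
    schedule: InfusionSchedule,
    grid: np.ndarray,
    n_sim: int,
    rng: np.random.Generator,
    site: str,
    error: ErrorModel | None,
) -> np.ndarray:
    theta = model.sample(n_sim, rng)
    amounts = pk_core.solve_amounts(theta, schedule, grid)
    col, vol = (0, 1) if site == "plasma" else (2, 6)
    conc = np.clip(amounts[:, :, col] / theta[:, vol : vol + 1], 0.0, None)
    if error is not None:
        sd = model.gamma * error.sd(site, conc)
        conc = np.clip(conc + sd * rng.standard_normal(conc.shape), 0.0, None)
    return conc


def vpc(
    model: PopulationModel,
    schedule: InfusionSchedule,
    grid: np.ndarray,
    n_sim: int = 1000,
    seed: int = 0,
    site: str = "plasma",
    error: ErrorModel | None = None,
) -> VpcBands:
    """Visual-predictive-check percentile bands (5th, 50th, 95th).

    Simulates ``n_sim`` subjects from the population model (optionally with
    residual assay noise) and returns per-time percentiles.  For a
    well-specified model about 90% of observations should fall inside the
    5th-95th band.
    """
    if n_sim < 100:
        raise InputError("vpc requires n_sim >= 100")
    rng = np.random.default_rng(seed)
    grid = np.asarray(grid, dtype=float)
    conc = _simulate_concentrations(model, schedule, grid, n_sim, rng, site, error)
    p5, p50, p95 = np.percentile(conc, [5, 50, 95], axis=0)
    return VpcBands(grid, p5, p50, p95, site)


def npde(
    model: PopulationModel,
    subjects: Sequence[SubjectData],
    n_sim: int = 1000,
    seed: int = 0,
    error: ErrorModel | None = None,
) -> np.ndarray:
    """Normalized prediction distribution errors, one per observation.

    Each observation is ranked among ``n_sim`` model-simulated replicates of
    itself; the uniform score (rank + 0.5) / (n_sim + 1) is mapped through the
    standard-normal quantile function.  Under a correct model the NPDE sample
    is approximately N(0, 1).  The decorrelation step of the reference method
    is deliberately omitted (weakly identifiable with a single ELF observation
    per subject); values at the rank extremes stay finite by construction.
    """
    if n_sim < 500:
        raise InputError("npde requires n_sim >= 500")
    error = error if error is not None else ErrorModel()
    rng = np.random.default_rng(seed)
    out = []
    for subj in subjects:
        theta = model.sample(n_sim, rng)
        pred = _predict_subject(theta, subj)  # (n_sim, n_obs)
        sd = np.empty_like(pred)
        for analyte in np.unique(subj.analytes):
            cols = subj.analytes == analyte
            sd[:, cols] = model.gamma * error.sd(str(analyte), pred[:, cols])
        sims = pred + sd * rng.standard_normal(pred.shape)
        rank = (sims < subj.values[None, :]).sum(axis=0)
        pde = (rank + 0.5) / (n_sim + 1.0)
        out.append(ndtri(pde))
    return np.concatenate(out)


def population_predictions(
    model: PopulationModel, subjects: Sequence[SubjectData], mode: str = "map"
) -> pd.DataFrame:
    """Observed vs predicted table for diagnostics.

    mode "map": individual MAP-Bayesian (posterior-mode point) predictions;
    mode "population": posterior-weighted mean predictions.
    """
    rows = []
    for subj in subjects:
        _, post = map_estimate(model, subj)
        preds = _predict_subject(model.support, subj)
        if mode == "map":
            pred = preds[int(np.argmax(post))]
        elif mode == "population":
            pred = post @ preds
        else:
            raise InputError("mode must be 'map' or 'population'")
        for t, a, v, p in zip(subj.times, subj.analytes, subj.values, pred):
            rows.append((subj.subject_id, t, a, v, p))
    return pd.DataFrame(
        rows, columns=["subject_id", "time_h", "analyte", "observed", "predicted"]
    )


def fit_diagnostics(
    model: PopulationModel,
    subjects: Sequence[SubjectData],
    n_sim_npde: int = 1000,
    seed: int = 0,
    error: ErrorModel | None = None,
) -> FitDiagnostics:
    """Bias, imprecision, observed-vs-predicted regression and NPDE in one pass."""
    table = population_predictions(model, subjects, mode="map")
    bias, imprecision = bias_imprecision(table["observed"], table["predicted"])
    intercept, slope, r2 = obs_pred_regression(table["observed"], table["predicted"])
    values = npde(model, subjects, n_sim=n_sim_npde, seed=seed, error=error)
    return FitDiagnostics(bias, imprecision, intercept, slope, r2, values)
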