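"""Likelihood contributions and maximum-likelihood fitting.

Each individual's likelihood contribution is conditional on the state
observed at baseline.  For subjects healthy at baseline the unobserved onset
age w is integrated out over its interval-censoring window by composite
Simpson quadrature; stay probabilities are products of per-subinterval
exponential survivals under piecewise-constant intensities evaluated at left
subinterval limits (resolution ``h``), with the state-1 grid anchored at the
baseline age A_b and the state-2 grid anchored at the onset age w.

Writing P11(a -> b) for the stay probability in state 1 under escape rate
q12 + q13 and P22(w -> b | w) for the stay probability in state 2, the six
pattern contributions are

    A: int_{A_1N}^{A_20} P11(A_b->w) q12(w) P22(w->A_N|w) q23(A_N|w) dw
    B: as A without the terminal q23 factor (right censored alive)
    C: int_{A_1N}^{A_N}  P11(A_b->w) q12(w) P22(w->A_N|w) q23(A_N|w) dw
       + P11(A_b->A_N) q13(A_N)          (death with no observed illness)
    D: int_{A_1N}^{A_N}  P11(A_b->w) q12(w) P22(w->A_N|w) dw + P11(A_b->A_N)
    E: P22(A_b->A_N | W) q23(A_N | W)    (ill at baseline, onset W imputed)
    F: P22(A_b->A_N | W)

Exact death ages enter as hazard factors (densities); right censoring drops
them.  Interior healthy visits contribute only through P11 (the observation
scheme is taken as non-informative).  Because the log-intensities are linear
in age, per-subinterval rates form geometric progressions along any grid, so
cumulative hazards reduce to closed-form geometric sums; the evaluator below
exploits this to evaluate the full dataset log-likelihood with a handful of
vectorised array operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .model import LINPRED_CAP, CoefficientSet
from .records import IndividualRecord

__all__ = [
    "LikelihoodSettings",
    "FitResult",
    "simpson_integrate",
    "classify_pattern",
    "contribution_A",
    "contribution_B",
    "contribution_C",
    "contribution_D",
    "contribution_EF",
    "total_minus_log_likelihood",
    "fit_mle",
    "LikelihoodEvaluator",
]

# re-export for convenience: pattern classification lives with the records
from .records import classify_pattern  # noqa: E402  (public API surface)

_EPS = 1e-9
_TINY = 1e-300


@dataclass
class LikelihoodSettings:
    """Numeric settings for likelihood evaluation and fitting.

    h: resolution of the piecewise-constant intensity grid (years).
    integ_res: composite-Simpson resolution for the onset-age integrals
        (years); must not exceed h.
    A_0: age at which every subject is assumed to have been healthy, used
        for the left-censored onset posteriors of patterns E/F.
    """

    h: float = 0.25
    integ_res: float = 0.05
    A_0: float = 40.0
    gtol: float = 1e-5
    maxiter: int = 200
    em_tol_theta: float = 1e-4
    em_tol_loglik: float = 1e-6
    em_max_iter: int = 50

    def __post_init__(self):
        if not (self.h > 0 and self.integ_res > 0):
            raise ValueError("h and integ_res must be positive")
        if self.integ_res > self.h + _EPS:
            raise ValueError("integ_res must not exceed h")


@dataclass
class FitResult:
    """A converged (or flagged) maximum-likelihood fit."""

    theta: CoefficientSet
    minus_log_lik: float
    converged: bool
    grad_norm: float
    n_iter: int
    message: str = ""
    imputed_onsets: Optional[Dict[str, float]] = None
    em_trace: Optional[object] = None
    ci: Optional[object] = None


# ---------------------------------------------------------------------------
# Simpson quadrature
# ---------------------------------------------------------------------------

def _simpson_nodes(a: float, b: float, resolution: float):
    """Nodes and weights of composite Simpson's rule on [a, b].

    Uses the smallest even number of panels >= 2 whose width does not exceed
    ``resolution``.
    """
    if b < a:
        raise ValueError("b must be >= a")
    if b == a:
        return np.zeros(0), np.zeros(0)
    n = max(2, 2 * int(np.ceil((b - a) / (2.0 * resolution) - _EPS)))
    x = a + (b - a) * np.arange(n + 1) / n
    w = np.ones(n + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w *= (b - a) / (3.0 * n)
    return x, w


def simpson_integrate(f: Callable, a: float, b: float, resolution: float) -> float:
    """Composite Simpson estimate of the integral of ``f`` over [a, b]."""
    x, w = _simpson_nodes(a, b, resolution)
    if len(x) == 0:
        return 0.0
    try:
        y = np.asarray(f(x), dtype=float)
        if y.shape != x.shape:
            raise TypeError
    except (TypeError, ValueError):
        y = np.array([f(xi) for xi in x], dtype=float)
    return float(np.sum(w * y))


# ---------------------------------------------------------------------------
# Vectorised dataset evaluator
# ---------------------------------------------------------------------------

def _cexp(x):
    return np.exp(np.clip(x, -LINPRED_CAP, LINPRED_CAP))


def _geom_sum(log_a, log_r, n):
    """sum_{m=0}^{n-1} exp(log_a + m log_r), elementwise and overflow-safe."""
    log_a = np.clip(log_a, -LINPRED_CAP, LINPRED_CAP)
    t_full = np.clip(log_r * n, -60.0, 60.0)
    t_one = np.clip(log_r, -60.0, 60.0)
    small = np.abs(log_r) < 1e-12
    denom = np.where(small, 1.0, np.expm1(t_one))
    ratio = np.where(small, n, np.expm1(t_full) / denom)
    return np.exp(log_a) * ratio


def _split(d, h):
    """Number of full subintervals of width h in d, and the remainder."""
    d = np.maximum(np.asarray(d, dtype=float), 0.0)
    n = np.floor(d / h + _EPS)
    rem = np.maximum(d - n * h, 0.0)
    rem = np.where(rem < _EPS, 0.0, rem)
    return n, rem


def _rate_index(n, rem):
    """Subinterval index whose left-limit rate is in force just before d."""
    return np.where(rem > 0, n, np.maximum(n - 1.0, 0.0))


class LikelihoodEvaluator:
    """Precompiled likelihood for a fixed dataset and settings.

    Precomputes quadrature nodes and grid offsets once; evaluating the
    likelihood at a new parameter vector then costs only vectorised array
    arithmetic.  Assumes baseline-constant covariates (the default covariate
    handling), which lets extra covariates fold into per-record intercepts.
    """

    def __init__(self, records: Sequence[IndividualRecord],
                 settings: LikelihoodSettings,
                 covariate_names: Sequence[str] = ()):
        self.settings = settings
        self.covariate_names = tuple(covariate_names)
        self.records = list(records)
        r = len(self.covariate_names)
        for rec in self.records:
            if len(rec.covariates) != r:
                raise ValueError(f"record {rec.id}: expected {r} covariates")
        h = settings.h

        self.ids = [rec.id for rec in self.records]
        self.patterns = np.array([rec.pattern for rec in self.records])
        self.A_b = np.array([rec.baseline_age for rec in self.records])
        self.A_N = np.array([rec.end_age for rec in self.records])
        # design matrix with the age column zeroed: folds covariates into
        # per-record intercept offsets c_ij = X0 . beta_ij
        self.X0 = np.column_stack(
            [np.ones(len(self.records)), np.zeros(len(self.records))]
            + [np.array([rec.covariates[i] for rec in self.records]) for i in range(r)]
        )

        # --- integral patterns (A-D): flatten Simpson nodes --------------
        node_w, node_wt, node_rec, node_q23 = [], [], [], []
        self.int_windows = {}
        for i, rec in enumerate(self.records):
            p = self.patterns[i]
            if p in ("E", "F"):
                continue
            lo = rec.last_healthy_age
            hi = rec.first_ill_age if p in ("A", "B") else rec.end_age
            if p in ("A", "B") and hi - lo <= _EPS:
                raise ValueError(f"record {rec.id}: degenerate onset window")
            self.int_windows[rec.id] = (lo, hi)
            if hi - lo <= _EPS:
                continue  # censored exactly at the last healthy visit (C/D)
            x, wt = _simpson_nodes(lo, hi, settings.integ_res)
            node_w.append(x)
            node_wt.append(wt)
            node_rec.append(np.full(len(x), i, dtype=np.int64))
            node_q23.append(np.full(len(x), p in ("A", "C")))
        if node_w:
            self.node_w = np.concatenate(node_w)
            self.node_wt = np.concatenate(node_wt)
            self.node_rec = np.concatenate(node_rec)
            self.node_q23 = np.concatenate(node_q23)
        else:
            self.node_w = np.zeros(0)
            self.node_wt = np.zeros(0)
            self.node_rec = np.zeros(0, dtype=np.int64)
            self.node_q23 = np.zeros(0, dtype=bool)
        # state-1 grid offsets of each node relative to its record's A_b
        self.n1, self.rem1 = _split(self.node_w - self.A_b[self.node_rec], h)
        # state-2 grid: anchored at the node's onset age w, up to A_N
        self.n2, self.rem2 = _split(self.A_N[self.node_rec] - self.node_w, h)
        self.i2 = _rate_index(self.n2, self.rem2)

        # --- per-record closed-form pieces --------------------------------
        self.is_int = np.isin(self.patterns, ("A", "B", "C", "D"))
        self.is_CD = np.isin(self.patterns, ("C", "D"))
        self.is_C = self.patterns == "C"
        self.is_E = self.patterns == "E"
        self.is_F = self.patterns == "F"
        self.is_EF = self.is_E | self.is_F
        self.n1N, self.rem1N = _split(self.A_N - self.A_b, h)
        self.i1N = _rate_index(self.n1N, self.rem1N)
        self.ef_idx = np.flatnonzero(self.is_EF)

    # -- parameter unpacking ----------------------------------------------
    def _unpack(self, v):
        theta = CoefficientSet.from_vector(v, self.covariate_names)
        c12 = self.X0 @ theta.beta_12
        c13 = self.X0 @ theta.beta_13
        c23 = self.X0 @ theta.beta_23
        return theta, c12, c13, c23

    def contributions(self, v: np.ndarray, W: Optional[np.ndarray] = None):
        """Likelihood contribution of every record at parameter vector v.

        ``W`` holds imputed onset ages for the E/F records (aligned with
        ``ef_idx``); contributions of E/F records are returned on the log
        scale alongside the plain values to avoid underflow.
        """
        theta, c12, c13, c23 = self._unpack(v)
        h = self.settings.h
        b12, b13, b23, g = (theta.beta_12[1], theta.beta_13[1],
                            theta.beta_23[1], theta.gamma)
        contrib = np.zeros(len(self.records))

        if len(self.node_w):
            rec = self.node_rec
            Ab = self.A_b[rec]
            # cumulative state-1 escape hazard from A_b to the node age w
            u12 = c12[rec] + b12 * Ab
            u13 = c13[rec] + b13 * Ab
            lam1 = (h * (_geom_sum(u12, b12 * h, self.n1)
                         + _geom_sum(u13, b13 * h, self.n1))
                    + self.rem1 * (_cexp(u12 + b12 * h * self.n1)
                                   + _cexp(u13 + b13 * h * self.n1)))
            q12 = _cexp(u12 + b12 * h * self.n1)
            # cumulative 2->3 hazard from onset w to A_N (sojourn clock at w)
            u23 = c23[rec] + b23 * self.node_w
            r23 = (b23 + g) * h
            lam2 = (h * _geom_sum(u23, r23, self.n2)
                    + self.rem2 * _cexp(u23 + r23 * self.n2))
            integrand = np.exp(-lam1) * q12 * np.exp(-lam2)
            q23_end = _cexp(u23 + r23 * self.i2)
            integrand = np.where(self.node_q23, integrand * q23_end, integrand)
            contrib += np.bincount(rec, weights=self.node_wt * integrand,
                                   minlength=len(self.records))

        # second branch of C/D: no illness at all during follow-up
        if np.any(self.is_CD):
            u12 = c12 + b12 * self.A_b
            u13 = c13 + b13 * self.A_b
            lam1N = (h * (_geom_sum(u12, b12 * h, self.n1N)
                          + _geom_sum(u13, b13 * h, self.n1N))
                     + self.rem1N * (_cexp(u12 + b12 * h * self.n1N)
                                     + _cexp(u13 + b13 * h * self.n1N)))
            p11 = np.exp(-lam1N)
            q13_end = _cexp(u13 + b13 * h * self.i1N)
            contrib[self.is_CD] += np.where(self.is_C, p11 * q13_end, p11)[self.is_CD]

        # E/F: stay (and death) in state 2 over follow-up given onset age W
        log_ef = np.zeros(len(self.ef_idx))
        if len(self.ef_idx):
            if W is None:
                raise ValueError("E/F records present but no onset ages supplied")
            W = np.asarray(W, dtype=float)
            idx = self.ef_idx
            if np.any(W >= self.A_b[idx]):
                raise ValueError("imputed onset age must precede baseline age")
            r23 = (b23 + g) * h
            u = c23[idx] + (b23 + g) * self.A_b[idx] - g * W
            lam2 = (h * _geom_sum(u, r23, self.n1N[idx])
                    + self.rem1N[idx] * _cexp(u + r23 * self.n1N[idx]))
            log_q23 = np.clip(u + r23 * self.i1N[idx], -LINPRED_CAP, LINPRED_CAP)
            log_ef = -lam2 + np.where(self.is_E[idx], log_q23, 0.0)
            contrib[idx] = np.exp(log_ef)
        return contrib, log_ef

    def nll(self, v: np.ndarray, W: Optional[np.ndarray] = None) -> float:
        """Total minus log-likelihood at parameter vector v."""
        contrib, log_ef = self.contributions(v, W)
        out = -np.sum(np.log(np.maximum(contrib[self.is_int], _TINY)))
        out -= np.sum(log_ef)
        if not np.isfinite(out):
            return 1e12
        return float(out)

    def W_array(self, W_map: Optional[Dict[str, float]]) -> Optional[np.ndarray]:
        """Onset ages for the E/F records, in evaluator order."""
        if len(self.ef_idx) == 0:
            return None
        if W_map is None:
            raise ValueError("dataset has E/F records: onset-age map required")
        missing = [self.ids[i] for i in self.ef_idx if self.ids[i] not in W_map]
        if missing:
            raise KeyError(f"no onset age for records: {missing}")
        return np.array([W_map[self.ids[i]] for i in self.ef_idx])


# ---------------------------------------------------------------------------
# Single-record contribution wrappers
# ---------------------------------------------------------------------------

def _single(record, theta, settings, expected, W=None):
    ev = LikelihoodEvaluator([record], settings, theta.covariate_names)
    p = record.pattern
    if p not in expected:
        raise ValueError(f"record {record.id} has pattern {p}, expected {expected}")
    W_arr = None if W is None else np.array([W])
    contrib, _ = ev.contributions(theta.to_vector(), W_arr)
    return float(contrib[0])


def contribution_A(record, theta, settings=None):
    """Pattern-A likelihood: illness observed during follow-up, then death."""
    return _single(record, theta, settings or LikelihoodSettings(), ("A",))


def contribution_B(record, theta, settings=None):
    """Pattern-B likelihood: illness observed, right censored alive."""
    return _single(record, theta, settings or LikelihoodSettings(), ("B",))


def contribution_C(record, theta, settings=None):
    """Pattern-C likelihood: death with illness possibly missed (two branches)."""
    return _single(record, theta, settings or LikelihoodSettings(), ("C",))


def contribution_D(record, theta, settings=None):
    """Pattern-D likelihood: censored healthy, illness possibly missed."""
    return _single(record, theta, settings or LikelihoodSettings(), ("D",))


def contribution_EF(record, theta, W: float, settings=None):
    """Pattern E/F likelihood given an (imputed) onset age W < A_b."""
    return _single(record, theta, settings or LikelihoodSettings(), ("E", "F"), W=W)


# ---------------------------------------------------------------------------
# Total likelihood and fitting
# ---------------------------------------------------------------------------

def total_minus_log_likelihood(dataset: Sequence[IndividualRecord],
                               theta: CoefficientSet,
                               W_map: Optional[Dict[str, float]] = None,
                               settings: Optional[LikelihoodSettings] = None) -> float:
    """Minus the log of the product of all individual contributions."""
    if len(dataset) == 0:
        return 0.0
    settings = settings or LikelihoodSettings()
    ev = LikelihoodEvaluator(dataset, settings, theta.covariate_names)
    contrib, log_ef = ev.contributions(theta.to_vector(), ev.W_array(W_map))
    bad = np.flatnonzero(~np.isfinite(contrib) | (contrib <= 0.0))
    bad = [ev.ids[i] for i in bad if ev.is_int[i]]
    if bad:
        raise FloatingPointError(f"non-positive likelihood contribution for ids {bad}")
    return float(-np.sum(np.log(contrib[ev.is_int])) - np.sum(log_ef))


def _central_diff_grad(f, x, rel_step=1e-5):
    g = np.zeros_like(x)
    for i in range(len(x)):
        s = rel_step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += s
        xm[i] -= s
        g[i] = (f(xp) - f(xm)) / (2.0 * s)
    return g


def fit_mle(dataset: Sequence[IndividualRecord],
            theta0: CoefficientSet,
            W_map: Optional[Dict[str, float]] = None,
            settings: Optional[LikelihoodSettings] = None,
            evaluator: Optional[LikelihoodEvaluator] = None) -> FitResult:
    """Quasi-Newton (BFGS) maximisation of the likelihood.

    Gradients are central finite differences (relative step 1e-5); the
    parameters are unconstrained on the log-linear scale.  Optimiser failure
    is reported through the ``converged`` flag, never raised.
    """
    settings = settings or LikelihoodSettings()
    ev = evaluator or LikelihoodEvaluator(dataset, settings, theta0.covariate_names)
    W = ev.W_array(W_map)
    fun = lambda v: ev.nll(v, W)
    res = minimize(fun, theta0.to_vector(), method="BFGS",
                   jac=lambda v: _central_diff_grad(fun, v),
                   options={"gtol": settings.gtol, "maxiter": settings.maxiter})
    theta = CoefficientSet.from_vector(res.x, theta0.covariate_names)
    grad_norm = float(np.max(np.abs(res.jac)))
    # line searches on a flat likelihood ridge can end with "precision loss"
    # at an effectively stationary point; accept small gradients as converged
    converged = bool(res.success) or grad_norm < 1e-3
    return FitResult(theta=theta, minus_log_lik=float(res.fun),
                     converged=converged, grad_norm=grad_norm,
                     n_iter=int(res.nit), message=str(res.message))
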