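"""EM-inspired imputation of left-censored illness-onset ages.

Subjects already ill at baseline (patterns E/F) have an onset age W known
only to lie in (A_0, A_b), where A_0 is the age at which everyone is assumed
to have been healthy.  The fitting algorithm alternates between:

1. fit the model on the fully-specified patterns A-D to get theta^0;
2. for each E/F subject, compute the posterior probability P_k that onset
   fell in subinterval k of the [A_0, A_b] grid, conditional on being
   healthy at A_0 and ill at baseline (Bayes), take the expected subinterval
   k* = floor(sum_k k P_k), the expected within-subinterval transition time
   (a truncated-exponential mean), and impute W from them;
3. refit on all patterns using the imputed baseline sojourn A_b - W;
4. repeat 2-3 until both the parameter vector and the likelihood converge.

The posterior numerator for subinterval k multiplies survival in state 1 up
to k, the probability of a 1->2 transition inside k, and survival in state 2
from k to baseline with the sojourn clock started at k's left limit:

    num_k = [prod_{m<k} p11.m] * p12.k * [prod_{m>k} p22.m | onset in k]

with p11.m = exp(-lambda_1.m len_m), p12.k = (q12.k / lambda_1.k)
(1 - exp(-lambda_1.k len_k)) and p22.m = exp(-q23.m len_m).  Death within
the onset subinterval itself is ignored, consistent with this factorisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .model import LINPRED_CAP, AgeGrid, CoefficientSet, build_grid
from .records import IndividualRecord
from .likelihood import (FitResult, LikelihoodEvaluator, LikelihoodSettings,
                         fit_mle)

__all__ = [
    "OnsetPosterior",
    "EMTrace",
    "onset_posterior",
    "expected_subinterval",
    "expected_time_within",
    "impute_onset_age",
    "initial_theta",
    "em_fit",
]

_CLAMP_EPS = 1e-6


@dataclass
class OnsetPosterior:
    """Posterior distribution of the onset subinterval on the [A_0, A_b] grid."""

    grid: AgeGrid
    P: np.ndarray

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (self.grid.K,):
            raise ValueError("need one probability per subinterval")
        if np.any(self.P < 0) or abs(self.P.sum() - 1.0) > 1e-12:
            raise ValueError("posterior must be a probability vector")


@dataclass
class EMTrace:
    """Per-iteration record of the fit-impute loop."""

    thetas: List[np.ndarray] = field(default_factory=list)
    minus_log_liks: List[float] = field(default_factory=list)
    imputed: List[Dict[str, float]] = field(default_factory=list)
    converged: bool = False

    @property
    def n_iter(self) -> int:
        return len(self.minus_log_liks)


def _fold_intercepts(theta: CoefficientSet, covariates: np.ndarray):
    """Per-record intercepts with baseline covariates absorbed."""
    x0 = np.concatenate([[1.0, 0.0], covariates])
    return (float(x0 @ theta.beta_12), float(x0 @ theta.beta_13),
            float(x0 @ theta.beta_23))


def onset_posterior(theta: CoefficientSet, record: IndividualRecord,
                    A_0: float, h: float) -> OnsetPosterior:
    """Posterior P_1..P_K of the onset subinterval for an E/F record."""
    if record.baseline_state != 2:
        raise ValueError(f"record {record.id} is not ill at baseline")
    A_b = record.baseline_age
    if not A_0 < A_b:
        raise ValueError(f"A_0={A_0} must precede baseline age {A_b}")
    grid = build_grid(A_0, A_b, h)
    c12, c13, c23 = _fold_intercepts(theta, record.covariates)
    b12, b13, b23, g = (theta.beta_12[1], theta.beta_13[1],
                        theta.beta_23[1], theta.gamma)
    a = grid.lefts
    L = grid.lengths
    q12 = np.exp(np.clip(c12 + b12 * a, -LINPRED_CAP, LINPRED_CAP))
    q13 = np.exp(np.clip(c13 + b13 * a, -LINPRED_CAP, LINPRED_CAP))
    lam1 = q12 + q13
    log_p11 = -lam1 * L
    # survival in state 1 through all subintervals before k
    before = np.concatenate([[0.0], np.cumsum(log_p11)[:-1]])
    with np.errstate(divide="ignore"):
        log_p12 = np.log(np.where(lam1 > 0, q12 / np.where(lam1 > 0, lam1, 1.0), 0.0)) \
            + np.log(-np.expm1(-lam1 * L))
    # state-2 survival from subinterval k+1 to baseline, clock at a_k:
    # sum_{m>k} exp(c23 + b23 a_m + g (a_m - a_k)) L_m = e^{-g a_k} T_k
    v = np.exp(np.clip(c23 + (b23 + g) * a, -LINPRED_CAP, LINPRED_CAP)) * L
    suffix = np.concatenate([np.cumsum(v[::-1])[::-1][1:], [0.0]])
    log_p22 = -np.exp(np.clip(-g * a, -LINPRED_CAP, LINPRED_CAP)) * suffix
    log_num = before + log_p12 + log_p22
    m = np.max(log_num)
    if not np.isfinite(m):
        raise FloatingPointError(
            f"record {record.id}: degenerate onset posterior (all numerators zero)")
    P = np.exp(log_num - m)
    P /= P.sum()
    return OnsetPosterior(grid, P)


def expected_subinterval(posterior: OnsetPosterior) -> int:
    """Expected (floored) onset subinterval k* = floor(sum_k k P_k), 1-based."""
    k = np.arange(1, posterior.grid.K + 1)
    k_star = int(np.floor(float(k @ posterior.P) + 1e-12))
    return min(max(k_star, 1), posterior.grid.K)


def expected_time_within(lambda_star: float, h: float) -> float:
    """Mean of an exponential(lambda_star) truncated to [0, h].

    This is the expected transition time within the onset subinterval,
    conditional on the transition happening there:
    t = 1/lambda - h exp(-lambda h) / (1 - exp(-lambda h)), with the uniform
    limit h/2 as lambda -> 0; always in (0, h).
    """
    if lambda_star < 0:
        raise ValueError("rate must be non-negative")
    if h <= 0:
        raise ValueError("subinterval length must be positive")
    x = lambda_star * h
    if x < 1e-12:
        return h * (0.5 - x / 12.0)
    return h * (1.0 / x - 1.0 / np.expm1(min(x, 700.0)))


def impute_onset_age(A_0: float, k_star: int, t: float, h: float,
                     A_b: Optional[float] = None) -> float:
    """Imputed onset age W = A_0 + (k* - 1) h + t, optionally clamped below A_b."""
    W = A_0 + (k_star - 1) * h + t
    if A_b is not None and W >= A_b - _CLAMP_EPS:
        warnings.warn("imputed onset age at the baseline boundary; clamping",
                      RuntimeWarning, stacklevel=2)
        W = A_b - _CLAMP_EPS
    return W


def _impute_record(theta, record, settings) -> float:
    post = onset_posterior(theta, record, settings.A_0, settings.h)
    k_star = expected_subinterval(post)
    length = float(post.grid.lengths[k_star - 1])
    c12, c13, _ = _fold_intercepts(theta, record.covariates)
    a_left = float(post.grid.lefts[k_star - 1])
    lam = (np.exp(np.clip(c12 + theta.beta_12[1] * a_left, -LINPRED_CAP, LINPRED_CAP))
           + np.exp(np.clip(c13 + theta.beta_13[1] * a_left, -LINPRED_CAP, LINPRED_CAP)))
    t = expected_time_within(float(lam), length)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return impute_onset_age(settings.A_0, k_star, t, settings.h,
                                A_b=record.baseline_age)


def initial_theta(dataset: Sequence[IndividualRecord],
                  covariate_names: Sequence[str] = ()) -> CoefficientSet:
    """Feasible starting values from crude occurrence/exposure rates.

    Intercepts are log crude rates, all slopes (age, covariates) and gamma
    start at zero.
    """
    py1 = py2 = 0.0
    ev12 = ev13 = ev23 = 0
    for rec in dataset:
        p = rec.pattern
        if p in ("A", "B"):
            mid = 0.5 * (rec.last_healthy_age + rec.first_ill_age)
            py1 += mid - rec.baseline_age
            py2 += rec.end_age - mid
            ev12 += 1
            ev23 += p == "A"
        elif p in ("C", "D"):
            py1 += rec.end_age - rec.baseline_age
            ev13 += p == "C"
        else:
            py2 += rec.end_age - rec.baseline_age
            ev23 += p == "E"
    r = len(covariate_names)
    def crude(events, py):
        return np.log(max(events, 0.5) / max(py, 1e-6))
    def beta(intercept):
        return np.concatenate([[intercept, 0.0], np.zeros(r)])
    return CoefficientSet(beta(crude(ev12, py1)), beta(crude(ev13, py1)),
                          beta(crude(ev23, py2)), 0.0, tuple(covariate_names))


def em_fit(dataset: Sequence[IndividualRecord],
           settings: Optional[LikelihoodSettings] = None,
           theta0: Optional[CoefficientSet] = None,
           covariate_names: Sequence[str] = ()) -> FitResult:
    """Full fit-impute iteration handling left-censored onsets.

    Deterministic given the dataset and settings.  With no E/F records the
    algorithm degenerates to a single maximum-likelihood fit on patterns A-D.
    """
    settings = settings or LikelihoodSettings()
    if theta0 is not None:
        covariate_names = theta0.covariate_names
    else:
        theta0 = initial_theta(dataset, covariate_names)
    ad = [rec for rec in dataset if rec.pattern in "ABCD"]
    ef = [rec for rec in dataset if rec.pattern in "EF"]
    if not ad:
        raise ValueError("em_fit requires at least one record in patterns A-D")

    trace = EMTrace()
    # step 1: theta^0 from the fully-specified patterns only
    fit = fit_mle(ad, theta0, settings=settings)
    trace.thetas.append(fit.theta.to_vector())
    trace.minus_log_liks.append(fit.minus_log_lik)
    trace.imputed.append({})
    if not ef:
        trace.converged = fit.converged
        fit.imputed_onsets = {}
        fit.em_trace = trace
        return fit

    ev_all = LikelihoodEvaluator(dataset, settings, covariate_names)
    theta = fit.theta
    prev_v = theta.to_vector()
    prev_nll = np.inf
    best = None  # (nll, fit, W_map)
    stall = 0
    W_map: Dict[str, float] = {}
    for _ in range(settings.em_max_iter):
        W_map = {rec.id: _impute_record(theta, rec, settings) for rec in ef}
        fit = fit_mle(dataset, theta, W_map=W_map, settings=settings,
                      evaluator=ev_all)
        theta = fit.theta
        v = theta.to_vector()
        trace.thetas.append(v)
        trace.minus_log_liks.append(fit.minus_log_lik)
        trace.imputed.append(dict(W_map))
        d_theta = float(np.max(np.abs(v - prev_v)))
        d_nll = abs(fit.minus_log_lik - prev_nll)
        prev_v, prev_nll = v, fit.minus_log_lik
        scale = settings.em_tol_loglik * max(1.0, abs(fit.minus_log_lik))
        if best is None or fit.minus_log_lik < best[0] - scale:
            best = (fit.minus_log_lik, fit, dict(W_map))
            stall = 0
        else:
            # the floor-discretised imputation can enter a small limit cycle
            # (an onset flipping between adjacent subintervals); a run of
            # non-improving iterations is treated as converged and the
            # best-likelihood iterate is returned
            stall += 1
        if (d_theta < settings.em_tol_theta and d_nll < scale) or stall >= 3:
            trace.converged = True
            break
    _, fit, W_map = best if best[0] < fit.minus_log_lik else (0, fit, W_map)
    fit.imputed_onsets = dict(W_map)
    fit.em_trace = trace
    fit.converged = fit.converged and trace.converged
    return fit
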