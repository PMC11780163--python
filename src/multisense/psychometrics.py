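"""Probit psychometric functions for 2AFC data.

A 2AFC observer judging which of two vibration periods is longer is modelled
as a cumulative-normal (probit) psychometric function

    P(respond "comparison longer" | x) = Phi(beta0 + beta1 * x)

where ``x`` is the comparison period in seconds.  Two summary statistics are
derived from the fitted coefficients:

* PSE (point of subjective equality): the period judged longer than the
  reference on 50% of trials, ``-beta0 / beta1``.
* JND (just-noticeable difference): the increment from the PSE to the period
  judged longer on 84% of trials, ``Phi^-1(0.84) / beta1``.  The 84% point
  makes the JND equal to one standard deviation of the underlying Gaussian
  sensory noise.

The maximum-likelihood fit is a two-parameter Fisher-scoring (IRLS) iteration
on per-level binomial counts.  It is written in batched form — ``B`` response
tables sharing one stimulus design are fitted simultaneously — because the
parametric bootstrap refits thousands of resampled tables per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "Z84",
    "PsychometricFit",
    "fit_probit",
    "pse_from_fit",
    "jnd_from_fit",
    "predict_curve",
    "aggregate_trials",
    "batch_fit_probit",
]

#: Phi^-1(0.84), the probit of the 84% threshold that defines the JND.
#: Kept at full double precision (never the rounded 0.9945).
Z84: float = float(norm.ppf(0.84))

_PCLIP = 1e-12
_SLOPE_CAP = 1e8


@dataclass
class PsychometricFit:
    """Probit coefficients and derived thresholds for one condition/site."""

    beta0: float
    beta1: float
    pse: float
    jnd: float
    n_trials: int
    log_likelihood: float
    converged: bool
    separable: bool = False
    subject: str | None = None
    site: str | None = None
    condition: str | None = None
    levels: np.ndarray = field(default=None, repr=False)
    n_per_level: np.ndarray = field(default=None, repr=False)


def aggregate_trials(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse a trial table to per-level binomial counts.

    Accepts a DataFrame with ``comparison_period`` and ``response`` columns
    or any iterable of objects with those attributes.  Returns
    ``(x, n, k)``: sorted distinct comparison levels, trials per level, and
    "comparison longer" responses per level.
    """
    if not isinstance(trials, pd.DataFrame):
        trials = pd.DataFrame(
            {
                "comparison_period": [t.comparison_period for t in trials],
                "response": [int(t.response_comparison_longer) for t in trials],
            }
        )
    g = trials.groupby("comparison_period")["response"]
    x = np.asarray(sorted(g.groups), dtype=float)
    n = g.count().loc[x].to_numpy(dtype=float)
    k = g.sum().loc[x].to_numpy(dtype=float)
    return x, n, k


def _detect_separation(x: np.ndarray, n: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Complete-separation mask for batched count tables.

    A table is separable when no level has mixed responses and the all-0 /
    all-1 levels are split by a threshold in x (monotone in either
    direction).  Such tables have no finite ML slope.
    """
    k = np.atleast_2d(k)
    frac = k / n  # (B, L)
    mixed = (k > 0) & (k < n)
    any_mixed = mixed.any(axis=1)
    # monotone step up or down in the 0/1 level pattern
    d = np.diff(frac, axis=1)
    mono_up = (d >= 0).all(axis=1)
    mono_down = (d <= 0).all(axis=1)
    both = ((frac == 0).any(axis=1)) & ((frac == 1).any(axis=1))
    return (~any_mixed) & (mono_up | mono_down) & both


def _loglik(eta: np.ndarray, n: np.ndarray, k: np.ndarray) -> np.ndarray:
    p = np.clip(norm.cdf(eta), _PCLIP, 1 - _PCLIP)
    return (k * np.log(p) + (n - k) * np.log1p(-p)).sum(axis=-1)


def batch_fit_probit(
    x: np.ndarray,
    n: np.ndarray,
    k: np.ndarray,
    *,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``B`` probit GLMs sharing one design by Fisher scoring.

    Parameters
    ----------
    x : (L,) comparison levels in seconds.
    n : (L,) trials per level.
    k : (B, L) or (L,) "longer" responses per level.

    Returns
    -------
    beta : (B, 2) array of (intercept, slope).
    loglik : (B,) maximized log-likelihood.
    converged : (B,) bool, relative log-likelihood change < tol.
    ok : (B,) bool, usable fit (converged, finite, not separable, not
        degenerate).  Rows with ``~ok`` carry NaN/sentinel coefficients.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    k2 = np.atleast_2d(np.asarray(k, dtype=float))
    B, L = k2.shape
    if L != x.size or L < 2:
        raise ValueError("need counts for >= 2 distinct comparison levels")

    all_same = (k2.sum(axis=1) == 0) | (k2.sum(axis=1) == n.sum())
    separable = _detect_separation(x, n, k2)
    bad = all_same | separable

    # start values: weighted OLS on the empirical probit transform
    p_emp = (k2 + 0.5) / (n + 1.0)
    z = norm.ppf(p_emp)
    w0 = np.broadcast_to(n, (B, L))
    sw, swx = (w0).sum(axis=1), (w0 * x).sum(axis=1)
    swxx, swz, swxz = (w0 * x * x).sum(axis=1), (w0 * z).sum(axis=1), (w0 * x * z).sum(axis=1)
    det0 = sw * swxx - swx**2
    b1 = (sw * swxz - swx * swz) / det0
    b0 = (swz - b1 * swx) / sw

    eta = b0[:, None] + b1[:, None] * x
    ll = _loglik(eta, n, k2)
    converged = np.zeros(B, dtype=bool)
    active = ~bad

    for _ in range(max_iter):
        if not active.any():
            break
        eta = b0[:, None] + b1[:, None] * x
        p = np.clip(norm.cdf(eta), _PCLIP, 1 - _PCLIP)
        phi = norm.pdf(eta)
        w = n * phi**2 / (p * (1 - p))
        zz = eta + (k2 / n - p) / np.maximum(phi, 1e-300)
        s0, s1 = w.sum(axis=1), (w * x).sum(axis=1)
        s2 = (w * x * x).sum(axis=1)
        t0, t1 = (w * zz).sum(axis=1), (w * x * zz).sum(axis=1)
        det = s0 * s2 - s1**2
        with np.errstate(divide="ignore", invalid="ignore"):
            b1_new = (s0 * t1 - s1 * t0) / det
            b0_new = (t0 - b1_new * s1) / s0
        step_ok = np.isfinite(b0_new) & np.isfinite(b1_new) & (det > 1e-300)
        upd = active & step_ok
        b0 = np.where(upd, b0_new, b0)
        b1 = np.where(upd, b1_new, b1)
        bad |= active & ~step_ok
        active &= step_ok

        ll_new = _loglik(b0[:, None] + b1[:, None] * x, n, k2)
        done = active & (np.abs(ll_new - ll) <= tol * (np.abs(ll) + tol))
        converged |= done
        ll = np.where(active, ll_new, ll)
        active &= ~done

    diverged = np.abs(b1) > _SLOPE_CAP
    ok = converged & ~bad & ~diverged & np.isfinite(b0) & np.isfinite(b1)
    b0 = np.where(ok, b0, np.nan)
    b1 = np.where(ok, b1, np.nan)
    return np.stack([b0, b1], axis=1), ll, converged & ~bad, ok


def fit_probit(trials, *, subject=None, site=None, condition=None) -> PsychometricFit:
    """Maximum-likelihood probit fit of one condition's 2AFC trial table.

    Raises
    ------
    ValueError
        Fewer than two distinct comparison levels, or all responses
        identical (no information about either parameter).

    Notes
    -----
    Completely separated tables (all-0 responses below some level, all-1
    above, none mixed) have an infinite ML slope; they are returned as a
    flagged fit (``separable=True, converged=False``) with an
    infinite-slope sentinel so bootstrap machinery can drop them
    deterministically instead of crashing.
    """
    x, n, k = aggregate_trials(trials)
    if x.size < 2:
        raise ValueError("need >= 2 distinct comparison levels")
    total, hits = n.sum(), k.sum()
    if hits == 0 or hits == total:
        raise ValueError("all responses identical; psychometric function undefined")

    sep = bool(_detect_separation(x, n, k[None, :])[0])
    if sep:
        lo = x[k == n].min() if (k == n).any() else x[-1]
        hi = x[k == 0].max() if (k == 0).any() else x[0]
        return PsychometricFit(
            beta0=-np.inf, beta1=np.inf, pse=float((lo + hi) / 2.0), jnd=0.0,
            n_trials=int(total), log_likelihood=0.0, converged=False,
            separable=True, subject=subject, site=site, condition=condition,
            levels=x, n_per_level=n,
        )

    beta, ll, converged, ok = batch_fit_probit(x, n, k[None, :])
    b0, b1 = float(beta[0, 0]), float(beta[0, 1])
    if ok[0]:
        pse = -b0 / b1
        jnd = Z84 / b1
    else:
        pse, jnd = np.nan, np.nan
    return PsychometricFit(
        beta0=b0, beta1=b1, pse=float(pse), jnd=float(jnd),
        n_trials=int(total), log_likelihood=float(ll[0]), converged=bool(ok[0]),
        subject=subject, site=site, condition=condition,
        levels=x, n_per_level=n,
    )


def pse_from_fit(fit: PsychometricFit) -> float:
    """Point of subjective equality, ``-beta0/beta1`` (seconds)."""
    if not fit.converged:
        raise ValueError("PSE undefined for a non-converged fit")
    if fit.beta1 == 0:
        raise ValueError("PSE undefined for zero slope")
    return -fit.beta0 / fit.beta1


def jnd_from_fit(fit: PsychometricFit) -> float:
    """Just-noticeable difference, ``Phi^-1(0.84)/beta1`` (seconds)."""
    if not fit.converged:
        raise ValueError("JND undefined for a non-converged fit")
    if fit.beta1 <= 0:
        raise ValueError("JND undefined for a non-increasing psychometric curve")
    return Z84 / fit.beta1


def predict_curve(fit: PsychometricFit, x: np.ndarray) -> np.ndarray:
    """Predicted P(comparison judged longer) on a grid of periods."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    return norm.cdf(fit.beta0 + fit.beta1 * np.asarray(x, dtype=float))


def fits_to_frame(fits: list[PsychometricFit]) -> pd.DataFrame:
    """Tidy per-fit table (one row per subject/site/condition)."""
    return pd.DataFrame(
        [
            {
                "subject": f.subject, "site": f.site, "condition": f.condition,
                "beta0": f.beta0, "beta1": f.beta1, "pse": f.pse, "jnd": f.jnd,
                "n": f.n_trials, "converged": f.converged,
            }
            for f in fits
        ]
    )
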