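"""Reaction-time extraction, outlier filtering and the race-model check.

RTs are measured from the offset of the second stimulus to the keypress.
Cleaning is a fixed two-stage pass: (1) values above 5 s are discarded as
non-representative; (2) values more than three standard deviations from the
mean of the survivors are removed.  Each stage runs exactly once.

The race-model (Miller) inequality bounds the bimodal RT distribution a
parallel race of independent unimodal channels could produce:

    F_bimodal(t) <= min(1, F_T(t) + F_V(t)).

Positive excursions of F_bimodal above the bound — typically at early
quantiles — indicate coactivation (true multisensory facilitation) rather
than statistical facilitation from the race.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RTSet",
    "extract_rt",
    "filter_rts",
    "equalize_counts",
    "race_model_inequality",
    "rt_summary",
]

RT_CEILING_S = 5.0
SD_CRITERION = 3.0


@dataclass
class RTSet:
    """Cleaned reaction times for one subject x site x condition."""

    values: np.ndarray = field(repr=False)
    n_raw: int
    n_valid: int
    subject: str | None = None
    site: str | None = None
    condition: str | None = None


def extract_rt(offsets, presses) -> np.ndarray:
    """Per-trial RT = keypress - second-stimulus offset, in trial order.

    Missing keypresses (NaN) stay missing; anticipations (press before
    offset) are flagged invalid as NaN.
    """
    off = np.asarray(offsets, dtype=float)
    prs = np.asarray(presses, dtype=float)
    if off.shape != prs.shape:
        raise ValueError("offset and keypress arrays must align per trial")
    rt = prs - off
    rt[rt < 0] = np.nan
    return rt


def filter_rts(values, **labels) -> RTSet:
    """Two-stage outlier filter: the 5 s ceiling, then the +/-3 SD pass.

    Stage 2's mean and SD are computed on the stage-1 survivors only, and
    the pass runs once (no iteration to convergence).  Missing values are
    not counted as raw trials.  Raises if fewer than 3 values survive.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n_raw = v.size
    if n_raw < 3:
        raise ValueError("need at least 3 reaction times")
    v = v[v <= RT_CEILING_S]
    if v.size >= 1:
        m, sd = v.mean(), v.std(ddof=0)
        v = v[np.abs(v - m) <= SD_CRITERION * sd]
    if v.size < 3:
        raise ValueError("fewer than 3 reaction times survive outlier filtering")
    return RTSet(values=v, n_raw=n_raw, n_valid=int(v.size), **labels)


def equalize_counts(rt_sets: list[RTSet], seed: int) -> list[RTSet]:
    """Subsample every set to the smallest valid count across sets.

    The paired Friedman test needs equal repetition counts per condition;
    the count used is that of the condition with the fewest valid RTs.
    Random (seeded) subsampling rather than truncation avoids
    time-on-task bias.
    """
    if len(rt_sets) < 2:
        raise ValueError("need at least two RT sets to equalize")
    n_min = min(s.n_valid for s in rt_sets)
    rng = np.random.default_rng(seed)
    out = []
    for s in rt_sets:
        if s.n_valid == n_min:
            vals = s.values.copy()
        else:
            idx = np.sort(rng.choice(s.n_valid, size=n_min, replace=False))
            vals = s.values[idx]
        out.append(
            RTSet(values=vals, n_raw=s.n_raw, n_valid=n_min,
                  subject=s.subject, site=s.site, condition=s.condition)
        )
    return out


def _ecdf(sample: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Right-continuous empirical CDF of `sample` evaluated at `t`."""
    s = np.sort(sample)
    return np.searchsorted(s, t, side="right") / s.size


def race_model_inequality(
    rt_t: np.ndarray,
    rt_v: np.ndarray,
    rt_vt: np.ndarray,
    quantiles: np.ndarray | None = None,
) -> pd.DataFrame:
    """Miller-bound test of the bimodal RT distribution.

    The bound B(t) = min(1, F_T(t) + F_V(t)) is evaluated at the empirical
    quantiles of the bimodal distribution (default 0.05 ... 0.95 in steps
    of 0.05); violation(q) = F_VT(t_q) - B(t_q).  Returns a tidy frame with
    columns ``quantile, t, F_vt, bound, violation`` plus the positive-area
    summary in ``df.attrs["positive_area"]`` (sum of positive violations
    times the quantile step).
    """
    for arr in (rt_t, rt_v, rt_vt):
        if np.asarray(arr).size == 0:
            raise ValueError("empty RT set")
    if quantiles is None:
        quantiles = np.arange(0.05, 0.951, 0.05)
    q = np.asarray(quantiles, dtype=float)
    t_q = np.quantile(np.asarray(rt_vt, float), q)
    f_vt = _ecdf(np.asarray(rt_vt, float), t_q)
    bound = np.minimum(1.0, _ecdf(np.asarray(rt_t, float), t_q) + _ecdf(np.asarray(rt_v, float), t_q))
    viol = f_vt - bound
    df = pd.DataFrame({"quantile": q, "t": t_q, "F_vt": f_vt, "bound": bound, "violation": viol})
    step = np.diff(q).mean() if q.size > 1 else 1.0
    df.attrs["positive_area"] = float(np.clip(viol, 0, None).sum() * step)
    return df


def rt_summary(rt_sets: list[RTSet]) -> pd.DataFrame:
    """Per-condition summary table: ``subject, site, condition, n, mean, sd``."""
    return pd.DataFrame(
        [
            {
                "subject": s.subject, "site": s.site, "condition": s.condition,
                "n": s.n_valid, "mean": float(s.values.mean()),
                "sd": float(s.values.std(ddof=1)) if s.n_valid > 1 else 0.0,
            }
            for s in rt_sets
        ]
    )
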