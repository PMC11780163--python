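"""Bootstrap and group-level inference for psychometric thresholds.

Intra-subject uncertainty on PSE/JND uses a parametric bootstrap "with x
fixed": binary responses are redrawn at the original comparison levels from
the fitted probit model, the model is refitted, and the statistic recorded.
Pairwise p-values come from inverting the percentile bootstrap confidence
interval of the difference — the smallest alpha whose equi-tailed (1-alpha)
interval excludes zero — and are adjusted across each comparison family by
the Benjamini–Hochberg false-discovery-rate step-up.

Group-level (inter-subject) contracts route by normality: a
Kolmogorov–Smirnov check sends the per-subject condition matrix to a
repeated-measures ANOVA with unadjusted (LSD) paired post hocs when normal,
or to a Friedman test with Wilcoxon post hocs otherwise; two paired samples
go to a paired t / Wilcoxon signed-rank directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cue_combination import predicted_bimodal_jnd
from .psychometrics import PsychometricFit, Z84, batch_fit_probit

__all__ = [
    "BootstrapResult",
    "PairwiseTest",
    "parametric_bootstrap",
    "invert_ci_pvalue",
    "fdr_adjust",
    "pairwise_jnd_tests",
    "group_tests",
    "cohens_d_paired",
]


@dataclass
class BootstrapResult:
    """Bootstrap distribution of one statistic (PSE or JND)."""

    statistic: str
    point_estimate: float
    samples: np.ndarray = field(repr=False)
    ci_low: float
    ci_high: float
    level: float
    n_failed_refits: int


@dataclass
class PairwiseTest:
    """CI-inversion test of one bootstrap difference distribution."""

    pair: str
    diff_samples: np.ndarray = field(repr=False)
    p_raw: float
    p_fdr: float = np.nan


def parametric_bootstrap(
    fit: PsychometricFit,
    B: int = 5000,
    seed: int = 0,
    *,
    level: float = 0.95,
    max_failed_frac: float = 0.20,
) -> dict[str, BootstrapResult]:
    """Parametric bootstrap (x fixed) of the PSE and JND of one fit.

    For each of ``B`` replicates, responses at every comparison level ``x``
    are drawn Binomial(n_x, Phi(b0 + b1 x)) from the fitted coefficients and
    the probit model refitted.  Replicates whose refit separates or fails to
    converge are dropped (and counted); survivors keep their draw order.

    Raises
    ------
    ValueError
        Non-converged base fit, or more than ``max_failed_frac`` of the
        replicates failing to refit (the design is too small for bootstrap
        inference).
    """
    if not fit.converged:
        raise ValueError("parametric bootstrap requires a converged base fit")
    x, n = fit.levels, fit.n_per_level
    if x is None or n is None:
        raise ValueError("fit carries no level table; refit from trials")
    rng = np.random.default_rng(seed)
    p = stats.norm.cdf(fit.beta0 + fit.beta1 * x)

    if B > 0:
        k = rng.binomial(n.astype(int), p, size=(B, x.size)).astype(float)
        beta, _, _, ok = batch_fit_probit(x, n, k)
        n_failed = int(B - ok.sum())
        if B > 0 and n_failed > max_failed_frac * B:
            raise ValueError(
                f"{n_failed}/{B} bootstrap refits failed; the stimulus design is "
                "too small or the fit too extreme for bootstrap inference"
            )
        b0, b1 = beta[ok, 0], beta[ok, 1]
        pse_s = -b0 / b1
        jnd_s = Z84 / b1
    else:
        n_failed = 0
        pse_s = np.empty(0)
        jnd_s = np.empty(0)

    out = {}
    for name, point, samples in (
        ("pse", fit.pse, pse_s),
        ("jnd", fit.jnd, jnd_s),
    ):
        if samples.size:
            lo, hi = np.percentile(samples, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
        else:
            lo = hi = np.nan
        out[name] = BootstrapResult(
            statistic=name, point_estimate=float(point), samples=samples,
            ci_low=float(lo), ci_high=float(hi), level=level, n_failed_refits=n_failed,
        )
    return out


def invert_ci_pvalue(diff_samples: np.ndarray) -> float:
    """p-value of a bootstrap difference by percentile-CI inversion.

    The smallest alpha whose equi-tailed (1-alpha) percentile interval of
    the difference excludes zero: ``p = 2 * min(#{d <= 0}, #{d >= 0}) / B``,
    floored at ``2/B`` (the inversion cannot resolve below it) and capped
    at 1.
    """
    d = np.asarray(diff_samples, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference sample")
    B = d.size
    p = 2.0 * min((d <= 0).sum(), (d >= 0).sum()) / B
    return float(min(max(p, 2.0 / B), 1.0))


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # enforce monotonicity from largest rank down
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def _trim_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = min(a.size, b.size)
    return a[:n], b[:n]


def pairwise_jnd_tests(
    boots: dict[str, dict[str, BootstrapResult]],
    *,
    statistic: str = "jnd",
) -> dict[str, PairwiseTest]:
    """The per-site family of JND comparisons used to judge integration.

    ``boots`` maps condition name ("T", "VB", "VTB") to the bootstrap
    results of that condition's fit.  Builds the replicate-paired difference
    distributions for T-VTB, VB-VTB, VTB-MLE and T-VB, where the MLE
    replicate is the optimal combination of the T and VB replicates, then
    applies CI-inversion p-values and BH-FDR across the family.
    """
    for cond in ("T", "VB", "VTB"):
        if cond not in boots:
            raise ValueError(f"missing bootstrap for condition {cond!r}")
    t = boots["T"][statistic].samples
    vb = boots["VB"][statistic].samples
    vtb = boots["VTB"][statistic].samples
    t_m, vb_m = _trim_pair(t, vb)
    mle = np.array([predicted_bimodal_jnd(v, u) for v, u in zip(vb_m, t_m)])

    pairs = {
        "T_VTB": _sub(t, vtb),
        "VB_VTB": _sub(vb, vtb),
        "VTB_MLE": _sub(vtb, mle),
        "T_VB": _sub(t, vb),
    }
    tests = {
        name: PairwiseTest(pair=name, diff_samples=d, p_raw=invert_ci_pvalue(d))
        for name, d in pairs.items()
    }
    adj = fdr_adjust([tests[k].p_raw for k in tests])
    for tt, q in zip(tests.values(), adj):
        tt.p_fdr = float(q)
    return tests


def _sub(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a, b = _trim_pair(a, b)
    return a - b


def cohens_d_paired(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d for a paired contrast: mean difference / SD of differences."""
    d = np.asarray(a, float) - np.asarray(b, float)
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
    return float(d.mean() / sd)


def _ks_normal(v: np.ndarray) -> tuple[float, float]:
    v = np.asarray(v, float)
    s = v.std(ddof=1)
    if s == 0:
        return 0.0, 1.0
    stat, p = stats.kstest((v - v.mean()) / s, "norm")
    return float(stat), float(p)


def group_tests(per_subject_values: pd.DataFrame, *, alpha: float = 0.05) -> dict:
    """Group-level test report for a complete subjects x conditions matrix.

    Routing follows the study's contract: Kolmogorov–Smirnov normality per
    condition; if every condition is consistent with normality the omnibus
    is a repeated-measures ANOVA, otherwise a Friedman test; with exactly
    two conditions a paired t (normal) or Wilcoxon signed-rank
    (non-normal).  Post hocs are unadjusted (LSD-style) paired contrasts
    run after a significant omnibus, with Cohen's d reported.

    Returns a JSON-serializable dict:
    ``{normality, omnibus: {test, stat, p}, posthoc: [{pair, p, cohens_d}]}``.
    """
    df = pd.DataFrame(per_subject_values)
    if df.isna().any().any():
        raise ValueError("missing cells in the per-subject condition matrix; no imputation")
    conds = list(df.columns)
    if len(conds) < 2:
        raise ValueError("need at least two conditions")

    normality = {c: dict(zip(("stat", "p"), _ks_normal(df[c].to_numpy()))) for c in conds}
    normal = all(v["p"] >= alpha for v in normality.values())

    cols = [df[c].to_numpy(float) for c in conds]
    if len(conds) == 2:
        if normal:
            stat, p = stats.ttest_rel(cols[0], cols[1])
            omnibus = {"test": "paired_t", "stat": float(stat), "p": float(p)}
        else:
            if np.all(cols[0] == cols[1]):
                omnibus = {"test": "wilcoxon", "stat": 0.0, "p": 1.0}
            else:
                stat, p = stats.wilcoxon(cols[0], cols[1])
                omnibus = {"test": "wilcoxon", "stat": float(stat), "p": float(p)}
        posthoc = [
            {
                "pair": f"{conds[0]}_{conds[1]}",
                "p": omnibus["p"],
                "cohens_d": cohens_d_paired(cols[0], cols[1]),
            }
        ]
        return {"normality": normality, "omnibus": omnibus, "posthoc": posthoc}

    if normal:
        long = df.reset_index(names="subject").melt(
            id_vars="subject", var_name="condition", value_name="value"
        )
        from statsmodels.stats.anova import AnovaRM

        res = AnovaRM(long, "value", "subject", within=["condition"]).fit()
        row = res.anova_table.iloc[0]
        omnibus = {"test": "rm_anova", "stat": float(row["F Value"]), "p": float(row["Pr > F"])}
    else:
        if all(np.all(c == cols[0]) for c in cols[1:]):
            omnibus = {"test": "friedman", "stat": 0.0, "p": 1.0}
        else:
            stat, p = stats.friedmanchisquare(*cols)
            omnibus = {"test": "friedman", "stat": float(stat), "p": float(p)}

    posthoc = []
    if omnibus["p"] < alpha:
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                a, b = cols[i], cols[j]
                if normal:
                    _, p = stats.ttest_rel(a, b)
                elif np.all(a == b):
                    p = 1.0
                else:
                    _, p = stats.wilcoxon(a, b)
                posthoc.append(
                    {
                        "pair": f"{conds[i]}_{conds[j]}",
                        "p": float(p),
                        "cohens_d": cohens_d_paired(a, b),
                    }
                )
    return {"normality": normality, "omnibus": omnibus, "posthoc": posthoc}
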