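"""Maximum-likelihood (optimal) cue combination for visuo-tactile percepts.

Under the Ernst–Banks MLE model, the bimodal percept is a reliability-weighted
average of the unimodal estimates,

    s_vt = w_v s_v + w_t s_t,      w_i = R_i / (R_v + R_t),  R_i = 1/sigma_i^2,

and the combined variance is lower than either single cue:

    sigma_vt^2 = sigma_v^2 sigma_t^2 / (sigma_v^2 + sigma_t^2).

Because the JND is proportional to sigma (JND = Phi^-1(0.84) * sigma), the
variance-combination formula applies verbatim in JND units: it is homogeneous
of degree 2, so the z84 factors cancel.  All routines below therefore accept
and return JNDs in seconds.

`classify_integration` reproduces the operational decision rule used to call
an observer an optimal integrator from bootstrap pairwise tests: the bimodal
JND must sit significantly below both unimodal JNDs while not exceeding the
MLE prediction; a significant unimodal reliability difference (T vs VB)
triggers the winner-take-all regime where one cue dominates and the test is
uninformative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "CueWeights",
    "MLEPrediction",
    "IntegrationClass",
    "optimal_weights",
    "predicted_bimodal_jnd",
    "predicted_bimodal_pse",
    "predict_mle",
    "classify_integration",
]


@dataclass(frozen=True)
class CueWeights:
    """Reliability weights of the visual and tactile cue (sum to 1)."""

    w_v: float
    w_t: float


@dataclass(frozen=True)
class MLEPrediction:
    """Predicted bimodal JND/PSE from two unimodal fits."""

    predicted_jnd: float
    predicted_pse: float
    jnd_v: float
    jnd_t: float
    pse_v: float
    pse_t: float
    weights: CueWeights


class IntegrationClass(str, Enum):
    OPTIMAL = "optimal"
    NO_INTEGRATION = "no_integration"
    WINNER_TAKE_ALL = "winner_take_all"
    INDETERMINATE = "indeterminate"


def optimal_weights(jnd_v: float, jnd_t: float) -> CueWeights:
    """Reliability weights from unimodal JNDs (reliability = 1/JND^2).

    JND is proportional to sigma, so reliabilities expressed in JND units
    are proportional to those in sigma units and the weights are identical.
    """
    if jnd_v <= 0 or jnd_t <= 0:
        raise ValueError("JNDs must be positive")
    r_v, r_t = 1.0 / jnd_v**2, 1.0 / jnd_t**2
    return CueWeights(w_v=r_v / (r_v + r_t), w_t=r_t / (r_v + r_t))


def predicted_bimodal_jnd(jnd_v: float, jnd_t: float) -> float:
    """Optimal combined JND: sqrt(jv^2 jt^2 / (jv^2 + jt^2)).

    Strictly below min(jnd_v, jnd_t) for finite positive inputs; the benefit
    is largest (a factor 1/sqrt(2)) when the cues are equally reliable.
    """
    if jnd_v <= 0 or jnd_t <= 0:
        raise ValueError("JNDs must be positive")
    return math.sqrt(jnd_v**2 * jnd_t**2 / (jnd_v**2 + jnd_t**2))


def predicted_bimodal_pse(pse_v: float, pse_t: float, weights: CueWeights) -> float:
    """Reliability-weighted average of the unimodal PSEs."""
    return weights.w_v * pse_v + weights.w_t * pse_t


def predict_mle(jnd_v, jnd_t, pse_v, pse_t) -> MLEPrediction:
    """Full MLE prediction (weights, combined JND and PSE) from unimodal fits."""
    w = optimal_weights(jnd_v, jnd_t)
    return MLEPrediction(
        predicted_jnd=predicted_bimodal_jnd(jnd_v, jnd_t),
        predicted_pse=predicted_bimodal_pse(pse_v, pse_t, w),
        jnd_v=jnd_v, jnd_t=jnd_t, pse_v=pse_v, pse_t=pse_t, weights=w,
    )


def classify_integration(
    jnd_t: float,
    jnd_vb: float,
    jnd_vtb: float,
    jnd_mle: float,
    tests: dict,
    *,
    alpha: float = 0.05,
) -> tuple[IntegrationClass, bool]:
    """Classify one site's integration outcome from FDR-adjusted pairwise tests.

    Parameters
    ----------
    tests : mapping with keys ``"T_VTB"``, ``"VB_VTB"``, ``"VTB_MLE"``,
        ``"T_VB"``; values expose ``p_fdr`` (PairwiseTest) or are bare
        p-values.

    Returns
    -------
    (label, super_optimal) : the integration class, plus a flag set when
        the observed bimodal JND is significantly *below* the MLE
        prediction while still meeting the optimality criteria
        (super-optimal performance, as seen in one amputee).
    """
    required = ("T_VTB", "VB_VTB", "VTB_MLE", "T_VB")
    missing = [kk for kk in required if kk not in tests]
    if missing:
        raise ValueError(f"missing pairwise tests: {missing}")

    def p(key):
        t = tests[key]
        return t.p_fdr if hasattr(t, "p_fdr") else float(t)

    if p("T_VB") < alpha:
        return IntegrationClass.WINNER_TAKE_ALL, False

    below_t = p("T_VTB") < alpha and jnd_vtb < jnd_t
    below_vb = p("VB_VTB") < alpha and jnd_vtb < jnd_vb
    mle_differs = p("VTB_MLE") < alpha

    if below_t and below_vb:
        super_optimal = mle_differs and jnd_vtb < jnd_mle
        if not mle_differs or super_optimal:
            return IntegrationClass.OPTIMAL, super_optimal
        return IntegrationClass.INDETERMINATE, False
    if not below_t and not below_vb and p("T_VTB") >= alpha and p("VB_VTB") >= alpha:
        return IntegrationClass.NO_INTEGRATION, False
    return IntegrationClass.INDETERMINATE, False
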