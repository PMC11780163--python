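"""Synthetic observers, reaction times and EEG with known ground truth.

The study this package analyses — a 2AFC vibration-period discrimination
task under unimodal (visual, tactile) and bimodal (visuo-tactile) conditions,
with EEG recorded throughout — has no publicly deposited raw data.  This
module generates all of it with planted parameters so every downstream stage
(psychometric fitting, cue combination, bootstrap inference, race-model and
workload analysis) can be validated by parameter recovery:

* a stimulus design of comparison periods around a fixed reference,
* binomial 2AFC responses from probit observers with specified PSE/JND per
  condition; bimodal conditions can follow the optimal MLE combination of
  the unimodal entries, copy a single cue, or average without benefit,
* shifted-lognormal reaction times with a bimodal facilitation factor,
  generated either through a single facilitated channel (coactivation; a
  known race-model violator) or a two-channel independent race (a known
  race-model satisfier),
* multichannel EEG built from 1/f background noise plus band-limited alpha
  and theta oscillations with planted powers and a planted individual alpha
  frequency (IAF).

All randomness flows through one explicit seed per call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .cue_combination import optimal_weights, predicted_bimodal_jnd, predicted_bimodal_pse
from .psychometrics import Z84

__all__ = [
    "StimulusDesign",
    "TrialPair",
    "ObserverSpec",
    "RTParams",
    "EEGParams",
    "TrialRecord",
    "EEGRecording",
    "build_stimulus_design",
    "effective_params",
    "simulate_observer_responses",
    "simulate_reaction_times",
    "simulate_rt_condition_sets",
    "simulate_eeg",
    "SMARTING_24_CHANNELS",
    "FRONTAL_CHANNELS",
    "PARIETAL_CHANNELS",
]

#: 24-channel 10-20 montage of the portable amplifier used in the study.
SMARTING_24_CHANNELS = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz", "M1",
    "M2", "AFz", "CPz", "POz",
]
FRONTAL_CHANNELS = ("Fz", "F7", "F8")
PARIETAL_CHANNELS = ("Pz", "P3", "P4")

BIMODAL_SOURCES = {"VT": ("V", "T"), "VTB": ("VB", "T")}


@dataclass(frozen=True)
class StimulusDesign:
    """Comparison-period ladder around a fixed reference.

    Defaults reproduce the study's design: reference period 0.24442 s,
    three steps down of 0.05555 s, five steps up of 0.07777 s, each of the
    nine resulting levels paired with the reference ten times (90 pairs).
    """

    reference_period: float = 0.24442
    step_down: float = 0.05555
    step_up: float = 0.07777
    n_down: int = 3
    n_up: int = 5
    n_reps: int = 10

    def __post_init__(self):
        if self.reference_period <= 0 or self.step_down <= 0 or self.step_up <= 0:
            raise ValueError("periods and steps must be positive")
        if self.n_down < 0 or self.n_up < 0 or self.n_reps < 0:
            raise ValueError("counts must be non-negative")
        if self.n_down * self.step_down >= self.reference_period:
            raise ValueError("stepping down crosses zero: non-positive comparison period")

    def levels(self) -> np.ndarray:
        """The n_down + 1 + n_up distinct comparison periods, ascending."""
        down = self.reference_period - self.step_down * np.arange(self.n_down, 0, -1)
        up = self.reference_period + self.step_up * np.arange(1, self.n_up + 1)
        return np.concatenate([down, [self.reference_period], up])


@dataclass(frozen=True)
class TrialPair:
    """One 2AFC presentation: the reference and one comparison level."""

    comparison_period: float
    reference_period: float
    comparison_first: bool


def build_stimulus_design(design: StimulusDesign, seed: int) -> list[TrialPair]:
    """Expand a design into a randomized list of trial pairs.

    Each distinct level (the reference itself included) is paired with the
    reference ``n_reps`` times; pair order and the within-pair presentation
    order are both randomized under the supplied seed.
    """
    rng = np.random.default_rng(seed)
    levels = np.repeat(design.levels(), design.n_reps)
    rng.shuffle(levels)
    first = rng.random(levels.size) < 0.5
    return [
        TrialPair(float(lv), design.reference_period, bool(f))
        for lv, f in zip(levels, first)
    ]


@dataclass(frozen=True)
class RTParams:
    """Shifted-lognormal reaction-time generator parameters (seconds).

    ``rt = shift + exp(N(log_mean, log_sd))`` for unimodal conditions;
    bimodal conditions multiply the lognormal component by
    ``bimodal_facilitation`` (1 = no benefit).  ``architecture`` selects the
    generating mechanism for bimodal trials: ``"facilitated"`` (a single
    coactivated channel — violates the race-model bound) or ``"race"``
    (minimum of two independent channel latencies — satisfies it).
    """

    shift: float = 0.2
    log_mean: float = float(np.log(0.5))
    log_sd: float = 0.35
    bimodal_facilitation: float = 0.75
    architecture: str = "facilitated"

    def __post_init__(self):
        if not (0.0 < self.bimodal_facilitation <= 1.0):
            raise ValueError("bimodal_facilitation must be in (0, 1]")
        if self.architecture not in ("facilitated", "race"):
            raise ValueError("architecture must be 'facilitated' or 'race'")


@dataclass(frozen=True)
class EEGParams:
    """Planted-spectrum EEG parameters.

    ``iaf`` is the individual alpha frequency in Hz (must lie in the
    detection window [7.5, 12.5]); powers are oscillation variances in
    microvolt^2; ``noise_level`` is the RMS of the 1/f background in
    microvolts (default keeps in-band SNR well above 10).
    """

    iaf: float = 10.0
    frontal_theta_power: float = 2.0
    parietal_alpha_power: float = 1.0
    noise_exponent: float = 1.0
    noise_level: float = 0.1


@dataclass(frozen=True)
class ObserverSpec:
    """Ground truth for one synthetic observer.

    ``conditions`` maps condition name -> (pse, jnd) in seconds for the
    conditions the observer has explicit parameters for (normally the
    unimodal V, T, VB).  Bimodal conditions (VT, VTB) are derived from the
    unimodal entries according to ``integration_mode`` unless given
    explicitly.
    """

    conditions: dict = field(default_factory=dict)
    integration_mode: str = "optimal"
    rt_params: RTParams = field(default_factory=RTParams)
    eeg_params: EEGParams = field(default_factory=EEGParams)
    subject_id: str = "sim"
    group: str = "healthy"

    def __post_init__(self):
        for cond, (pse, jnd) in self.conditions.items():
            if jnd <= 0:
                raise ValueError(f"JND must be positive for condition {cond!r}")
        if self.integration_mode not in (
            "optimal", "single_cue_visual", "single_cue_tactile", "non_integrating"
        ):
            raise ValueError(f"unknown integration_mode {self.integration_mode!r}")
        if not (7.5 <= self.eeg_params.iaf <= 12.5):
            raise ValueError("iaf must lie in [7.5, 12.5] Hz")


def effective_params(spec: ObserverSpec, condition: str) -> tuple[float, float]:
    """(pse, jnd) the observer actually follows in ``condition``.

    Bimodal conditions not listed explicitly are derived from their source
    cues: optimal observers combine per the MLE model (reliability-weighted
    PSE, variance-combined JND), single-cue observers copy the named cue,
    and non-integrating observers average the two cues without any
    variance reduction.
    """
    if condition in spec.conditions:
        return spec.conditions[condition]
    if condition not in BIMODAL_SOURCES:
        raise KeyError(f"condition {condition!r} not in observer spec")
    vis_name, tac_name = BIMODAL_SOURCES[condition]
    try:
        pse_v, jnd_v = spec.conditions[vis_name]
        pse_t, jnd_t = spec.conditions[tac_name]
    except KeyError as e:
        raise KeyError(
            f"bimodal condition {condition!r} needs unimodal entries "
            f"{vis_name!r} and {tac_name!r}"
        ) from e
    mode = spec.integration_mode
    if mode == "optimal":
        w = optimal_weights(jnd_v, jnd_t)
        return predicted_bimodal_pse(pse_v, pse_t, w), predicted_bimodal_jnd(jnd_v, jnd_t)
    if mode == "single_cue_visual":
        return pse_v, jnd_v
    if mode == "single_cue_tactile":
        return pse_t, jnd_t
    # non_integrating: percept bounces between cues; no precision benefit
    return (pse_v + pse_t) / 2.0, (jnd_v + jnd_t) / 2.0


@dataclass
class TrialRecord:
    """One 2AFC trial of one observer."""

    subject_id: str
    group: str
    site: str
    condition: str
    comparison_period: float
    reference_period: float
    response_comparison_longer: bool
    rt: float | None = None

    @property
    def response(self) -> int:
        return int(self.response_comparison_longer)


def simulate_observer_responses(
    pairs: list[TrialPair],
    spec: ObserverSpec,
    condition: str,
    seed: int,
    *,
    site: str = "L1",
    longer_convention: bool = True,
) -> list[TrialRecord]:
    """Draw Bernoulli 2AFC responses from a probit observer.

    P(judge comparison longer | x) = Phi((x - pse)/sigma) with
    sigma = jnd / Phi^-1(0.84), so x = pse gives exactly p = 0.5 and
    x = pse + jnd gives p = 0.84.  ``longer_convention=False`` flips the
    response coding to "comparison faster" (higher frequency = shorter
    period), the instruction actually given to subjects.
    """
    pse, jnd = effective_params(spec, condition)
    sigma = jnd / Z84
    rng = np.random.default_rng(seed)
    x = np.array([p.comparison_period for p in pairs])
    prob_longer = norm.cdf((x - pse) / sigma)
    p_resp = prob_longer if longer_convention else 1.0 - prob_longer
    resp = rng.random(x.size) < p_resp
    return [
        TrialRecord(
            subject_id=spec.subject_id, group=spec.group, site=site,
            condition=condition, comparison_period=pair.comparison_period,
            reference_period=pair.reference_period,
            response_comparison_longer=bool(r),
        )
        for pair, r in zip(pairs, resp)
    ]


def _draw_rts(n: int, params: RTParams, bimodal: bool, rng) -> np.ndarray:
    if not bimodal:
        return params.shift + rng.lognormal(params.log_mean, params.log_sd, n)
    if params.architecture == "race":
        lat = rng.lognormal(params.log_mean, params.log_sd, (2, n))
        return params.shift + lat.min(axis=0)
    # single facilitated (coactivated) channel
    return params.shift + params.bimodal_facilitation * rng.lognormal(
        params.log_mean, params.log_sd, n
    )


def simulate_reaction_times(
    records: list[TrialRecord], spec: ObserverSpec, seed: int
) -> list[TrialRecord]:
    """Fill the ``rt`` field of simulated trials in place (and return them)."""
    rng = np.random.default_rng(seed)
    bimodal = np.array([r.condition in BIMODAL_SOURCES for r in records])
    rts = np.empty(len(records))
    if (~bimodal).any():
        rts[~bimodal] = _draw_rts(int((~bimodal).sum()), spec.rt_params, False, rng)
    if bimodal.any():
        rts[bimodal] = _draw_rts(int(bimodal.sum()), spec.rt_params, True, rng)
    for r, t in zip(records, rts):
        r.rt = float(t)
    return records


def simulate_rt_condition_sets(
    n: int, params: RTParams, seed: int
) -> dict[str, np.ndarray]:
    """Raw RT samples for the T, VB and VTB conditions of one site.

    Unimodal sets are single-channel shifted lognormals; the bimodal set
    follows ``params.architecture``.  Convenience entry point for the
    race-model analysis.
    """
    rng = np.random.default_rng(seed)
    return {
        "T": _draw_rts(n, params, False, rng),
        "VB": _draw_rts(n, params, False, rng),
        "VTB": _draw_rts(n, params, True, rng),
    }


@dataclass
class EEGRecording:
    """Multichannel EEG (microvolts) with a stimulus-onset event stream."""

    channel_names: list[str]
    sampling_rate: float
    data: np.ndarray  # channels x samples
    events: list[tuple[int, str, str]]  # (sample_index, site, condition)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


def _one_over_f_noise(n_samples, n_channels, exponent, rms, rng, fs):
    """Gaussian noise with amplitude spectrum ~ 1/f^(exponent/2), unit-free RMS."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * rms


def simulate_eeg(
    spec: ObserverSpec,
    events: list[tuple[int, str, str]],
    duration: float,
    seed: int,
    *,
    sampling_rate: float = 500.0,
    epoch_duration: float = 1.75,
) -> EEGRecording:
    """Synthesize a 24-channel recording with planted alpha/theta oscillations.

    Each channel is 1/f^exponent Gaussian noise.  A sinusoid at the planted
    IAF rides on the parietal channels (Pz, P3, P4) with variance equal to
    ``parietal_alpha_power``; a theta sinusoid at IAF - 4 Hz (the centre of
    the individualized theta band) rides on the frontal channels (Fz, F7,
    F8) with variance ``frontal_theta_power``.  Oscillations share one phase
    across their channels so common-average referencing rescales frontal and
    parietal oscillations by the same factor and leaves their power ratio
    intact.
    """
    p = spec.eeg_params
    if not (7.5 <= p.iaf <= 12.5):
        raise ValueError("iaf must lie in [7.5, 12.5] Hz")
    n_samples = int(round(duration * sampling_rate))
    need = int(round(epoch_duration * sampling_rate))
    for s, _, _ in events:
        if s + need > n_samples:
            raise ValueError(f"event at sample {s} leaves less than {epoch_duration} s of signal")

    rng = np.random.default_rng(seed)
    names = list(SMARTING_24_CHANNELS)
    data = _one_over_f_noise(n_samples, len(names), p.noise_exponent, p.noise_level, rng, sampling_rate)

    t = np.arange(n_samples) / sampling_rate
    phase_a, phase_t = rng.uniform(0, 2 * np.pi, 2)
    alpha = np.sqrt(2.0 * p.parietal_alpha_power) * np.sin(2 * np.pi * p.iaf * t + phase_a)
    theta = np.sqrt(2.0 * p.frontal_theta_power) * np.sin(
        2 * np.pi * (p.iaf - 4.0) * t + phase_t
    )
    for ch in PARIETAL_CHANNELS:
        data[names.index(ch)] += alpha
    for ch in FRONTAL_CHANNELS:
        data[names.index(ch)] += theta
    return EEGRecording(names, sampling_rate, data, list(events))
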