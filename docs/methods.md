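# Methods

## The observer model

All psychometric machinery assumes a Gaussian (probit) 2AFC observer: the
internal estimate of a comparison period `x` is normally distributed around
`x` with noise σ, so the probability of judging the comparison longer than
the reference is `Φ((x − PSE)/σ)`. Two summaries parameterize each curve:

* **PSE** — the period at the 50% point, `−β₀/β₁` for the fitted
  `Φ(β₀ + β₁x)`.
* **JND** — the increment from the PSE to the 84% point,
  `z₈₄/β₁` with `z₈₄ = Φ⁻¹(0.84) ≈ 0.994458` (kept at full double
  precision; the 84% convention makes JND = σ exactly).

The synthetic generator inverts the same model (`σ = JND/z₈₄`), so
`x = PSE` yields p = 0.5 and `x = PSE + JND` yields p = 0.84 by
construction. Subjects in such tasks are typically instructed in terms of
"faster" (shorter period); the generator codes responses on the
longer-period convention and exposes `longer_convention=False` to flip it —
the fitted JND is invariant to the choice, the curve is simply mirrored.

## Fitting

`fit_probit` maximizes the Bernoulli likelihood by Fisher scoring (IRLS) on
per-level binomial counts, converging when the relative log-likelihood
change drops below 1e−10 (max 100 iterations). The solver is written in
batched form — B response tables sharing one design are fitted at once with
closed-form 2×2 weighted least-squares updates — because the parametric
bootstrap refits thousands of tables per condition; a full 500-replicate
bootstrap costs a few milliseconds. The implementation is cross-checked in
the test suite against statsmodels' GLM with a probit link (agreement to
~1e−5) and against a brute-force likelihood grid search.

Degenerate tables are handled deterministically: all-identical responses
raise; completely separated tables (no mixed level, responses monotone in
x) have no finite ML slope and return a flagged infinite-slope sentinel
that bootstrap machinery counts and drops. This matters because resampled
replicates can separate even when the original data do not.

## Cue combination

Reliabilities are inverse variances, `Rᵢ = 1/σᵢ²`; weights
`w_v = R_v/(R_v + R_t)`; combined variance
`σ_vt² = σ_v²σ_t²/(σ_v² + σ_t²)`. Because JND ∝ σ and the formula is
homogeneous of degree 2, it is applied directly in JND units:
`JND_vt = √(J_v²J_t²/(J_v² + J_t²))`, strictly below `min(J_v, J_t)`,
symmetric, and scale-equivariant. The predicted bimodal PSE is the
reliability-weighted average of the unimodal PSEs — the model's own
prediction, kept for generator self-consistency even though the empirical
analysis compares JNDs only.

### Classification rule

Given FDR-adjusted pairwise bootstrap tests at α = 0.05:

* **winner-take-all** if the two unimodal JNDs (T vs VB) differ
  significantly — one cue dominates and the optimality test is
  uninformative;
* **optimal** if the bimodal JND is significantly below both unimodal JNDs
  and does not significantly exceed the MLE prediction. An observed JND
  significantly *below* the prediction is still labelled optimal, with a
  `super_optimal` flag (observed super-optimality does occur empirically
  and meeting the operational criteria is what the label tracks);
* **no integration** if the bimodal JND differs from neither unimodal JND;
* **indeterminate** otherwise.

## Bootstrap inference

The parametric bootstrap holds the design fixed: at every comparison level
x, responses are redrawn `Binomial(n_x, Φ(β̂₀ + β̂₁x))` and the model
refitted; failed refits are dropped (never redrawn — the survivor order is
preserved and the count reported; >20% failures aborts with advice to
enlarge the design). CIs are equi-tailed percentiles. The p-value of a
difference is the CI inversion `p = max(2·min(#{d≤0}, #{d≥0})/B, 2/B)` —
the smallest α whose (1−α) percentile interval excludes zero, floored at
2/B where the inversion loses resolution. Families of comparisons
(T−VTB, VB−VTB, VTB−MLE, T−VB per site) are adjusted by Benjamini–Hochberg;
the per-replicate MLE value is the optimal combination of that replicate's
T and VB JNDs, which is why its bootstrap mean sits a few percent off the
plug-in value computed from the point estimates.

**Calibration.** Verified by simulation in the test suite: at 900
trials/condition the 95% percentile CI covers the true JND in ≈95% of
runs; at the 90-trial design coverage is ≈91–93% (the interval inherits
the small-sample bias of the ML slope — misses are almost exclusively when
the JND is underestimated), and the CI-inversion test's type-I error at
α = 0.05 is ≈0.05–0.08. Users drawing inferences from 90-trial sessions
should treat the nominal 95% level as approximate.

**Test sizing.** The end-to-end classification check uses the 9-level
design with 100 repetitions per level (900 trials/condition). A Fisher
information power analysis shows why: the relative SE of a fitted JND at 90
trials is ≈19%, so the √2 bimodal benefit of an equal-reliability optimal
integrator is a ≈1.2 SE effect — per-comparison power below 25%, far too
low for any classifier built on significance at α = 0.05. At 900 trials
the effect is ≈3.9 SE and both synthetic observer types are classified
correctly in ≥90% of runs.

## Group-level tests

Per-subject condition matrices route by a Kolmogorov–Smirnov normality
check (on standardized values, per condition): normal → repeated-measures
ANOVA (statsmodels) with unadjusted ("LSD") paired-t post hocs after a
significant omnibus; non-normal → Friedman with Wilcoxon signed-rank post
hocs; exactly two conditions → paired t or Wilcoxon directly. Cohen's d for
paired contrasts is mean(difference)/SD(difference). Missing cells raise —
no imputation. Identical columns short-circuit to a null result (χ² = 0,
p = 1) rather than erroring in scipy.

## Reaction times

RT = keypress − second-stimulus offset; anticipations are invalid.
Cleaning is exactly two passes, in order, each run once: (1) discard
values > 5 s; (2) discard values more than 3 SD from the mean of the
survivors. The second pass is not iterated, so the filter is idempotent
only when the cleaned sample has no value near the 3 SD criterion.
Equalizing counts across conditions (for the paired Friedman test) uses
seeded random subsampling to the smallest valid count rather than
truncation, avoiding time-on-task bias; the rule is a package choice.

The race-model analysis evaluates the Miller bound
`B(t) = min(1, F_T(t) + F_V(t))` from right-continuous empirical CDFs at
the empirical quantiles of the bimodal distribution (default 0.05–0.95,
step 0.05); `violation(q) = F_VT(t_q) − B(t_q)`, with a positive-area
summary (sum of positive violations × quantile step). The quantile grid,
statistic and absence of kill-the-twin corrections are standard choices
where the upstream procedure is not fully specified. The synthetic
generators provide both signatures: a coactivated (single facilitated
channel) bimodal condition violates the bound at early quantiles; an
independent two-channel race satisfies it by construction.

## EEG workload

Pipeline: Hamming windowed-sinc FIR band-pass 0.5–42 Hz, order 8000
(linear phase, applied centred so group delay is exactly compensated);
common-average reference; 1.75 s epochs from each stimulus onset (875
samples at 500 Hz, half-open window, no baseline correction); Welch PSD
per channel with Hamming segments of 437 samples (875 ms rounded down;
configurable to 438), 50% overlap, FFT length 1024 (resolution 500/1024 ≈
0.488 Hz).

* **IAF** — argmax of the pooled mean PSD in 7.5–12.5 Hz, estimated once
  per subject. Default channels are the parietal trio (Pz, P3, P4):
  alpha is a posterior rhythm, and including frontal electrodes lets a
  strong theta peak above 7.5 Hz hijack the search (demonstrably so for a
  planted IAF of 12 Hz with a 2:1 θ/α ratio). Configurable via
  `iaf_channels`.
* **Band power** — *integrated* PSD (bin sum × Δf) over bins with centre
  frequency in [low, high). Integration, not mean density: a 4 Hz band
  spans 8.192 bins on the 0.488 Hz grid, so the θ window always holds 8
  bins and the IAF-centred α window 9 — a mean-density ratio is
  systematically inflated by 9/8 (~12.5%), while the integral is immune
  and leakage (confined well within each 4 Hz band) cancels in the ratio.
* **Workload** — θ power averaged over Fz/F7/F8 divided by α power over
  Pz/P3/P4, per epoch; condition-level values average epochs after
  removing per-epoch workloads more than 3 SD from the mean.
* **Artifacts** — ICA or any other artifact pass is a caller-supplied hook
  (`artifact_hook`) on the continuous data; the package does not decompose.

## Synthetic data: what it does and does not emulate

Defaults mirror the study conditions: reference period 0.24442 s, three
0.05555 s steps down, five 0.07777 s steps up, ten repetitions (nine
levels, ninety randomized pairs, the reference itself paired against the
reference with p = 0.5 under any observer); 500 Hz, 24-channel recordings
with the standard 10–20 labels of a portable montage. Generator parameters
without a stated empirical value are fixed at field-typical magnitudes:
RT shift 0.2 s with lognormal(log 0.5, 0.35) decision times and a bimodal
facilitation factor 0.75; EEG 1/f exponent 1.0 with oscillation SNR well
above 10 (noise RMS 0.1 µV against unit-variance oscillations).

The generator is deliberately idealized: stationary spectra, no blinks,
EMG or electrode drift, no lapses or finger errors in the 2AFC responses,
no sequential dependencies or learning, and RT independent of stimulus
level. Passing tests therefore demonstrate the *correctness of the
analysis chain* against known ground truth — not robustness to the
artifacts and non-stationarities of real recordings, which require the
artifact hook and the usual visual quality control.

All randomness flows through explicit integer seeds (numpy Generator); the
pipeline derives per-stage seeds from a master seed via
`SeedSequence([master, stage_code, indices...])`, so any stage can be
re-run in isolation and full runs are byte-identical.

## Known limitations

* No lapse/guess-rate parameters in the psychometric model (a deliberate
  fidelity choice); heavy lapsing biases JND upward.
* Percentile bootstrap CIs undercover by a few percent at 90-trial
  designs (see Calibration above); BCa or profile-likelihood intervals
  would improve this but are out of scope.
* The race-model analysis reports violations descriptively; it does not
  test them inferentially (no permutation test over quantiles).
* EDF files are read (via mne) but fixtures are written only in the
  raw-float32 + JSON dialect.
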