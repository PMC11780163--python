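"""Generator ground truth: stimulus design, probit observers, RTs, EEG."""

import numpy as np
import pytest
from scipy.stats import lognorm, norm

from multisense.psychometrics import Z84
from multisense.synthetic import (
    EEGParams,
    ObserverSpec,
    RTParams,
    StimulusDesign,
    TrialPair,
    build_stimulus_design,
    effective_params,
    simulate_eeg,
    simulate_observer_responses,
    simulate_reaction_times,
    simulate_rt_condition_sets,
)


class TestStimulusDesign:
    def test_study_defaults_give_nine_levels_and_ninety_pairs(self):
        d = StimulusDesign()
        assert d.levels().size == 9
        assert len(build_stimulus_design(d, seed=0)) == 90

    def test_levels_are_reference_plus_minus_k_steps(self):
        lv = StimulusDesign().levels()
        expected = [0.07777, 0.13332, 0.18887, 0.24442, 0.32219, 0.39996,
                    0.47773, 0.55550, 0.63327]
        np.testing.assert_allclose(lv, expected, atol=1e-12)

    def test_zero_reps_gives_empty_list(self):
        assert build_stimulus_design(StimulusDesign(n_reps=0), seed=0) == []

    def test_reference_appears_as_a_comparison_level(self):
        d = StimulusDesign()
        counts = sum(p.comparison_period == d.reference_period
                     for p in build_stimulus_design(d, seed=3))
        assert counts == d.n_reps

    def test_design_crossing_zero_is_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            StimulusDesign(reference_period=0.1, step_down=0.05, n_down=2)

    def test_same_seed_is_bitwise_identical(self):
        d = StimulusDesign()
        assert build_stimulus_design(d, 7) == build_stimulus_design(d, 7)

    def test_presentation_order_is_randomized(self):
        first = [p.comparison_first for p in build_stimulus_design(StimulusDesign(), 11)]
        assert any(first) and not all(first)


class TestObserverResponses:
    @pytest.mark.parametrize(
        "offset,expected_p",
        [(0.0, 0.5), ("jnd", 0.84)],
        ids=["at_pse", "at_pse_plus_jnd"],
    )
    def test_response_rate_matches_probit_observer(self, offset, expected_p):
        """p = 0.5 at the PSE and 0.84 one JND above it, by construction."""
        pse, jnd = 0.25, 0.1
        spec = ObserverSpec(conditions={"T": (pse, jnd)})
        x = pse + (jnd if offset == "jnd" else 0.0)
        pairs = [TrialPair(x, pse, True)] * 100_000
        recs = simulate_observer_responses(pairs, spec, "T", seed=5)
        rate = np.mean([r.response for r in recs])
        assert rate == pytest.approx(expected_p, abs=3 * np.sqrt(0.25 / 100_000) + 1e-9)

    def test_response_curve_matches_generating_cdf_across_levels(self):
        """Observed frequencies track Phi((x-pse)/sigma) within binomial error."""
        spec = ObserverSpec(conditions={"T": (0.24442, 0.15)})
        d = StimulusDesign(n_reps=2000)
        pairs = build_stimulus_design(d, 1)
        recs = simulate_observer_responses(pairs, spec, "T", 2)
        sigma = 0.15 / Z84
        for lv in d.levels():
            got = np.mean([r.response for r in recs if r.comparison_period == lv])
            want = norm.cdf((lv - 0.24442) / sigma)
            assert got == pytest.approx(want, abs=4 * np.sqrt(want * (1 - want) / 2000) + 1e-3)

    def test_optimal_bimodal_jnd_below_both_unimodal(self):
        spec = ObserverSpec(
            conditions={"T": (0.25, 0.2), "VB": (0.23, 0.3)}, integration_mode="optimal"
        )
        _, jnd_vtb = effective_params(spec, "VTB")
        assert jnd_vtb < 0.2 and jnd_vtb < 0.3

    def test_equal_unimodal_jnds_combine_to_j_over_sqrt2(self):
        spec = ObserverSpec(conditions={"T": (0.25, 0.2), "VB": (0.25, 0.2)})
        _, jnd = effective_params(spec, "VTB")
        assert jnd == pytest.approx(0.2 / np.sqrt(2), rel=1e-12)

    def test_single_cue_modes_copy_the_named_cue(self):
        conds = {"T": (0.25, 0.2), "VB": (0.23, 0.3)}
        vis = ObserverSpec(conditions=conds, integration_mode="single_cue_visual")
        tac = ObserverSpec(conditions=conds, integration_mode="single_cue_tactile")
        assert effective_params(vis, "VTB") == conds["VB"]
        assert effective_params(tac, "VTB") == conds["T"]

    def test_unknown_condition_is_named_in_error(self):
        spec = ObserverSpec(conditions={"T": (0.25, 0.2)})
        with pytest.raises(KeyError, match="XX"):
            effective_params(spec, "XX")

    def test_same_seed_reproduces_responses(self):
        spec = ObserverSpec(conditions={"T": (0.25, 0.2)})
        pairs = build_stimulus_design(StimulusDesign(), 3)
        a = simulate_observer_responses(pairs, spec, "T", 9)
        b = simulate_observer_responses(pairs, spec, "T", 9)
        assert [r.response for r in a] == [r.response for r in b]


class TestReactionTimes:
    def test_identity_facilitation_keeps_distributions_identical_in_law(self):
        p = RTParams(bimodal_facilitation=1.0)
        rng_sets = simulate_rt_condition_sets(20_000, p, seed=4)
        # same generator law: compare means and variances within MC error
        assert rng_sets["VTB"].mean() == pytest.approx(rng_sets["T"].mean(), rel=0.02)
        assert rng_sets["VTB"].std() == pytest.approx(rng_sets["T"].std(), rel=0.05)

    def test_facilitation_scales_the_lognormal_component(self):
        """Monte-Carlo mean matches the closed-form lognormal mean times 0.7."""
        p = RTParams(shift=0.2, log_mean=np.log(0.5), log_sd=0.35,
                     bimodal_facilitation=0.7)
        sets = simulate_rt_condition_sets(10_000, p, seed=8)
        closed_form = np.exp(p.log_mean + p.log_sd**2 / 2)
        assert (sets["VTB"] - p.shift).mean() == pytest.approx(0.7 * closed_form, rel=0.02)
        assert (sets["T"] - p.shift).mean() == pytest.approx(closed_form, rel=0.02)

    def test_race_minima_match_product_form_cdf(self):
        """Empirical CDF of two-channel minima equals 1-(1-F)(1-F)."""
        p = RTParams(architecture="race")
        sets = simulate_rt_condition_sets(30_000, p, seed=2)
        t = np.linspace(0.4, 1.5, 25)
        f_single = lognorm.cdf(t - p.shift, s=p.log_sd, scale=np.exp(p.log_mean))
        expected = 1 - (1 - f_single) ** 2
        empirical = (sets["VTB"][:, None] <= t).mean(axis=0)
        np.testing.assert_allclose(empirical, expected, atol=0.015)

    def test_fills_rt_on_trial_records(self):
        spec = ObserverSpec(conditions={"T": (0.25, 0.2)})
        pairs = build_stimulus_design(StimulusDesign(), 5)
        recs = simulate_observer_responses(pairs, spec, "T", 6)
        out = simulate_reaction_times(recs, spec, 7)
        assert all(r.rt is not None and r.rt >= 0 for r in out)

    def test_facilitation_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            RTParams(bimodal_facilitation=0.0)


class TestSimulatedEEG:
    def test_pure_sinusoid_gives_planted_iaf_peak(self):
        from multisense.eeg import detect_iaf, epoch, welch_psd

        spec = ObserverSpec(conditions={"T": (0.25, 0.2)},
                            eeg_params=EEGParams(iaf=10.0, noise_level=1e-6))
        rec = simulate_eeg(spec, [(500, "L1", "T")], duration=5.0, seed=0)
        ep = epoch(rec)[0]
        freqs, psd = welch_psd(ep)
        iaf = detect_iaf(freqs, psd[rec.channel_names.index("Pz")])
        assert abs(iaf - 10.0) <= 500 / 1024 + 1e-9

    def test_iaf_outside_detection_window_rejected(self):
        with pytest.raises(ValueError, match="7.5"):
            ObserverSpec(conditions={"T": (0.25, 0.2)}, eeg_params=EEGParams(iaf=6.0))

    def test_event_too_close_to_end_rejected(self):
        spec = ObserverSpec(conditions={"T": (0.25, 0.2)})
        with pytest.raises(ValueError, match="1.75"):
            simulate_eeg(spec, [(2400, "L1", "T")], duration=5.0, seed=0)

    def test_oscillations_land_on_their_channels_only(self):
        spec = ObserverSpec(conditions={"T": (0.25, 0.2)},
                            eeg_params=EEGParams(noise_level=1e-9))
        rec = simulate_eeg(spec, [(100, "L1", "T")], duration=4.0, seed=1)
        assert rec.channel("Pz").std() > 100 * rec.channel("Cz").std()
        assert rec.channel("Fz").std() > 100 * rec.channel("O1").std()

    def test_same_seed_bitwise_identical(self):
        spec = ObserverSpec(conditions={"T": (0.25, 0.2)})
        a = simulate_eeg(spec, [(100, "L1", "T")], 4.0, seed=3)
        b = simulate_eeg(spec, [(100, "L1", "T")], 4.0, seed=3)
        np.testing.assert_array_equal(a.data, b.data)
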