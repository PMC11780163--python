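"""EEG mental workload: IAF detection and the theta/alpha ratio.

A synthetic 24-channel recording with a planted 10 Hz alpha rhythm
(parietal) and a theta rhythm at 6 Hz (frontal) twice as strong runs
through the full pipeline: FIR band-pass, common-average reference,
1.75 s epochs, Welch PSDs, IAF, individualized bands, workload ratio.
"""

from multisense.eeg import analyze_recording
from multisense.synthetic import EEGParams, ObserverSpec, simulate_eeg

observer = ObserverSpec(
    conditions={"T": (0.24442, 0.15)},
    eeg_params=EEGParams(iaf=10.0, frontal_theta_power=2.0,
                         parietal_alpha_power=1.0, noise_exponent=1.0),
)
events = [(1000 + i * 1000, "L1P", "VTB") for i in range(20)]
recording = simulate_eeg(observer, events, duration=45.0, seed=7)

iaf, per_epoch = analyze_recording(recording)
print(f"detected IAF          : {iaf:.2f} Hz (planted 10.00, bin 0.49 Hz)")
print(f"theta band            : {iaf - 6:.2f} - {iaf - 2:.2f} Hz (frontal Fz/F7/F8)")
print(f"alpha band            : {iaf - 2:.2f} - {iaf + 2:.2f} Hz (parietal Pz/P3/P4)")
print(f"mean workload (VTB)   : {per_epoch['workload'].mean():.3f} (planted ratio 2.0)")
# workload = frontal theta power / parietal alpha power; higher values
# index greater cognitive load.  The planted 2:1 ratio is recovered
# within a few percent despite filtering and re-referencing.
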