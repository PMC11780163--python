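"""Full study pipeline from a config: simulate -> fit -> classify -> report.

Two synthetic amputee-like observers - an optimal integrator at the
"stump" site and a non-integrating observer at the "intact leg" site -
run end to end; every stage artifact lands in ./scratch/pipeline_out.
"""

from multisense.pipeline import ObserverConfig, RunConfig, run_study

cfg = RunConfig(
    seed=11,
    design={"n_reps": 100},
    B=500,
    observers=[
        ObserverConfig(
            subject_id="a1", group="amputee", sites=["L1P"],
            integration_mode="optimal",
            conditions={"T": [0.24442, 0.15], "VB": [0.24442, 0.15]},
            eeg={"iaf": 10.0},
        ),
        ObserverConfig(
            subject_id="a1_intact", group="amputee", sites=["L2P"],
            integration_mode="non_integrating",
            conditions={"T": [0.24442, 0.15], "VB": [0.24442, 0.15]},
        ),
    ],
    output_dir="scratch/pipeline_out",
    eeg_events_per_condition=10,
)

report = run_study(cfg)
for row in report["classification"]:
    print(f"{row['subject']}/{row['site']}: class={row['class']}  "
          f"JND T/VB/VTB = {row['jnd_T']:.3f}/{row['jnd_VB']:.3f}/{row['jnd_VTB']:.3f}  "
          f"MLE = {row['jnd_MLE']:.3f}")
print("artifacts:", ", ".join(report["artifacts"]))
# Rerunning with the same seed reproduces every artifact byte-for-byte;
# the report's provenance block records the config hash and seed.
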