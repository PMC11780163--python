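"""End-to-end study pipeline: simulate -> fit -> combine -> test -> RT -> EEG.

A run is described by a :class:`RunConfig` (usually loaded from YAML).  For
every simulated observer and stimulation site the pipeline

1. builds the stimulus design and simulates 2AFC responses and reaction
   times for each condition (condition order randomized per seed, as in the
   experimental protocol),
2. fits probit psychometric functions and bootstraps PSE/JND,
3. runs the pairwise JND family (CI-inversion p-values, BH-FDR) and
   classifies the site's integration outcome,
4. summarizes cleaned reaction times and the race-model inequality,
5. optionally simulates/loads EEG and computes the per-epoch workload,

and writes every stage product as plain CSV/JSON plus a final report with a
provenance block (config hash, master seed, package version).

Reproducibility: every stochastic stage draws its seed from the master seed
through a documented counter scheme (``stage_seed``), so stages can be rerun
in isolation and a full rerun is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cue_combination import classify_integration, predict_mle
from .eeg import analyze_recording
from .inference import parametric_bootstrap, pairwise_jnd_tests
from .io import trials_to_frame, write_trials_csv
from .psychometrics import fit_probit, fits_to_frame
from .reaction_times import filter_rts, race_model_inequality, rt_summary
from .synthetic import (
    EEGParams,
    ObserverSpec,
    RTParams,
    StimulusDesign,
    build_stimulus_design,
    simulate_eeg,
    simulate_observer_responses,
    simulate_reaction_times,
)

__all__ = ["RunConfig", "ObserverConfig", "stage_seed", "run_subject", "run_study", "load_config"]

# stage codes for the seed counter scheme
_STAGES = {"design": 0, "responses": 1, "rt": 2, "eeg": 3, "bootstrap": 4, "order": 5}


def stage_seed(master: int, stage: str, *indices: int) -> int:
    """Deterministic per-stage seed: SeedSequence(master, stage_code, *indices)."""
    ss = np.random.SeedSequence([int(master), _STAGES[stage], *map(int, indices)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class ObserverConfig:
    """One synthetic observer: identity, sites and ground-truth parameters."""

    subject_id: str
    group: str = "healthy"
    sites: list[str] = field(default_factory=lambda: ["L1"])
    integration_mode: str = "optimal"
    conditions: dict = field(default_factory=dict)  # {cond: [pse, jnd]}
    rt: dict = field(default_factory=dict)
    eeg: dict | None = None  # None -> skip the EEG stage

    def spec(self) -> ObserverSpec:
        return ObserverSpec(
            conditions={c: tuple(v) for c, v in self.conditions.items()},
            integration_mode=self.integration_mode,
            rt_params=RTParams(**self.rt),
            eeg_params=EEGParams(**(self.eeg or {})),
            subject_id=self.subject_id,
            group=self.group,
        )


@dataclass
class RunConfig:
    """Full study configuration."""

    seed: int
    observers: list[ObserverConfig]
    design: dict = field(default_factory=dict)
    conditions: list[str] = field(default_factory=lambda: ["T", "VB", "VTB"])
    B: int = 500
    alpha: float = 0.05
    output_dir: str = "multisense_out"
    eeg_events_per_condition: int = 20
    eeg_event_spacing_s: float = 2.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a master seed is mandatory for any stochastic stage")
        if self.B < 100:
            raise ValueError("B must be >= 100 for the inference stages")
        if not self.observers:
            raise ValueError("config lists no observers")

    def stimulus_design(self) -> StimulusDesign:
        return StimulusDesign(**self.design)

    def canonical_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed, "design": self.design,
                "conditions": self.conditions, "B": self.B, "alpha": self.alpha,
                "observers": [asdict(o) for o in self.observers],
                "eeg_events_per_condition": self.eeg_events_per_condition,
                "eeg_event_spacing_s": self.eeg_event_spacing_s,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    observers = [ObserverConfig(**o) for o in raw.pop("observers", [])]
    return RunConfig(observers=observers, **raw)


def _simulate_site(cfg: RunConfig, obs: ObserverConfig, site_i: int, site: str):
    """Simulate all conditions of one observer x site, in randomized order."""
    spec = obs.spec()
    order_rng = np.random.default_rng(stage_seed(cfg.seed, "order", site_i))
    conds = list(cfg.conditions)
    order_rng.shuffle(conds)
    design = cfg.stimulus_design()
    trials = []
    for cond_i, cond in enumerate(conds):
        pairs = build_stimulus_design(design, stage_seed(cfg.seed, "design", site_i, cond_i))
        recs = simulate_observer_responses(
            pairs, spec, cond, stage_seed(cfg.seed, "responses", site_i, cond_i), site=site
        )
        simulate_reaction_times(recs, spec, stage_seed(cfg.seed, "rt", site_i, cond_i))
        trials.extend(recs)
    return spec, trials


def _analyse_site(cfg: RunConfig, subject: str, site: str, df_site: pd.DataFrame, site_i: int):
    """Fit/bootstrap/classify one site's blurred-condition family."""
    fits, boots = {}, {}
    for cond_i, cond in enumerate(("T", "VB", "VTB")):
        sub = df_site[df_site.condition == cond]
        if sub.empty:
            raise ValueError(f"stage fit: no trials for {subject}/{site}/{cond}")
        fit = fit_probit(sub, subject=subject, site=site, condition=cond)
        if not fit.converged:
            raise ValueError(f"stage fit: non-converged fit for {subject}/{site}/{cond}")
        fits[cond] = fit
        boots[cond] = parametric_bootstrap(
            fit, B=cfg.B, seed=stage_seed(cfg.seed, "bootstrap", site_i, cond_i)
        )
    tests = pairwise_jnd_tests(boots)
    mle = predict_mle(fits["VB"].jnd, fits["T"].jnd, fits["VB"].pse, fits["T"].pse)
    label, super_opt = classify_integration(
        fits["T"].jnd, fits["VB"].jnd, fits["VTB"].jnd, mle.predicted_jnd,
        tests, alpha=cfg.alpha,
    )
    row = {
        "subject": subject, "site": site,
        "jnd_T": fits["T"].jnd, "jnd_VB": fits["VB"].jnd, "jnd_VTB": fits["VTB"].jnd,
        "jnd_MLE": mle.predicted_jnd,
        "class": label.value, "super_optimal": super_opt,
        "p_T_VTB": tests["T_VTB"].p_fdr, "p_VB_VTB": tests["VB_VTB"].p_fdr,
        "p_VTB_MLE": tests["VTB_MLE"].p_fdr, "p_T_VB": tests["T_VB"].p_fdr,
    }
    return list(fits.values()), row


def _rt_stage(subject: str, site: str, df_site: pd.DataFrame):
    sets = []
    by_cond = {}
    for cond, sub in df_site.groupby("condition"):
        vals = sub["rt"].to_numpy(dtype=float)
        s = filter_rts(vals, subject=subject, site=site, condition=str(cond))
        sets.append(s)
        by_cond[str(cond)] = s.values
    summary = rt_summary(sets)
    rmi = None
    if all(c in by_cond for c in ("T", "VB", "VTB")):
        rmi = race_model_inequality(by_cond["T"], by_cond["VB"], by_cond["VTB"])
        rmi.insert(0, "site", site)
        rmi.insert(0, "subject", subject)
    return summary, rmi


def _eeg_stage(cfg: RunConfig, obs: ObserverConfig, site_i: int, site: str):
    spec = obs.spec()
    spacing = int(round(cfg.eeg_event_spacing_s * 500.0))
    events = []
    s = spacing
    for cond in cfg.conditions:
        for _ in range(cfg.eeg_events_per_condition):
            events.append((s, site, cond))
            s += spacing
    duration = (s + spacing) / 500.0
    rec = simulate_eeg(spec, events, duration, stage_seed(cfg.seed, "eeg", site_i))
    iaf, frame = analyze_recording(rec)
    frame.insert(0, "subject", obs.subject_id)
    return iaf, frame


def run_subject(cfg: RunConfig, obs: ObserverConfig, *, site_offset: int = 0) -> dict:
    """Run every stage for one observer; returns the in-memory report parts."""
    all_trials, all_fits, class_rows = [], [], []
    rt_frames, rmi_frames, eeg_frames = [], [], []
    for si, site in enumerate(obs.sites):
        site_i = site_offset + si
        spec, trials = _simulate_site(cfg, obs, site_i, site)
        df_site = trials_to_frame(trials)
        all_trials.append(df_site)
        fits, row = _analyse_site(cfg, obs.subject_id, site, df_site, site_i)
        all_fits.extend(fits)
        class_rows.append(row)
        summary, rmi = _rt_stage(obs.subject_id, site, df_site)
        rt_frames.append(summary)
        if rmi is not None:
            rmi_frames.append(rmi)
        if obs.eeg is not None:
            iaf, frame = _eeg_stage(cfg, obs, site_i, site)
            eeg_frames.append(frame)
    return {
        "trials": pd.concat(all_trials, ignore_index=True),
        "fits": all_fits,
        "classification": class_rows,
        "rt": pd.concat(rt_frames, ignore_index=True),
        "rmi": pd.concat(rmi_frames, ignore_index=True) if rmi_frames else None,
        "eeg": pd.concat(eeg_frames, ignore_index=True) if eeg_frames else None,
    }


def run_study(cfg: RunConfig, out_dir=None) -> dict:
    """Run all observers and write every stage artifact plus report.json."""
    out = Path(out_dir if out_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    parts = []
    offset = 0
    for obs in cfg.observers:
        parts.append(run_subject(cfg, obs, site_offset=offset))
        offset += len(obs.sites)

    trials = pd.concat([p["trials"] for p in parts], ignore_index=True)
    fits = fits_to_frame([f for p in parts for f in p["fits"]])
    classification = pd.DataFrame([r for p in parts for r in p["classification"]])
    rt = pd.concat([p["rt"] for p in parts], ignore_index=True)
    rmi = [p["rmi"] for p in parts if p["rmi"] is not None]
    eeg = [p["eeg"] for p in parts if p["eeg"] is not None]

    write_trials_csv(trials, out / "trials.csv")
    fits.to_csv(out / "fits.csv", index=False)
    classification.to_csv(out / "classification.csv", index=False)
    rt.to_csv(out / "rt_summary.csv", index=False)
    if rmi:
        pd.concat(rmi, ignore_index=True).to_csv(out / "race_model.csv", index=False)
    if eeg:
        eeg_all = pd.concat(eeg, ignore_index=True)
        eeg_all.to_csv(out / "workload.csv", index=False)
        workload_summary = (
            eeg_all.groupby(["subject", "site", "condition"])["workload"]
            .apply(lambda v: _condition_workload_values(v.to_numpy()))
            .reset_index()
        )
        workload_summary.to_csv(out / "workload_summary.csv", index=False)

    report = {
        "provenance": {
            "package": "multisense",
            "version": __version__,
            "seed": cfg.seed,
            "config_sha256": cfg.canonical_hash(),
        },
        "classification": classification.to_dict(orient="records"),
        "n_trials": int(len(trials)),
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _condition_workload_values(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    m, sd = v.mean(), v.std(ddof=0)
    if sd > 0:
        v = v[np.abs(v - m) <= 3.0 * sd]
    return float(v.mean())
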