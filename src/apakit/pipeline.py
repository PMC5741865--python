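"""Stage wiring: simulate -> screen -> onsets -> ERP -> statistics.

`run_pipeline` drives a fully reproducible end-to-end run on a simulated
cohort (or pre-existing session directories), writing ``screening.csv``,
``onsets.csv``, ``subject_means.csv``, ``erp.csv``, ``stats_report.json``
and a run log echoing the configuration and seed. Identical configuration
and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from apakit import stats as stats_mod
from apakit.core_model import POSTURAL_MUSCLES, Recording
from apakit.emg_onset import OnsetParams, relative_onsets, subject_means
from apakit.erp import N_TRIALS_REQUIRED, ErpResult, compute_erp
from apakit.preprocessing import emg_envelope_chain
from apakit.screening import ScreeningReport, ScreeningRule, screen_session
from apakit.simulate import (
    SimulationConfig,
    _rng,
    generate_session,
    make_subject_profile,
)

log = logging.getLogger("apakit")

#: protocol constants every default must reproduce
PAPER_DEFAULTS = {
    "k_sd": 2.0,
    "min_duration_ms": 50.0,
    "highpass_hz": 40.0,
    "highpass_order": 7,
    "lowpass_hz": 30.0,
    "cop_range_cm": 1.0,
    "artifact_limit_uv": 100.0,
    "required_accepted": 20,
    "isi_ms": 2500.0,
    "n_stimuli": 72,
    "p300_window_ms": (250.0, 500.0),
    "epoch_window_ms": (-200.0, 800.0),
}


@dataclass
class PipelineConfig:
    out_dir: str = "apakit_run"
    seed: int = 0
    # simulation block
    n_per_group: int = 14
    conditions: tuple[str, ...] = ("p15", "p45", "self")
    # stage toggles
    run_screening: bool = True
    run_onsets: bool = True
    run_erp: bool = True
    run_stats: bool = True
    # analysis parameters (defaults = protocol values)
    k_sd: float = 2.0
    min_duration_ms: float = 50.0
    highpass_hz: float = 40.0
    highpass_order: int = 7
    lowpass_hz: float = 30.0
    cop_range_cm: float = 1.0
    artifact_limit_uv: float = 100.0
    required_accepted: int = 20
    fs: float = 1000.0

    def onset_params(self) -> OnsetParams:
        return OnsetParams(k_sd=self.k_sd, min_duration_ms=self.min_duration_ms)

    def screening_rule(self) -> ScreeningRule:
        return ScreeningRule(
            cop_range_cm=self.cop_range_cm,
            artifact_limit_uv=self.artifact_limit_uv,
            required_accepted=self.required_accepted,
        )


def validate_config(cfg: PipelineConfig) -> dict:
    """Range checks plus an explicit list of deviations from the protocol
    defaults. Report-based: never raises."""
    problems, deviations = [], []
    if cfg.highpass_hz >= cfg.fs / 2:
        problems.append(
            f"highpass cutoff {cfg.highpass_hz} Hz at or above Nyquist ({cfg.fs / 2} Hz)"
        )
    if cfg.lowpass_hz >= cfg.fs / 2:
        problems.append(
            f"lowpass cutoff {cfg.lowpass_hz} Hz at or above Nyquist ({cfg.fs / 2} Hz)"
        )
    if cfg.min_duration_ms <= 0:
        problems.append("min_duration_ms must be positive")
    for key in ("k_sd", "min_duration_ms", "highpass_hz", "highpass_order",
                "lowpass_hz", "cop_range_cm", "artifact_limit_uv",
                "required_accepted"):
        got, ref = getattr(cfg, key), PAPER_DEFAULTS[key]
        if got != ref:
            deviations.append(f"{key} {got} != protocol {ref}")
    return {"ok": not problems, "problems": problems, "deviations": deviations}


def process_session(
    rec: Recording,
    rule: ScreeningRule | None = None,
    params: OnsetParams | None = None,
    n_erp_trials: int = N_TRIALS_REQUIRED,
) -> tuple[ScreeningReport, pd.DataFrame, ErpResult | None]:
    """Screen one session, extract relative onsets on accepted trials, and
    (oddball only) compute the P300 from the accepted target epochs."""
    rule = rule or ScreeningRule()
    params = params or OnsetParams()
    chains = {m: emg_envelope_chain(rec.channels[m]) for m in ("AD",) + POSTURAL_MUSCLES}

    report = screen_session(rec, rule, params, ad_chain=chains["AD"])
    accepted = set(report.accepted_indices)

    rows = []
    condition = rec.meta.get("condition", rec.events[0].condition if rec.events else "p15")
    for t in report.trials:
        if t.trial not in accepted:
            continue
        for recd in relative_onsets(rec, t.trial, t.anchor_ms, t.condition, params, chains):
            rows.append(
                {
                    "subject": rec.meta["subject"],
                    "group": rec.meta["group"],
                    "condition": t.condition,
                    "muscle": recd.muscle,
                    "trial": recd.trial,
                    "ad_onset_ms": recd.ad_onset_ms,
                    "onset_ms": recd.onset_ms,
                    "relative_onset_ms": recd.relative_onset_ms,
                    "detected": recd.detected,
                }
            )
    onsets = pd.DataFrame(
        rows,
        columns=["subject", "group", "condition", "muscle", "trial",
                 "ad_onset_ms", "onset_ms", "relative_onset_ms", "detected"],
    )

    erp_result = None
    if condition in ("p15", "p45"):
        target_times = [t.anchor_ms for t in report.trials]
        try:
            erp_result = compute_erp(
                rec.channels["Pz"], target_times, report.accepted_indices, n_erp_trials
            )
        except Exception as exc:  # insufficient trials is a reportable outcome
            log.warning("ERP stage failed for %s/%s: %s",
                        rec.meta.get("subject"), condition, exc)
    return report, onsets, erp_result


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Simulate a cohort and run every enabled stage; returns the run dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    check = validate_config(cfg)
    if not check["ok"]:
        raise ValueError("invalid config: " + "; ".join(check["problems"]))

    rule, params = cfg.screening_rule(), cfg.onset_params()
    screening_frames, onset_frames, erp_rows = [], [], []
    seed_rng = _rng(cfg.seed, "pipeline")
    for group in ("young", "older"):
        for s in range(cfg.n_per_group):
            subject = f"{group}{s:02d}"
            profile = make_subject_profile(group, _rng(cfg.seed, "profile", subject))
            for cond in cfg.conditions:
                sim = SimulationConfig(
                    condition=cond,
                    seed=int(seed_rng.integers(0, 2**31 - 1)),
                    n_target_trials=cfg.required_accepted,
                )
                rec, _truth = generate_session(
                    sim, profile, meta={"subject": subject, "group": group,
                                        "condition": cond},
                )
                report, onsets, erp_result = process_session(
                    rec, rule, params, cfg.required_accepted
                )
                sf = report.to_frame()
                sf.insert(0, "subject", subject)
                sf.insert(1, "group", group)
                screening_frames.append(sf)
                onset_frames.append(onsets)
                if erp_result is not None:
                    erp_rows.append(
                        {
                            "subject": subject,
                            "group": group,
                            "condition": cond,
                            "n_trials": erp_result.n_trials,
                            "p300_latency_ms": erp_result.p300_latency_ms,
                            "p300_amplitude_uv": erp_result.p300_amplitude_uv,
                            "found": erp_result.found,
                        }
                    )

    screening = pd.concat(screening_frames, ignore_index=True)
    onsets = pd.concat(onset_frames, ignore_index=True)
    erp = pd.DataFrame(erp_rows)
    means = subject_means(onsets)

    fmt = "%.10g"
    if cfg.run_screening:
        screening.to_csv(out / "screening.csv", index=False, float_format=fmt)
    if cfg.run_onsets:
        onsets.to_csv(out / "onsets.csv", index=False, float_format=fmt)
        means.to_csv(out / "subject_means.csv", index=False, float_format=fmt)
    if cfg.run_erp:
        erp.to_csv(out / "erp.csv", index=False, float_format=fmt)

    if cfg.run_stats and cfg.n_per_group >= 3 and not erp.empty:
        table = means[~means.flagged_missing][
            ["subject", "group", "condition", "muscle", "mean_relative_onset_ms"]
        ]
        erp_ok = erp[erp.found].drop(columns=["n_trials", "found"])
        report = stats_mod.run_battery(table, erp_ok)
        pattern = stats_mod.evaluate_pattern(report)
        payload = {"report": report_to_jsonable(report), "pattern": pattern}
        (out / "stats_report.json").write_text(json.dumps(payload, indent=1))

    (out / "run_log.txt").write_text(
        "apakit pipeline run\n"
        + json.dumps(dataclasses.asdict(cfg), indent=1)
        + "\nconfig check: "
        + json.dumps(check)
        + "\n"
    )
    return out


def report_to_jsonable(obj):
    """Recursively convert battery results to JSON-serializable objects."""
    if isinstance(obj, stats_mod.TestResult):
        return obj.to_dict()
    if isinstance(obj, stats_mod.MixedAnovaResult):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {str(k): report_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [report_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj
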