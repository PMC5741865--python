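"""Trial acceptance: initial-CoP window check and EEG/EOG artifact rejection.

A target trial is accepted when

1. a focal AD burst is detectable (otherwise ``no_ad_burst``),
2. the anteroposterior CoP stays within ±1 cm of the quiet-standing
   reference over the pre-flexion window — defined here as the 500 ms
   immediately preceding the detected AD onset (``cop_out_of_range``),
3. no EOG/Fz/Cz/Pz sample exceeds ±100 μV from 200 ms before to 800 ms
   after target onset (``artifact``).

Rules apply in that order and only the first failure is recorded, so
rejection counts are unambiguous. Self-timing trials skip the artifact rule
(no stimulus-locked averaging exists in that condition). The accepted list
is truncated to the first ``required_accepted`` trials (20 in the
protocol — blocks were repeated until 20 target trials were accepted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from apakit.core_model import EEG_CHANNELS, BoundsError, Recording, Signal
from apakit.emg_onset import OnsetParams, detect_ad_onset
from apakit.preprocessing import emg_envelope_chain

REASONS = ("none", "cop_out_of_range", "artifact", "no_ad_burst")


@dataclass(frozen=True)
class ScreeningRule:
    cop_range_cm: float = 1.0
    cop_window_ms: float = 500.0  # pre-flexion interval checked
    artifact_limit_uv: float = 100.0
    artifact_window: tuple[float, float] = (-200.0, 800.0)  # re target onset
    required_accepted: int = 20

    def __post_init__(self) -> None:
        if self.cop_range_cm <= 0 or self.artifact_limit_uv <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class TrialScreen:
    trial: int
    condition: str
    anchor_ms: float  # target onset (oddball) / go-window start (self)
    accepted: bool
    reason: str
    ad_onset_ms: float | None = None


@dataclass
class ScreeningReport:
    trials: list[TrialScreen]
    accepted_indices: list[int]  # truncated to required_accepted

    @property
    def counts(self) -> dict[str, int]:
        out = {r: 0 for r in REASONS}
        for t in self.trials:
            out["none" if t.accepted else t.reason] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [t.trial for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "anchor_ms": [t.anchor_ms for t in self.trials],
                "accepted": [t.accepted for t in self.trials],
                "reason": ["none" if t.accepted else t.reason for t in self.trials],
                "ad_onset_ms": [t.ad_onset_ms for t in self.trials],
            }
        )


def check_cop(
    cop: Signal, qsp_cm: float, ad_onset_ms: float, rule: ScreeningRule
) -> bool:
    """True (pass) iff every CoPap sample in the pre-flexion window lies
    within ``qsp ± cop_range_cm``. Window: ``[onset − cop_window, onset)``."""
    i0 = cop.index_at(ad_onset_ms - rule.cop_window_ms)
    i1 = cop.index_at(ad_onset_ms)
    if i0 < 0 or i1 > cop.n or i1 <= i0:
        raise BoundsError("CoP pre-flexion window not covered by the recording")
    seg = cop.values[i0:i1]
    return bool(np.all(np.abs(seg - qsp_cm) <= rule.cop_range_cm))


def check_artifact(rec: Recording, target_ms: float, rule: ScreeningRule) -> bool:
    """True (pass) iff no EOG/Fz/Cz/Pz sample exceeds the ±limit inside the
    −200..+800 ms window around the target."""
    lo, hi = rule.artifact_window
    for name in ("EOG",) + EEG_CHANNELS:
        sig = rec.channels[name]
        i0 = sig.index_at(target_ms + lo)
        i1 = sig.index_at(target_ms + hi)
        if i0 < 0 or i1 > sig.n or i1 <= i0:
            raise BoundsError(f"artifact window not covered on channel {name}")
        if np.any(np.abs(sig.values[i0:i1]) > rule.artifact_limit_uv):
            return False
    return True


def screen_session(
    rec: Recording,
    rule: ScreeningRule | None = None,
    params: OnsetParams | None = None,
    ad_chain=None,
) -> ScreeningReport:
    """Screen every target trial (oddball) / go-window trial (self-timing).

    ``ad_chain`` may carry the precomputed AD ``(rectified, envelope)`` pair.
    """
    rule = rule or ScreeningRule()
    params = params or OnsetParams()
    if ad_chain is None:
        ad_chain = emg_envelope_chain(rec.channels["AD"])
    ad_rect, ad_env = ad_chain
    cop = rec.channels["CoPap"]
    qsp = rec.qsp_cm

    trials: list[TrialScreen] = []
    anchors = [
        (i, ev)
        for i, ev in enumerate(rec.events)
        if ev.label in ("target", "go_window_start")
    ]
    for trial, (_, ev) in enumerate(anchors):
        ad_onset = detect_ad_onset(ad_rect, ad_env, ev.time_ms, ev.condition, params)
        if ad_onset is None:
            trials.append(TrialScreen(trial, ev.condition, ev.time_ms, False,
                                      "no_ad_burst"))
            continue
        if not check_cop(cop, qsp, ad_onset, rule):
            trials.append(TrialScreen(trial, ev.condition, ev.time_ms, False,
                                      "cop_out_of_range", ad_onset))
            continue
        if ev.condition != "self" and not check_artifact(rec, ev.time_ms, rule):
            trials.append(TrialScreen(trial, ev.condition, ev.time_ms, False,
                                      "artifact", ad_onset))
            continue
        trials.append(TrialScreen(trial, ev.condition, ev.time_ms, True, "none",
                                  ad_onset))

    accepted = [t.trial for t in trials if t.accepted][: rule.required_accepted]
    return ScreeningReport(trials=trials, accepted_indices=accepted)
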