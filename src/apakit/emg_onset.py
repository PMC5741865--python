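"""EMG burst-onset detection and relative-onset computation.

Burst criterion: the rectified-EMG envelope must exceed the background mean
by more than ``k_sd`` background SDs continuously for at least
``min_duration_ms``. The earliest such run whose start lies inside the
muscle-specific search window defines the coarse onset; the onset is then
refined backward to the point where the rectified wave itself last rose
through the background mean ("where the deviation began"), bounded by one
envelope window.

Windows (all half-open, in ms):

* AD (focal): background ``[-150, 0)`` re target onset; search
  ``[+200, +500)`` re target onset.
* Postural muscles (ES, BF, GcM): background ``[-300, -150)`` re the
  refined AD onset; search ``[-150, +100)`` re the refined AD onset.
* Self-timing (no target exists): the AD background window is anchored to a
  preliminary envelope-rise estimate (first crossing of a loose threshold
  inside the go window) and the AD search spans the whole go window.

Relative onset = postural onset − AD onset; negative values mean the
postural muscle fired before the focal muscle (an anticipatory adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from apakit.core_model import (
    POSTURAL_MUSCLES,
    BoundsError,
    Recording,
    Signal,
)
from apakit.preprocessing import ENVELOPE_WINDOW_MS, emg_envelope_chain


@dataclass(frozen=True)
class OnsetParams:
    """Detection parameters; defaults are the protocol's values."""

    k_sd: float = 2.0
    min_duration_ms: float = 50.0
    ad_background: tuple[float, float] = (-150.0, 0.0)  # re target onset
    ad_search: tuple[float, float] = (200.0, 500.0)  # re target onset
    postural_background: tuple[float, float] = (-300.0, -150.0)  # re AD onset
    postural_search: tuple[float, float] = (-150.0, 100.0)  # re AD onset
    envelope_window_ms: float = ENVELOPE_WINDOW_MS
    # self-timing: loose preliminary threshold (in background SDs) used only
    # to anchor the AD background window when no target exists
    self_prelim_k_sd: float = 5.0
    self_go_window_ms: float = 3000.0


@dataclass(frozen=True)
class BackgroundStats:
    """Mean/SD of envelope amplitude over a stated background window."""

    mean: float
    sd: float
    window: tuple[float, float]  # absolute session times, ms
    n_samples: int


@dataclass(frozen=True)
class BurstDetection:
    detected: bool
    onset_ms: float | None = None  # session time of the run start
    threshold: float = np.nan


@dataclass
class OnsetRecord:
    muscle: str
    trial: int
    ad_onset_ms: float | None
    onset_ms: float | None
    relative_onset_ms: float | None
    detected: bool


def background_stats(
    env: Signal, anchor_ms: float, from_ms: float, to_ms: float
) -> BackgroundStats:
    """Sample mean/SD of the envelope over the half-open window
    ``[anchor+from, anchor+to)``."""
    i0 = env.index_at(anchor_ms + from_ms)
    i1 = env.index_at(anchor_ms + to_ms)
    if i0 < 0 or i1 > env.n or i1 <= i0:
        raise BoundsError(
            f"background window [{anchor_ms + from_ms:g}, {anchor_ms + to_ms:g}) ms "
            f"outside signal [{env.t0:g}, {env.t_end:g})"
        )
    seg = env.values[i0:i1]
    return BackgroundStats(
        mean=float(np.mean(seg)),
        sd=float(np.std(seg, ddof=0)),
        window=(anchor_ms + from_ms, anchor_ms + to_ms),
        n_samples=seg.size,
    )


def detect_burst(
    env: Signal,
    bg: BackgroundStats,
    search_from_ms: float,
    search_to_ms: float,
    k_sd: float = 2.0,
    min_duration_ms: float = 50.0,
) -> BurstDetection:
    """Earliest envelope run above ``mean + k_sd*sd`` lasting >= the minimum.

    The run's *start* must lie inside the half-open search window; the run
    itself may extend beyond the window's right edge. Absence of any
    qualifying run is a valid result (``detected=False``).
    """
    thr = bg.mean + k_sd * bg.sd
    i0 = env.index_at(search_from_ms)
    i1 = env.index_at(search_to_ms)
    if i0 < 0 or i1 > env.n or i1 <= i0:
        raise BoundsError(
            f"search window [{search_from_ms:g}, {search_to_ms:g}) ms outside "
            f"signal [{env.t0:g}, {env.t_end:g})"
        )
    min_run = int(round(min_duration_ms * env.fs / 1000.0))
    above = env.values > thr
    for start in range(i0, i1):
        if not above[start]:
            continue
        if start > 0 and above[start - 1]:
            continue  # run started before the window opened
        end = start
        while end < env.n and above[end]:
            end += 1
        if end - start >= min_run:
            return BurstDetection(True, env.time_at(start), thr)
    return BurstDetection(False, None, thr)


def refine_onset(
    rectified: Signal,
    env: Signal,
    coarse_onset_ms: float,
    bg: BackgroundStats,
    envelope_window_ms: float = ENVELOPE_WINDOW_MS,
) -> float:
    """Locate where the deviation began in the rectified wave itself: the
    last up-crossing of the background mean at the foot of the burst.

    Starting from the envelope-criterion time, the walk first moves forward
    to the nearest above-mean rectified sample (the centered envelope can
    cross its threshold slightly *before* the raw wave rises), then backward
    while the rectified wave stays above the mean. Both directions are
    bounded by one envelope window around the coarse onset — the moving
    average cannot respond to activity further away than its own span.
    """
    i = rectified.index_at(coarse_onset_ms)
    i_min = max(rectified.index_at(coarse_onset_ms - envelope_window_ms), 0)
    i_max = min(rectified.index_at(coarse_onset_ms + envelope_window_ms), rectified.n - 1)
    j = i
    while j < i_max and rectified.values[j] <= bg.mean:
        j += 1
    if rectified.values[j] <= bg.mean:
        return coarse_onset_ms  # no raw rise nearby; keep the envelope time
    while j > i_min and rectified.values[j - 1] > bg.mean:
        j -= 1
    return rectified.time_at(j)


def _detect_and_refine(
    rect: Signal,
    env: Signal,
    bg: BackgroundStats,
    search: tuple[float, float],
    params: OnsetParams,
) -> float | None:
    det = detect_burst(
        env, bg, search[0], search[1], params.k_sd, params.min_duration_ms
    )
    if not det.detected:
        return None
    return refine_onset(rect, env, det.onset_ms, bg, params.envelope_window_ms)


def detect_ad_onset(
    rec_rect: Signal,
    rec_env: Signal,
    trial_anchor_ms: float,
    condition: str,
    params: OnsetParams | None = None,
) -> float | None:
    """Refined AD onset for one trial, or None when no burst qualifies.

    ``trial_anchor_ms`` is the target-onset time in the oddball conditions
    and the go-window start in the self-timing condition.
    """
    params = params or OnsetParams()
    if condition in ("p15", "p45"):
        bg = background_stats(rec_env, trial_anchor_ms, *params.ad_background)
        return _detect_and_refine(rec_rect, rec_env, bg, (
            trial_anchor_ms + params.ad_search[0],
            trial_anchor_ms + params.ad_search[1],
        ), params)
    # self-timing: anchor the background window to a preliminary envelope
    # rise found with a loose threshold inside the go window
    bg0 = background_stats(rec_env, trial_anchor_ms, -500.0, 0.0)
    prelim = detect_burst(
        rec_env,
        bg0,
        trial_anchor_ms,
        trial_anchor_ms + params.self_go_window_ms,
        params.self_prelim_k_sd,
        params.min_duration_ms,
    )
    if not prelim.detected:
        return None
    bg = background_stats(rec_env, prelim.onset_ms, *params.ad_background)
    return _detect_and_refine(rec_rect, rec_env, bg, (
        trial_anchor_ms,
        trial_anchor_ms + params.self_go_window_ms,
    ), params)


def relative_onsets(
    rec: Recording,
    trial: int,
    trial_anchor_ms: float,
    condition: str,
    params: OnsetParams | None = None,
    chains: dict[str, tuple[Signal, Signal]] | None = None,
) -> list[OnsetRecord]:
    """Per-postural-muscle onset records for one accepted trial.

    ``chains`` may carry precomputed ``(rectified, envelope)`` pairs per
    muscle (the pipeline computes each channel's chain once per session).
    Returns an empty list when the focal AD burst is undetected — the trial
    is then screened out as a miss.
    """
    params = params or OnsetParams()
    if chains is None:
        chains = {
            m: emg_envelope_chain(rec.channels[m])
            for m in ("AD",) + POSTURAL_MUSCLES
        }
    ad_rect, ad_env = chains["AD"]
    ad_onset = detect_ad_onset(ad_rect, ad_env, trial_anchor_ms, condition, params)
    if ad_onset is None:
        return []
    records = []
    for muscle in POSTURAL_MUSCLES:
        rect, env = chains[muscle]
        bg = background_stats(env, ad_onset, *params.postural_background)
        onset = _detect_and_refine(rect, env, bg, (
            ad_onset + params.postural_search[0],
            ad_onset + params.postural_search[1],
        ), params)
        records.append(
            OnsetRecord(
                muscle=muscle,
                trial=trial,
                ad_onset_ms=ad_onset,
                onset_ms=onset,
                relative_onset_ms=None if onset is None else onset - ad_onset,
                detected=onset is not None,
            )
        )
    return records


def subject_means(records: pd.DataFrame, missing_flag_fraction: float = 0.5) -> pd.DataFrame:
    """Per (subject, group, condition, muscle) mean relative onset.

    ``records`` must have columns ``subject, group, condition, muscle,
    relative_onset_ms`` (NaN = undetected). Cells where more than
    ``missing_flag_fraction`` of trials are missing are flagged; fully empty
    cells yield NaN means and are excluded downstream.
    """
    grouped = records.groupby(["subject", "group", "condition", "muscle"], sort=True)
    out = grouped["relative_onset_ms"].agg(
        mean_relative_onset_ms="mean",
        n_trials="size",
        n_detected="count",
    ).reset_index()
    out["flagged_missing"] = (
        out["n_detected"] < (1.0 - missing_flag_fraction) * out["n_trials"]
    )
    return out
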