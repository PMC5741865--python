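"""Target-locked ERP averaging and P300 extraction at Pz.

Epochs span −200..+800 ms around each accepted target; the mean over the
200-ms pre-stimulus interval is the baseline and is subtracted per epoch.
Exactly the first 20 accepted epochs enter the average. The averaged
waveform is smoothed with a 30-Hz zero-phase low-pass, and the P300 is the
largest positive local maximum between 250 and 500 ms post-stimulus;
latency is the peak time re stimulus onset and amplitude the voltage from
the (zero) baseline to the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from apakit.core_model import Signal, slice_epoch
from apakit.preprocessing import ERP_LOWPASS, FilterSpec, butterworth_filter

EPOCH_FROM_MS = -200.0
EPOCH_TO_MS = 800.0
BASELINE = (-200.0, 0.0)
P300_WINDOW = (250.0, 500.0)
N_TRIALS_REQUIRED = 20


class InsufficientTrialsError(ValueError):
    """Fewer accepted trials than the averaging requires."""


@dataclass(frozen=True)
class ErpResult:
    waveform: Signal  # averaged, smoothed, t0 = -200 ms re target
    n_trials: int
    p300_latency_ms: float | None
    p300_amplitude_uv: float | None
    found: bool
    boundary: bool  # waveform still rising at the window's right edge


def epoch_and_baseline(
    eeg: Signal, target_times_ms: list[float], accepted: list[int] | None = None
) -> list[Signal]:
    """One baseline-corrected epoch per accepted target.

    ``accepted`` indexes into ``target_times_ms``; None takes all targets.
    """
    if accepted is None:
        accepted = list(range(len(target_times_ms)))
    epochs = []
    for idx in accepted:
        ep = slice_epoch(eeg, target_times_ms[idx], EPOCH_FROM_MS, EPOCH_TO_MS)
        b0 = ep.index_at(BASELINE[0])
        b1 = ep.index_at(BASELINE[1])
        baseline = float(np.mean(ep.values[b0:b1]))
        epochs.append(replace(ep, values=ep.values - baseline))
    return epochs


def average_epochs(epochs: list[Signal], n_required: int = N_TRIALS_REQUIRED) -> Signal:
    """Pointwise mean of exactly the first ``n_required`` epochs."""
    if len(epochs) < n_required:
        raise InsufficientTrialsError(
            f"averaging requires {n_required} accepted trials, got {len(epochs)}"
        )
    used = epochs[:n_required]
    stack = np.stack([ep.values for ep in used])
    return replace(used[0], values=stack.mean(axis=0))


def smooth_average(avg: Signal) -> Signal:
    return butterworth_filter(avg, FilterSpec(**ERP_LOWPASS))


def find_p300(avg: Signal) -> tuple[float | None, float | None, bool, bool]:
    """Largest positive local maximum in the 250–500 ms window.

    ``avg`` must be the baseline-corrected, smoothed average (epoch time,
    t0 = −200 ms). A peak needs both neighbours strictly lower; ties on
    amplitude go to the earliest peak. A waveform still rising at the
    window's right edge sets the boundary flag instead of returning a peak.

    Returns ``(latency_ms, amplitude_uv, found, boundary)``.
    """
    v = avg.values
    i0 = avg.index_at(P300_WINDOW[0])
    i1 = avg.index_at(P300_WINDOW[1])
    best_i, best_v = None, 0.0
    for i in range(max(i0, 1), min(i1 + 1, v.size - 1)):
        if v[i] > 0 and v[i] > v[i - 1] and v[i] > v[i + 1]:
            if best_i is None or v[i] > best_v:
                best_i, best_v = i, v[i]
    if best_i is None:
        boundary = i1 < v.size and v[i1] > 0 and bool(np.all(np.diff(v[i0 : i1 + 1]) > 0))
        return None, None, False, boundary
    return avg.time_at(best_i), float(best_v), True, False


def compute_erp(
    eeg_pz: Signal,
    target_times_ms: list[float],
    accepted: list[int],
    n_required: int = N_TRIALS_REQUIRED,
) -> ErpResult:
    """Full ERP chain for one subject/condition: epoch, baseline, average
    the first ``n_required`` accepted trials, smooth, extract P300."""
    epochs = epoch_and_baseline(eeg_pz, target_times_ms, accepted)
    avg = smooth_average(average_epochs(epochs, n_required))
    lat, amp, found, boundary = find_p300(avg)
    return ErpResult(
        waveform=avg,
        n_trials=n_required,
        p300_latency_ms=lat,
        p300_amplitude_uv=amp,
        found=found,
        boundary=boundary,
    )
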