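"""Filtering, rectification and envelope computation for EMG and ERP traces.

The EMG chain is: 40-Hz high-pass (7th-order Butterworth, removing ECG and
movement artifact), full-wave rectification, then a short moving-average
envelope used by the burst-onset criterion. The averaged ERP waveform is
smoothed with a 30-Hz low-pass before peak extraction.

All filters are applied forward-backward (zero phase). Causal filtering
would delay detected onsets by the filter's group delay and corrupt ms-scale
onset comparisons between muscles; zero-phase application preserves timing,
at the cost of the effective magnitude response being the square of the
single-pass design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from apakit.core_model import Signal

#: single-pass filter order for the EMG high-pass
EMG_HIGHPASS = dict(kind="highpass", cutoff_hz=40.0, order=7)
#: smoothing applied to the averaged ERP waveform
ERP_LOWPASS = dict(kind="lowpass", cutoff_hz=30.0, order=4)
#: moving-average window of the rectified-EMG envelope, ms
ENVELOPE_WINDOW_MS = 20.0


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter: kind, −3 dB cutoff, single-pass order, phase."""

    kind: str  # "highpass" | "lowpass"
    cutoff_hz: float
    order: int = 7
    application: str = "zero_phase"  # "zero_phase" | "causal"

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass"):
            raise ValueError(f"kind must be highpass/lowpass, got {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff must be positive")
        if self.application not in ("zero_phase", "causal"):
            raise ValueError(f"unknown application {self.application!r}")

    def validate_for(self, fs: float) -> None:
        if self.cutoff_hz >= fs / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
            )


def butterworth_filter(sig: Signal, spec: FilterSpec) -> Signal:
    """Apply a Butterworth filter, preserving length and ``t0``.

    Zero-phase application uses ``filtfilt``; the magnitude response is then
    ``|H|^2`` of the single-pass design (still −6 dB at the nominal cutoff),
    with no group delay.
    """
    spec.validate_for(sig.fs)
    sos = sps.butter(
        spec.order, spec.cutoff_hz, btype=spec.kind, fs=sig.fs, output="sos"
    )
    if spec.application == "zero_phase":
        out = sps.sosfiltfilt(sos, sig.values)
    else:
        out = sps.sosfilt(sos, sig.values)
    return replace(sig, values=out)


def butterworth_gain(spec: FilterSpec, freq_hz: float, fs: float) -> float:
    """Analytic magnitude response of ``spec`` at ``freq_hz`` (squared for
    zero-phase application). Used as an oracle for filter behaviour."""
    w = freq_hz / spec.cutoff_hz
    if spec.kind == "highpass":
        w = 1.0 / w
    g = 1.0 / np.sqrt(1.0 + w ** (2 * spec.order))
    return float(g * g) if spec.application == "zero_phase" else float(g)


def rectify(sig: Signal) -> Signal:
    """Full-wave rectification (pointwise absolute value)."""
    return replace(sig, values=np.abs(sig.values))


def envelope(rectified: Signal, window_ms: float = ENVELOPE_WINDOW_MS) -> Signal:
    """Centered moving-average envelope of a rectified EMG.

    Length is preserved; at the edges the window shrinks to the available
    samples (no padding), so a constant input maps to itself exactly.
    """
    if window_ms < 1:
        raise ValueError("window_ms must be >= 1 ms")
    n = rectified.n
    w = int(round(window_ms * rectified.fs / 1000.0))
    w = max(w, 1)
    half_lo = (w - 1) // 2
    half_hi = w - 1 - half_lo
    csum = np.concatenate(([0.0], np.cumsum(rectified.values)))
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return replace(rectified, values=out)


def emg_envelope_chain(sig: Signal, *, highpass: FilterSpec | None = None,
                       window_ms: float = ENVELOPE_WINDOW_MS) -> tuple[Signal, Signal]:
    """Full EMG chain: high-pass, rectify, envelope.

    Returns ``(rectified, envelope)`` — onset refinement needs the rectified
    wave, the burst criterion runs on the envelope.
    """
    hp = highpass or FilterSpec(**EMG_HIGHPASS)
    rect = rectify(butterworth_filter(sig, hp))
    return rect, envelope(rect, window_ms)
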