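"""Shared fixtures: compact crafted recordings with exactly known content."""

from __future__ import annotations

import numpy as np
import pytest

from apakit.core_model import REQUIRED_CHANNELS, Event, Recording, Signal


def make_recording(
    duration_ms: float = 20000.0,
    fs: float = 1000.0,
    qsp_cm: float = 5.0,
    channel_values: dict[str, np.ndarray] | None = None,
    events: list[Event] | None = None,
    meta: dict | None = None,
    emg_noise_seed: int | None = None,
    emg_noise_sd: float = 0.05,
) -> Recording:
    """A valid 9-channel recording; unspecified channels are flat.

    ``emg_noise_seed`` adds seeded Gaussian background to the EMG channels
    (burst detection needs a nonzero background to estimate its threshold).
    """
    n = int(round(duration_ms * fs / 1000.0))
    units = {ch: "uV" for ch in ("Fz", "Cz", "Pz", "EOG")}
    units["CoPap"] = "cm"
    channel_values = channel_values or {}
    rng = np.random.default_rng(emg_noise_seed)
    channels = {}
    for ch in REQUIRED_CHANNELS:
        if ch in channel_values:
            vals = np.asarray(channel_values[ch], dtype=float)
        elif ch == "CoPap":
            vals = np.full(n, qsp_cm)
        elif ch in ("AD", "ES", "BF", "GcM") and emg_noise_seed is not None:
            vals = rng.normal(0.0, emg_noise_sd, n)
        else:
            vals = np.zeros(n)
        channels[ch] = Signal(values=vals, fs=fs, units=units.get(ch, "a.u."))
    full_meta = {"subject": "t01", "group": "young", "qsp_cm": qsp_cm}
    full_meta.update(meta or {})
    return Recording(channels=channels, events=events or [], meta=full_meta)


def emg_with_burst(
    n: int,
    onset: int,
    duration: int = 150,
    amplitude: float = 1.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    carrier_hz: float = 100.0,
    fs: float = 1000.0,
) -> np.ndarray:
    """Background noise plus a deterministic 100-Hz carrier burst (passes the
    40-Hz high-pass almost untouched), for trials with exactly known onsets."""
    rng = np.random.default_rng(seed)
    v = rng.normal(0.0, noise_sd, n)
    t = np.arange(duration) / fs
    v[onset : onset + duration] += amplitude * np.sin(2 * np.pi * carrier_hz * t)
    return v


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)
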