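"""Data model for signals, events and sessions, plus session-directory I/O.

Conventions used throughout the package:

* time is expressed in milliseconds as floats, relative to session start;
* sample indexing is 0-based; every analysis window is half-open ``[a, b)``;
* ms -> sample conversion is round-to-nearest: ``round((t - t0) * fs / 1000)``;
* the default sampling rate is 1000 Hz (all channels of a session share fs).

A session on disk is a directory holding ``channels.csv`` (wide table:
``time_ms`` plus one column per channel), ``events.csv``
(``time_ms,label,condition``) and ``meta.json`` (subject, group, fs, per
channel units, quiet-standing CoP reference).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: channels every Recording must carry
REQUIRED_CHANNELS = ("AD", "ES", "BF", "GcM", "Fz", "Cz", "Pz", "EOG", "CoPap")

#: muscles analysed for anticipatory activation, relative to the focal AD
POSTURAL_MUSCLES = ("ES", "BF", "GcM")

EEG_CHANNELS = ("Fz", "Cz", "Pz")

VALID_UNITS = ("uV", "mV", "cm", "a.u.")

EVENT_LABELS = ("target", "nontarget", "go_window_start")

CONDITIONS = ("p15", "p45", "self")


class SchemaError(ValueError):
    """A session is missing a required channel or field."""


class ConsistencyError(ValueError):
    """Channels of one session disagree on sampling rate or length."""


class BoundsError(ValueError):
    """A requested analysis window falls outside the recorded signal."""


@dataclass(frozen=True)
class Signal:
    """One uniformly sampled channel.

    Parameters
    ----------
    values : ndarray
        Sample values; must be non-empty and finite.
    fs : float
        Sampling rate in Hz (> 0).
    units : str
        One of ``uV``, ``mV``, ``cm``, ``a.u.``.
    t0 : float
        Time of the first sample in ms relative to session start.
    """

    values: np.ndarray
    fs: float = 1000.0
    units: str = "a.u."
    t0: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(vals)):
            raise ValueError("signal contains non-finite samples")
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}, got {self.units!r}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_ms(self) -> float:
        return self.n / self.fs * 1000.0

    @property
    def t_end(self) -> float:
        """End of the covered half-open time interval ``[t0, t_end)``."""
        return self.t0 + self.duration_ms

    def index_at(self, t_ms: float) -> int:
        """0-based sample index of session time ``t_ms`` (round-to-nearest)."""
        return int(round((t_ms - self.t0) * self.fs / 1000.0))

    def time_at(self, index: int) -> float:
        """Session time in ms of sample ``index``."""
        return self.t0 + index * 1000.0 / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) * 1000.0 / self.fs


@dataclass(frozen=True, order=True)
class Event:
    """A stimulus or task marker at ``time_ms`` (session time)."""

    time_ms: float
    label: str = field(compare=False)
    condition: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.label not in EVENT_LABELS:
            raise ValueError(f"unknown event label {self.label!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class Recording:
    """One session: named channels, the event log, and subject metadata.

    ``meta`` must carry ``subject``, ``group`` (``young``/``older``) and
    ``qsp_cm`` — the quiet-standing CoP reference the trial-acceptance rule
    is anchored to (mean of five 10-s quiet-standing measurements in the
    experimental protocol).
    """

    channels: dict[str, Signal]
    events: list[Event]
    meta: dict

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in REQUIRED_CHANNELS:
            if name not in self.channels:
                raise SchemaError(f"required channel {name!r} missing from session")
        fss = {sig.fs for sig in self.channels.values()}
        if len(fss) != 1:
            raise ConsistencyError(f"channels disagree on sampling rate: {sorted(fss)}")
        for name in EEG_CHANNELS + ("EOG",):
            if self.channels[name].units != "uV":
                raise ConsistencyError(f"channel {name} must be in uV")
        if self.channels["CoPap"].units != "cm":
            raise ConsistencyError("channel CoPap must be in cm")
        times = [ev.time_ms for ev in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConsistencyError("events must be strictly increasing in time")
        for key in ("subject", "group", "qsp_cm"):
            if key not in self.meta:
                raise SchemaError(f"meta missing required field {key!r}")

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def qsp_cm(self) -> float:
        return float(self.meta["qsp_cm"])

    def events_by(self, label: str | None = None, condition: str | None = None) -> list[Event]:
        out = self.events
        if label is not None:
            out = [e for e in out if e.label == label]
        if condition is not None:
            out = [e for e in out if e.condition == condition]
        return out


def slice_epoch(sig: Signal, anchor_ms: float, from_ms: float, to_ms: float) -> Signal:
    """Cut the half-open window ``[anchor+from, anchor+to)`` out of ``sig``.

    The returned Signal's ``t0`` equals ``from_ms`` — epoch time is relative
    to the anchor, so an epoch cut with ``from_ms=-200`` starts at −200 ms.
    Length depends only on ``(to_ms - from_ms)`` and ``fs``, never on the
    anchor.
    """
    if to_ms <= from_ms:
        raise ValueError("to_ms must exceed from_ms")
    i0 = sig.index_at(anchor_ms + from_ms)
    n = int(round((to_ms - from_ms) * sig.fs / 1000.0))
    if i0 < 0 or i0 + n > sig.n:
        raise BoundsError(
            f"window [{anchor_ms + from_ms:g}, {anchor_ms + to_ms:g}) ms outside "
            f"signal covering [{sig.t0:g}, {sig.t_end:g}) ms"
        )
    return replace(sig, values=sig.values[i0 : i0 + n].copy(), t0=from_ms)


# ---------------------------------------------------------------------------
# session-directory I/O


def write_session(rec: Recording, path: str | Path) -> None:
    """Write ``rec`` as a session directory (CSV channels/events + JSON meta).

    Numeric round trip through :func:`read_session` is lossless to full
    float64 precision (``repr``-style formatting).
    """
    rec.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    fs = rec.fs
    n = max(sig.n for sig in rec.channels.values())
    wide = {"time_ms": np.arange(n) * 1000.0 / fs}
    for name, sig in rec.channels.items():
        col = np.full(n, np.nan)
        col[: sig.n] = sig.values
        wide[name] = col
    pd.DataFrame(wide).to_csv(path / "channels.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        {
            "time_ms": [e.time_ms for e in rec.events],
            "label": [e.label for e in rec.events],
            "condition": [e.condition for e in rec.events],
        }
    ).to_csv(path / "events.csv", index=False, float_format="%.17g")

    meta = dict(rec.meta)
    meta["fs"] = fs
    meta["units"] = {name: sig.units for name, sig in rec.channels.items()}
    meta["t0"] = {name: sig.t0 for name, sig in rec.channels.items()}
    meta["n_samples"] = {name: sig.n for name, sig in rec.channels.items()}
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def read_session(path: str | Path) -> Recording:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    for fname in ("channels.csv", "events.csv", "meta.json"):
        if not (path / fname).exists():
            raise SchemaError(f"session at {path} missing {fname}")
    meta = json.loads((path / "meta.json").read_text())
    fs = float(meta.pop("fs"))
    units = meta.pop("units")
    t0s = meta.pop("t0", {})
    n_samples = meta.pop("n_samples", {})

    wide = pd.read_csv(path / "channels.csv", float_precision="round_trip")
    channels: dict[str, Signal] = {}
    for name in wide.columns:
        if name == "time_ms":
            continue
        vals = wide[name].to_numpy()
        n = int(n_samples.get(name, vals.size))
        channels[name] = Signal(
            values=vals[:n],
            fs=fs,
            units=units.get(name, "a.u."),
            t0=float(t0s.get(name, 0.0)),
        )

    evdf = pd.read_csv(path / "events.csv", float_precision="round_trip")
    events = [
        Event(float(r.time_ms), str(r.label), str(r.condition))
        for r in evdf.itertuples(index=False)
    ]
    return Recording(channels=channels, events=events, meta=meta)
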