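"""Seeded simulators producing sessions with known ground truth.

The generators emulate the experimental design the analysis targets:
auditory oddball blocks of 72 stimuli at a 2.5-s inter-stimulus interval
with 15% or 45% target probability (tone identities 2000 Hz = target,
1000 Hz = non-target carried as metadata only), plus a self-timing
condition in which arm flexion starts at the subject's own pace within a
3-s go window. Trials repeat until 20 target trials survive screening.

Signal models:

* EMG — zero-mean Gaussian background; a burst is an amplitude-modulated
  variance step (linear rise <= 10 ms) scaled so the rectified amplitude
  exceeds the background envelope mean by a configurable multiple of the
  background envelope SD.
* EEG — Gaussian background plus a smooth positive Gaussian-shaped
  deflection time-locked to each target (the P300 stand-in); non-targets
  get no deflection.
* EOG — low-noise trace with Poisson-placed biphasic blink transients.
  Background blinks are placed outside trial windows (subjects typically
  suppress blinks during trials); artifact injections place one inside.
* CoPap — mean-reverting (Ornstein-Uhlenbeck) drift around the
  quiet-standing reference, with scheduled excursions to create
  out-of-range trials on demand. In full sessions the pre-flexion window
  of non-violation trials is kept in range, mirroring the online
  buzzing-sound feedback that gated every real trial.

Determinism: one global seed expands into per-channel/per-purpose child
seeds through a fixed registry (``_rng``), so adding a channel never
perturbs the others, and identical (config, profile, seed) yields
bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from apakit.core_model import (
    CONDITIONS,
    POSTURAL_MUSCLES,
    Event,
    Recording,
    Signal,
)

SQRT_2_OVER_PI = float(np.sqrt(2.0 / np.pi))
# rectified-sample SD of zero-mean Gaussian noise, as a multiple of sigma
_RECT_SD_RATIO = float(np.sqrt(1.0 - 2.0 / np.pi))

TONE_HZ = {"target": 2000, "nontarget": 1000}


def _rng(seed: int, *tags: str) -> np.random.Generator:
    """Child generator for (seed, tags) via a stable splitting scheme."""
    key = tuple(zlib.crc32(t.encode()) for t in tags)
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + key))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one simulated session (defaults = the study's conditions)."""

    condition: str = "p15"  # p15 | p45 | self
    n_stimuli: int = 72  # stimuli per oddball block
    isi_ms: float = 2500.0
    n_target_trials: int = 20  # accepted target trials wanted
    seed: int = 0
    lead_in_ms: float = 5000.0
    block_gap_ms: float = 5000.0
    self_trial_period_ms: float = 7000.0
    # injected violations: indices among target trials (in order of occurrence)
    cop_violation_trials: tuple[int, ...] = ()
    artifact_trials: tuple[int, ...] = ()
    miss_trials: tuple[int, ...] = ()

    @property
    def target_probability(self) -> float:
        return {"p15": 0.15, "p45": 0.45, "self": float("nan")}[self.condition]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.n_stimuli < 1:
            raise ValueError("n_stimuli must be >= 1")
        if self.condition != "self":
            if round(self.target_probability * self.n_stimuli) == 0:
                raise ValueError("target probability rounds to zero targets per block")


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth generative parameters for one subject.

    ``offsets_ms`` holds the true postural-muscle onset offsets relative to
    the focal AD burst, per condition (negative = precedes AD).
    """

    offsets_ms: dict = field(
        default_factory=lambda: {
            "ES": {"p15": -30.0, "p45": -30.0, "self": -35.0},
            "BF": {"p15": -25.0, "p45": -30.0, "self": -45.0},
            "GcM": {"p15": -20.0, "p45": -35.0, "self": -55.0},
        }
    )
    trial_jitter_sd_ms: float = 10.0
    ad_latency_mean_ms: float = 250.0  # AD onset after target
    ad_latency_sd_ms: float = 30.0
    ad_burst_multiple: float = 8.0  # rectified amplitude, background SDs
    postural_burst_multiple: float = 6.0
    burst_duration_ms: float = 150.0
    burst_rise_ms: float = 10.0
    emg_noise_sd: float = 0.05  # mV
    erp_latency_ms: dict = field(
        default_factory=lambda: {"p15": 380.0, "p45": 350.0}
    )
    erp_amplitude_uv: dict = field(
        default_factory=lambda: {"p15": 12.0, "p45": 8.0}
    )
    erp_width_ms: float = 50.0  # SD of the Gaussian-shaped deflection
    eeg_noise_sd_uv: float = 10.0
    blink_rate_per_min: float = 2.0
    blink_amplitude_uv: float = 300.0
    cop_drift_sd_cm: float = 0.5
    qsp_cm: float = 5.0

    def __post_init__(self) -> None:
        if self.postural_burst_multiple <= 2 or self.ad_burst_multiple <= 2:
            raise ValueError(
                "burst amplitude multiples must exceed the 2-SD detection criterion"
            )
        for cond, lat in self.erp_latency_ms.items():
            if not 250.0 <= lat <= 500.0:
                raise ValueError(
                    f"ERP latency {lat} ms ({cond}) outside the valid P300 window"
                )


# ---------------------------------------------------------------------------
# elementary generators


def generate_stimulus_sequence(cfg: SimulationConfig, start_ms: float = 0.0) -> list[Event]:
    """One oddball block: ``n_stimuli`` slots at fixed ISI with exactly
    ``round(p * n)`` targets placed by seeded shuffle."""
    n_targets = int(round(cfg.target_probability * cfg.n_stimuli))
    if n_targets == 0:
        raise ValueError("target probability rounds to zero targets per block")
    labels = np.array(
        ["target"] * n_targets + ["nontarget"] * (cfg.n_stimuli - n_targets)
    )
    _rng(cfg.seed, "stimulus_order", f"block@{start_ms:.0f}").shuffle(labels)
    return [
        Event(start_ms + i * cfg.isi_ms, str(lab), cfg.condition)
        for i, lab in enumerate(labels)
    ]


def burst_sd_multiplier(amplitude_multiple: float) -> float:
    """Gaussian-SD scale giving a rectified burst amplitude (folded-normal
    mean) of ``background rectified mean + multiple x background rectified
    SD``; both moments refer to the rectified background samples."""
    return 1.0 + amplitude_multiple * _RECT_SD_RATIO / SQRT_2_OVER_PI


def generate_emg(
    true_onsets_ms,
    profile: SubjectProfile,
    duration_ms: float,
    rng: np.random.Generator,
    amplitude_multiple: float | None = None,
    fs: float = 1000.0,
    units: str = "mV",
) -> Signal:
    """EMG background noise with variance-step bursts at ``true_onsets_ms``.

    ``true_onsets_ms`` may be None (no burst), a scalar, or a sequence.
    Each burst ramps linearly to the target SD over the rise time and holds
    it for the burst duration.
    """
    if true_onsets_ms is None:
        onsets: list[float] = []
    elif np.isscalar(true_onsets_ms):
        onsets = [float(true_onsets_ms)]
    else:
        onsets = [float(t) for t in true_onsets_ms]
    n = int(round(duration_ms * fs / 1000.0))
    mult = amplitude_multiple or profile.postural_burst_multiple
    scale = np.full(n, profile.emg_noise_sd)
    s_burst = profile.emg_noise_sd * burst_sd_multiplier(mult)
    n_rise = max(int(round(profile.burst_rise_ms * fs / 1000.0)), 1)
    n_burst = int(round(profile.burst_duration_ms * fs / 1000.0))
    for onset in onsets:
        if not 0 <= onset < duration_ms:
            raise ValueError(f"burst onset {onset} ms outside the signal")
        i = int(round(onset * fs / 1000.0))
        ramp = np.linspace(profile.emg_noise_sd, s_burst, n_rise, endpoint=False)
        hold_end = min(i + n_burst, n)
        scale[i : min(i + n_rise, n)] = ramp[: max(min(i + n_rise, n) - i, 0)]
        scale[min(i + n_rise, n) : hold_end] = s_burst
    return Signal(values=rng.normal(0.0, 1.0, n) * scale, fs=fs, units=units)


def generate_eeg(
    target_times_ms,
    profile: SubjectProfile,
    duration_ms: float,
    rng: np.random.Generator,
    latency_ms: float = 350.0,
    amplitude_uv: float = 10.0,
    gain: float = 1.0,
    fs: float = 1000.0,
) -> Signal:
    """EEG background noise plus a positive Gaussian-shaped deflection of the
    given latency/amplitude time-locked to each target. ``gain`` scales the
    deflection (parietal maximum: Pz 1.0, Cz/Fz attenuated)."""
    n = int(round(duration_ms * fs / 1000.0))
    out = rng.normal(0.0, profile.eeg_noise_sd_uv, n)
    t = np.arange(n) * 1000.0 / fs
    w = profile.erp_width_ms
    for tt in np.atleast_1d(np.asarray(target_times_ms, dtype=float)):
        center = tt + latency_ms
        i0 = max(int((center - 5 * w) * fs / 1000.0), 0)
        i1 = min(int((center + 5 * w) * fs / 1000.0), n)
        out[i0:i1] += gain * amplitude_uv * np.exp(
            -0.5 * ((t[i0:i1] - center) / w) ** 2
        )
    return Signal(values=out, fs=fs, units="uV")


def blink_waveform(amplitude_uv: float, fs: float = 1000.0) -> np.ndarray:
    """Biphasic blink transient: dominant positive lobe (~150 ms) followed by
    a smaller negative rebound."""
    t = np.arange(int(round(0.35 * fs))) * 1000.0 / fs
    pos = np.exp(-0.5 * ((t - 80.0) / 35.0) ** 2)
    neg = 0.3 * np.exp(-0.5 * ((t - 220.0) / 55.0) ** 2)
    return amplitude_uv * (pos - neg)


def generate_blinks(
    rate_per_min: float,
    amplitude_uv: float,
    duration_ms: float,
    rng: np.random.Generator,
    noise_sd_uv: float = 5.0,
    exclude_windows: list[tuple[float, float]] | None = None,
    force_times_ms: list[float] | None = None,
    fs: float = 1000.0,
) -> Signal:
    """Low-noise EOG trace with Poisson-placed biphasic blinks.

    ``exclude_windows`` keeps spontaneous blinks (their full extent) out of
    the given [start, end) intervals; ``force_times_ms`` adds blinks at
    exact times regardless.
    """
    n = int(round(duration_ms * fs / 1000.0))
    out = rng.normal(0.0, noise_sd_uv, n)
    wave = blink_waveform(amplitude_uv, fs)
    span = wave.size * 1000.0 / fs
    n_blinks = rng.poisson(rate_per_min * duration_ms / 60000.0)
    times = np.sort(rng.uniform(0.0, duration_ms - span, n_blinks))
    placed = []
    for t in times:
        if exclude_windows and any(
            t < end and t + span > start for start, end in exclude_windows
        ):
            continue
        placed.append(float(t))
    for t in placed + list(force_times_ms or []):
        i = int(round(t * fs / 1000.0))
        seg = wave[: max(min(n - i, wave.size), 0)]
        out[i : i + seg.size] += seg
    return Signal(values=out, fs=fs, units="uV")


def generate_cop(
    qsp_cm: float,
    drift_sd_cm: float,
    excursions: list[tuple[float, float, float]],
    duration_ms: float,
    rng: np.random.Generator,
    tau_ms: float = 1000.0,
    clamp_windows: list[tuple[float, float]] | None = None,
    clamp_cm: float = 0.95,
    fs: float = 1000.0,
) -> Signal:
    """Mean-reverting drift around ``qsp_cm`` plus scheduled excursions.

    An Ornstein-Uhlenbeck walk with stationary SD ``drift_sd_cm`` and time
    constant ``tau_ms``. ``excursions`` is a list of
    ``(start_ms, end_ms, offset_cm)`` added on top. ``clamp_windows``
    clips the *drift* to ``qsp ± clamp_cm`` inside the given intervals
    (emulating the in-range gate that preceded every real trial);
    excursions are added after clamping so they always take effect.
    """
    n = int(round(duration_ms * fs / 1000.0))
    phi = float(np.exp(-1000.0 / (tau_ms * fs)))
    innov_sd = drift_sd_cm * np.sqrt(max(1.0 - phi * phi, 0.0))
    steps = rng.normal(0.0, 1.0, n)
    e = innov_sd * steps
    e[0] = drift_sd_cm * steps[0]  # start in the stationary law
    from scipy.signal import lfilter

    x = lfilter([1.0], [1.0, -phi], e)
    if clamp_windows:
        for start, end in clamp_windows:
            i0 = max(int(round(start * fs / 1000.0)), 0)
            i1 = min(int(round(end * fs / 1000.0)), n)
            x[i0:i1] = np.clip(x[i0:i1], -clamp_cm, clamp_cm)
    for start, end, offset in excursions:
        i0 = max(int(round(start * fs / 1000.0)), 0)
        i1 = min(int(round(end * fs / 1000.0)), n)
        x[i0:i1] += offset
    return Signal(values=qsp_cm + x, fs=fs, units="cm")


# ---------------------------------------------------------------------------
# full sessions


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size), out)
        bad = (out < lo) | (out > hi)
    return out


def generate_session(
    cfg: SimulationConfig, profile: SubjectProfile, meta: dict | None = None
) -> tuple[Recording, pd.DataFrame]:
    """Compose a full 9-channel session plus its ground-truth table.

    Oddball blocks are appended until enough target trials exist to cover
    the wanted count plus every injected rejection (mirroring the protocol's
    block repetition until 20 accepted trials). The self-timing condition
    has go-window markers instead of tones; AD bursts fall uniformly within
    0.5–3 s of each go-window start.

    The ground-truth table has one row per target trial: anchor time, true
    AD onset (NaN for injected misses), true postural onsets and offsets,
    configured ERP latency/amplitude, and the injected rejection cause.
    """
    seed = cfg.seed
    cond = cfg.condition
    n_rejected = len(
        set(cfg.cop_violation_trials) | set(cfg.artifact_trials) | set(cfg.miss_trials)
    )
    n_targets_needed = cfg.n_target_trials + n_rejected

    events: list[Event] = []
    if cond == "self":
        for k in range(n_targets_needed):
            events.append(
                Event(cfg.lead_in_ms + k * cfg.self_trial_period_ms, "go_window_start", cond)
            )
        duration_ms = cfg.lead_in_ms + n_targets_needed * cfg.self_trial_period_ms + 2000.0
    else:
        per_block = int(round(cfg.target_probability * cfg.n_stimuli))
        n_blocks = int(np.ceil(n_targets_needed / per_block))
        t = cfg.lead_in_ms
        for _ in range(n_blocks):
            events.extend(generate_stimulus_sequence(replace(cfg, seed=seed), t))
            t += cfg.n_stimuli * cfg.isi_ms + cfg.block_gap_ms
        duration_ms = t + 2000.0

    anchors = [e.time_ms for e in events if e.label in ("target", "go_window_start")]
    rng_tr = _rng(seed, "trials")
    rows = []
    for k, anchor in enumerate(anchors):
        miss = k in cfg.miss_trials
        if cond == "self":
            ad = anchor + rng_tr.uniform(500.0, 3000.0)
        else:
            # truncated with margin inside the 200-500 ms search window so a
            # genuine response never straddles the window edge
            ad = anchor + _truncated_normal(
                rng_tr, profile.ad_latency_mean_ms, profile.ad_latency_sd_ms, 220.0, 480.0
            )
        row = {
            "trial": k,
            "condition": cond,
            "anchor_ms": anchor,
            "true_ad_onset_ms": np.nan if miss else ad,
            "injected_rejection": (
                "no_ad_burst" if miss
                else "cop_out_of_range" if k in cfg.cop_violation_trials
                else "artifact" if k in cfg.artifact_trials
                else "none"
            ),
            "erp_latency_ms": profile.erp_latency_ms.get(cond, np.nan),
            "erp_amplitude_uv": profile.erp_amplitude_uv.get(cond, np.nan),
        }
        for muscle in POSTURAL_MUSCLES:
            offset = profile.offsets_ms[muscle][cond] + rng_tr.normal(
                0.0, profile.trial_jitter_sd_ms
            )
            row[f"true_{muscle}_offset_ms"] = np.nan if miss else offset
            row[f"true_{muscle}_onset_ms"] = np.nan if miss else ad + offset
        rows.append(row)
    truth = pd.DataFrame(rows)

    active = truth[truth.injected_rejection != "no_ad_burst"]
    channels: dict[str, Signal] = {}
    channels["AD"] = generate_emg(
        active.true_ad_onset_ms.tolist(), profile, duration_ms,
        _rng(seed, "emg", "AD"), amplitude_multiple=profile.ad_burst_multiple,
    )
    for muscle in POSTURAL_MUSCLES:
        channels[muscle] = generate_emg(
            active[f"true_{muscle}_onset_ms"].tolist(), profile, duration_ms,
            _rng(seed, "emg", muscle),
        )

    target_times = [] if cond == "self" else anchors
    for name, gain in (("Pz", 1.0), ("Cz", 0.8), ("Fz", 0.6)):
        channels[name] = generate_eeg(
            target_times, profile, duration_ms, _rng(seed, "eeg", name),
            latency_ms=profile.erp_latency_ms.get(cond, 350.0),
            amplitude_uv=profile.erp_amplitude_uv.get(cond, 0.0),
            gain=gain,
        )

    trial_windows = [(a - 400.0, a + 1200.0) for a in anchors]
    forced_blinks = [
        anchors[k] + 300.0 for k in cfg.artifact_trials if k < len(anchors)
    ]
    channels["EOG"] = generate_blinks(
        profile.blink_rate_per_min, profile.blink_amplitude_uv, duration_ms,
        _rng(seed, "eog"), exclude_windows=trial_windows, force_times_ms=forced_blinks,
    )
    # blink leakage into frontal-dominant EEG (decreasing toward parietal)
    for name, leak in (("Fz", 0.30), ("Cz", 0.20), ("Pz", 0.12)):
        eog = channels["EOG"].values - np.mean(channels["EOG"].values)
        channels[name] = replace(channels[name], values=channels[name].values + leak * eog)

    clamp_windows = [
        (row.true_ad_onset_ms - 700.0, row.true_ad_onset_ms + 50.0)
        for row in truth.itertuples()
        if row.injected_rejection in ("none", "artifact")
        and np.isfinite(row.true_ad_onset_ms)
    ]
    excursions = [
        (row.true_ad_onset_ms - 450.0, row.true_ad_onset_ms - 150.0, 2.0)
        for row in truth.itertuples()
        if row.injected_rejection == "cop_out_of_range"
    ]
    channels["CoPap"] = generate_cop(
        profile.qsp_cm, profile.cop_drift_sd_cm, excursions, duration_ms,
        _rng(seed, "cop"), clamp_windows=clamp_windows,
    )

    full_meta = {
        "subject": "sim",
        "group": "young",
        "qsp_cm": profile.qsp_cm,
        "condition": cond,
        "tone_hz": TONE_HZ,
        "seed": seed,
    }
    full_meta.update(meta or {})
    rec = Recording(channels=channels, events=events, meta=full_meta)
    return rec, truth


# ---------------------------------------------------------------------------
# cohort-level effect structure
#
# Group mean offset tables encode the qualitative pattern the analysis is
# meant to resolve: young adults show graded anticipatory gastrocnemius
# activation (self-timing earliest, then 45%, then 15%), while older adults
# show no anticipatory GcM activation in the oddball conditions, an overall
# self-vs-oddball condition effect, and no 15-vs-45 differences. Young P300
# is shorter/smaller at 45% than 15%; older P300 does not differ.

GROUP_OFFSETS_MS = {
    "young": {
        "ES": {"p15": -30.0, "p45": -30.0, "self": -35.0},
        "BF": {"p15": -25.0, "p45": -30.0, "self": -45.0},
        "GcM": {"p15": -20.0, "p45": -35.0, "self": -55.0},
    },
    "older": {
        "ES": {"p15": -15.0, "p45": -15.0, "self": -40.0},
        "BF": {"p15": -13.0, "p45": -13.0, "self": -38.0},
        "GcM": {"p15": 0.0, "p45": 0.0, "self": -25.0},
    },
}

GROUP_ERP = {
    "young": {
        "latency_ms": {"p15": 380.0, "p45": 350.0},
        "amplitude_uv": {"p15": 12.0, "p45": 8.0},
    },
    "older": {
        "latency_ms": {"p15": 400.0, "p45": 400.0},
        "amplitude_uv": {"p15": 8.0, "p45": 8.0},
    },
}

#: between-subject and residual variance components (ms / uV)
VARIANCE = dict(
    onset_subject_sd=10.0,  # subject(-by-muscle) random intercept
    onset_cell_sd=7.0,  # subject x condition residual
    p300_latency_subject_sd=25.0,
    p300_latency_cell_sd=10.0,
    p300_amplitude_subject_sd=2.5,
    p300_amplitude_cell_sd=1.2,
)

N_TRIALS_PER_CELL = 20


def make_subject_profile(
    group: str, rng: np.random.Generator, **overrides
) -> SubjectProfile:
    """Draw one subject's true parameters around the group means."""
    base = GROUP_OFFSETS_MS[group]
    offsets = {}
    for muscle in POSTURAL_MUSCLES:
        b = rng.normal(0.0, VARIANCE["onset_subject_sd"])
        offsets[muscle] = {
            cond: base[muscle][cond] + b + rng.normal(0.0, VARIANCE["onset_cell_sd"])
            for cond in CONDITIONS
        }
    erp = GROUP_ERP[group]
    b_lat = rng.normal(0.0, VARIANCE["p300_latency_subject_sd"])
    b_amp = rng.normal(0.0, VARIANCE["p300_amplitude_subject_sd"])
    latency = {
        c: float(np.clip(
            erp["latency_ms"][c] + b_lat
            + rng.normal(0.0, VARIANCE["p300_latency_cell_sd"]), 260.0, 490.0))
        for c in ("p15", "p45")
    }
    amplitude = {
        c: max(erp["amplitude_uv"][c] + b_amp
               + rng.normal(0.0, VARIANCE["p300_amplitude_cell_sd"]), 1.0)
        for c in ("p15", "p45")
    }
    return SubjectProfile(
        offsets_ms=offsets, erp_latency_ms=latency, erp_amplitude_uv=amplitude,
        **overrides,
    )


def generate_cohort_measures(
    n_per_group: int = 14, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-level measures for a young + older cohort.

    Draws each subject's true cell means from the group effect structure and
    adds the measurement noise a 20-trial pipeline average carries
    (trial jitter SD / sqrt(20)). Returns ``(onsets, erp)`` tables ready for
    the statistical battery — the fast route for power/calibration studies;
    signal-level sessions feed the same battery through the full pipeline.
    """
    rng = _rng(seed, "cohort")
    meas_sd = SubjectProfile().trial_jitter_sd_ms / np.sqrt(N_TRIALS_PER_CELL)
    onset_rows, erp_rows = [], []
    for group in ("young", "older"):
        for s in range(n_per_group):
            subject = f"{group}{s:02d}"
            prof = make_subject_profile(group, rng)
            for muscle in POSTURAL_MUSCLES:
                for cond in CONDITIONS:
                    onset_rows.append(
                        {
                            "subject": subject,
                            "group": group,
                            "condition": cond,
                            "muscle": muscle,
                            "mean_relative_onset_ms": prof.offsets_ms[muscle][cond]
                            + rng.normal(0.0, meas_sd),
                        }
                    )
            for cond in ("p15", "p45"):
                erp_rows.append(
                    {
                        "subject": subject,
                        "group": group,
                        "condition": cond,
                        "p300_latency_ms": prof.erp_latency_ms[cond]
                        + rng.normal(0.0, 3.0),
                        "p300_amplitude_uv": prof.erp_amplitude_uv[cond]
                        + rng.normal(0.0, 0.5),
                    }
                )
    return pd.DataFrame(onset_rows), pd.DataFrame(erp_rows)
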