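"""Synthetic crossover-study generator.

Generates the full study design — wake recordings at six timepoints
(T1..T6) under active and sham arms, plus a sleep night with hypnogram —
with ground truth for every injected feature, so each downstream stage
can be verified without real data.

Signal model
------------
Each channel is a sum of five band-limited Gaussian noise components,
one per analysis band, produced by filtering white noise with the same
band edges the spectral module uses (4th-order Butterworth,
forward-backward). The white-noise variance is pre-compensated by the
measured mean squared magnitude response of the filter inside the band,
so the configured value *is* the expected Welch mean PSD in the band
(μV²/Hz).

Injected effects:

* active arm: delta and theta components scaled by a non-decreasing
  per-timepoint gain ramp (T1 gain fixed at 1), modulated by a
  subject-specific responsiveness factor;
* phase coupling: a configured channel pair shares a common narrowband
  source, linearly mixed (``sqrt(1−c)·own + sqrt(c)·shared``) so band
  power is preserved and downstream PLV grows monotonically (not
  identically) with the strength c; the active arm ramps the strength
  across timepoints, the sham arm stays uncoupled;
* artifacts: 200-ms raised-cosine pulses of ±300 μV on one channel,
  sized to cross the ±100 μV rejection rule unambiguously even after
  re-referencing and band-pass filtering;
* line noise: a 50 Hz sinusoid of configurable amplitude.

The sleep night draws a semi-Markov hypnogram (W latency, then
NREM/REM cycles with stage runs of random length, first NREM period
guaranteed ≥ 15 min) and synthesizes each stage run with stage-dependent
band powers (delta: N3 > N2 > N1 > R, W). The subject's wake
responsiveness also scales first-night theta power after the active
arm, giving the wake→sleep correlation a ground truth.

Reproducibility: one global seed expands to per-(subject, arm,
timepoint) substreams through ``numpy.random.SeedSequence`` spawn keys —
a documented counter scheme that makes every recording independently
reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .bands import get_band
from .errors import ValidationError
from .io import Recording, SLEEP_CHANNELS_6, WAKE_CHANNELS_21
from .preprocess import SLEEP_EPOCH_S, WAKE_EPOCH_S

ARMS = ("active", "sham")
TIMEPOINTS = ("T1", "T2", "T3", "T4", "T5", "T6")

#: default per-band baseline PSD levels, μV²/Hz (eyes-closed wake:
#: alpha-dominant, 1/f-like decline into beta/gamma)
DEFAULT_BAND_POWER = {
    "delta": 20.0, "theta": 10.0, "alpha": 15.0, "beta": 3.0, "gamma": 0.5,
}

#: stage-dependent multipliers on the wake baseline; delta strictly
#: ordered N3 > N2 > N1 > R, W
DEFAULT_STAGE_GAINS = {
    "W":  {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0},
    "N1": {"delta": 2.0, "theta": 1.5, "alpha": 0.7, "beta": 0.6, "gamma": 0.5},
    "N2": {"delta": 5.0, "theta": 2.0, "alpha": 0.5, "beta": 0.5, "gamma": 0.4},
    "N3": {"delta": 10.0, "theta": 2.5, "alpha": 0.3, "beta": 0.3, "gamma": 0.3},
    "R":  {"delta": 1.2, "theta": 1.3, "alpha": 0.6, "beta": 0.8, "gamma": 0.7},
}

# ±300 μV so the transient still clears the ±100 μV rule after the 1 Hz
# high-pass strips the unipolar pulse's sub-1 Hz content (the filtered
# peak is ~0.8 of the raw amplitude) and the common average dilutes it
ARTIFACT_AMPLITUDE_UV = 300.0
ARTIFACT_DURATION_S = 0.2


@dataclass
class SimConfig:
    """Study-design and signal parameters of the synthetic crossover."""

    n_subjects: int = 20
    sfreq_wake: float = 1000.0
    sfreq_sleep: float = 512.0
    wake_duration: float = 300.0
    sleep_duration_minutes: float = 480.0
    channel_set: tuple = WAKE_CHANNELS_21
    sleep_channel_set: tuple = SLEEP_CHANNELS_6
    band_power_baseline: dict = field(
        default_factory=lambda: dict(DEFAULT_BAND_POWER))
    active_effect_ramp: tuple = (1.0, 1.1, 1.1, 1.2, 1.2, 1.3)
    effect_bands: tuple = ("delta", "theta")
    coupling_pairs: tuple = (("F4", "O1", "theta", 0.6),
                             ("F4", "O1", "delta", 0.6))
    coupling_ramp: tuple = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    artifact_rate: float = 2.0            # events / minute
    line_noise_amplitude: float = 5.0     # μV
    subject_effect_sd: float = 0.2        # responsiveness spread
    baseline_power_sd: float = 0.2        # lognormal between-subject spread
    wake_sleep_coupling: float = 1.0      # responsiveness → sleep theta
    stage_gains: dict = field(default_factory=lambda: {
        s: dict(g) for s, g in DEFAULT_STAGE_GAINS.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if len(self.active_effect_ramp) != 6:
            raise ValidationError("active_effect_ramp must have length 6")
        if self.active_effect_ramp[0] != 1.0:
            raise ValidationError(
                "active_effect_ramp[0] must be 1.0 (baseline T1 unmodified)")
        if any(b > a for a, b in zip(self.active_effect_ramp[1:],
                                     self.active_effect_ramp[:-1])):
            raise ValidationError("active_effect_ramp must be non-decreasing")
        if len(self.coupling_ramp) != 6:
            raise ValidationError("coupling_ramp must have length 6")
        for ca, cb, band, c in self.coupling_pairs:
            if not 0.0 <= c <= 1.0:
                raise ValidationError(
                    f"coupling strength for ({ca},{cb},{band}) must be in "
                    f"[0,1], got {c}")
            get_band(band)
        if any(v <= 0 for v in self.band_power_baseline.values()):
            raise ValidationError("band powers must be positive")
        top = max(get_band(b).f_hi for b in self.band_power_baseline)
        for name, sf in (("sfreq_wake", self.sfreq_wake),
                         ("sfreq_sleep", self.sfreq_sleep)):
            if sf <= 2 * top:
                raise ValidationError(
                    f"{name}={sf} must exceed twice the highest band edge "
                    f"({top} Hz)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_set"] = list(self.channel_set)
        d["sleep_channel_set"] = list(self.sleep_channel_set)
        return d


@dataclass
class GroundTruth:
    """Injected-effect bookkeeping for one recording or night."""

    band_power: dict                      # channel -> band -> μV²/Hz used
    coupled_pairs: list = field(default_factory=list)
    artifact_epochs: list = field(default_factory=list)
    artifact_spans: list = field(default_factory=list)   # (start, end) samples
    line_noise_amplitude: float = 0.0
    hypnogram: list | None = None
    stage_band_power: dict | None = None
    subject_effect: float = 1.0


# ---------------------------------------------------------------------------
# Substreams and band-limited noise
# ---------------------------------------------------------------------------

_STREAM_WAKE, _STREAM_SLEEP, _STREAM_SUBJECT = 0, 1, 2


def _rng(cfg: SimConfig, *key: int) -> np.random.Generator:
    """Substream for a (kind, subject, arm, timepoint) counter key."""
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


def subject_effect(cfg: SimConfig, subject: int) -> float:
    """Subject responsiveness factor (shared across arms/timepoints)."""
    r = _rng(cfg, _STREAM_SUBJECT, subject, 0)
    return float(max(0.1, 1.0 + cfg.subject_effect_sd * r.standard_normal()))


def subject_baseline_scale(cfg: SimConfig, subject: int) -> float:
    """Between-subject lognormal scale on all baseline band powers."""
    r = _rng(cfg, _STREAM_SUBJECT, subject, 1)
    return float(np.exp(cfg.baseline_power_sd * r.standard_normal()))


_gain_cache: dict = {}


def _band_filter_gain(band_name: str, sfreq: float) -> float:
    """Mean |H(f)|⁴ of the band filter inside its own band (filtfilt
    applies the magnitude response twice); used to pre-compensate the
    white-noise variance so configured PSD levels are realized."""
    key = (band_name, sfreq)
    if key not in _gain_cache:
        band = get_band(band_name)
        sos = signal.butter(4, (band.f_lo, band.f_hi), btype="bandpass",
                            fs=sfreq, output="sos")
        f = np.linspace(band.f_lo, band.f_hi, 512, endpoint=False)
        _, h = signal.sosfreqz(sos, worN=f, fs=sfreq)
        _gain_cache[key] = float(np.mean(np.abs(h) ** 4))
    return _gain_cache[key]


def band_limited_noise(band_name: str, psd_level: float, n_samples: int,
                       sfreq: float, rng: np.random.Generator,
                       size: int = 1) -> np.ndarray:
    """``size`` independent channels of band-limited noise whose expected
    Welch mean PSD inside the band equals ``psd_level`` μV²/Hz."""
    band = get_band(band_name)
    g = _band_filter_gain(band_name, sfreq)
    sigma = np.sqrt(psd_level * sfreq / 2.0 / g)
    # pad both ends so filtfilt edge transients (the unfiltered white
    # noise is far larger than the band-limited result) never reach the
    # returned samples
    n_pad = int(round(4.0 / band.f_lo * sfreq))
    white = rng.standard_normal((size, n_samples + 2 * n_pad)) * sigma
    sos = signal.butter(4, (band.f_lo, band.f_hi), btype="bandpass",
                        fs=sfreq, output="sos")
    out = signal.sosfiltfilt(sos, white, axis=-1)
    return out[:, n_pad:n_pad + n_samples]


# ---------------------------------------------------------------------------
# Wake recordings
# ---------------------------------------------------------------------------

def _validate_arm_timepoint(arm: str, timepoint: str) -> int:
    if arm not in ARMS:
        raise ValidationError(f"arm must be one of {ARMS}, got {arm!r}")
    if timepoint not in TIMEPOINTS:
        raise ValidationError(
            f"timepoint must be one of {TIMEPOINTS}, got {timepoint!r}")
    return TIMEPOINTS.index(timepoint)


def _effective_band_power(cfg: SimConfig, subject: int, arm: str,
                          tp_idx: int) -> dict:
    """channel -> band -> PSD level after arm/timepoint/subject effects."""
    base_scale = subject_baseline_scale(cfg, subject)
    u = subject_effect(cfg, subject)
    powers: dict = {}
    for ch in cfg.channel_set:
        powers[ch] = {}
        for band, level in cfg.band_power_baseline.items():
            gain = 1.0
            if arm == "active" and band in cfg.effect_bands:
                gain = 1.0 + (cfg.active_effect_ramp[tp_idx] - 1.0) * u
            powers[ch][band] = level * base_scale * gain
    return powers


def _insert_artifacts(data: np.ndarray, cfg: SimConfig, sfreq: float,
                      rng: np.random.Generator, epoch_length: float):
    """Raised-cosine ±150 μV pulses on one random channel each; returns
    (sample spans, epoch indices under the given segmentation)."""
    n_ch, n_samp = data.shape
    minutes = n_samp / sfreq / 60.0
    n_events = rng.poisson(cfg.artifact_rate * minutes)
    n_pulse = int(round(ARTIFACT_DURATION_S * sfreq))
    pulse = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n_pulse) / n_pulse))
    spans, epochs = [], set()
    n_per = int(round(epoch_length * sfreq))
    for _ in range(n_events):
        start = int(rng.integers(0, n_samp - n_pulse))
        ch = int(rng.integers(0, n_ch))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        data[ch, start:start + n_pulse] += sign * ARTIFACT_AMPLITUDE_UV * pulse
        spans.append((start, start + n_pulse))
        first = start // n_per
        last = (start + n_pulse - 1) // n_per
        for e in range(first, last + 1):
            if e < n_samp // n_per:
                epochs.add(int(e))
    return spans, sorted(epochs)


def simulate_wake_recording(cfg: SimConfig, subject: int, arm: str,
                            timepoint: str) -> tuple[Recording, GroundTruth]:
    """One 5-minute resting-state wake recording plus its ground truth.

    Deterministic under (cfg.seed, subject, arm, timepoint).
    """
    tp_idx = _validate_arm_timepoint(arm, timepoint)
    rng = _rng(cfg, _STREAM_WAKE, subject, ARMS.index(arm), tp_idx)
    sfreq = cfg.sfreq_wake
    n_samp = int(round(cfg.wake_duration * sfreq))
    channels = list(cfg.channel_set)
    n_ch = len(channels)
    powers = _effective_band_power(cfg, subject, arm, tp_idx)

    coupling_factor = cfg.coupling_ramp[tp_idx] if arm == "active" else 0.0
    coupled = {}
    for ca, cb, band, c in cfg.coupling_pairs:
        c_eff = c * coupling_factor
        if c_eff > 0 and ca in channels and cb in channels:
            coupled[(band, ca)] = coupled[(band, cb)] = None
    data = np.zeros((n_ch, n_samp))
    for band in cfg.band_power_baseline:
        # unit-PSD components, scaled per channel afterwards
        comp = band_limited_noise(band, 1.0, n_samp, sfreq, rng, size=n_ch)
        for ca, cb, cband, c in cfg.coupling_pairs:
            c_eff = c * coupling_factor
            if cband != band or c_eff <= 0:
                continue
            if ca not in channels or cb not in channels:
                raise ValidationError(
                    f"coupling pair ({ca},{cb}) not in channel_set")
            shared = band_limited_noise(band, 1.0, n_samp, sfreq, rng, size=1)[0]
            for ch in (ca, cb):
                i = channels.index(ch)
                comp[i] = (np.sqrt(1.0 - c_eff) * comp[i]
                           + np.sqrt(c_eff) * shared)
        scales = np.sqrt([powers[ch][band] for ch in channels])
        data += comp * scales[:, None]

    if cfg.line_noise_amplitude > 0:
        t = np.arange(n_samp) / sfreq
        data += cfg.line_noise_amplitude * np.sin(2 * np.pi * 50.0 * t)

    spans, artifact_epochs = ([], [])
    if cfg.artifact_rate > 0:
        spans, artifact_epochs = _insert_artifacts(
            data, cfg, sfreq, rng, WAKE_EPOCH_S)

    rec = Recording(data, channels, sfreq,
                    meta={"subject": subject, "arm": arm,
                          "timepoint": timepoint, "kind": "wake"})
    gt = GroundTruth(
        band_power=powers,
        coupled_pairs=[(ca, cb, band, c * coupling_factor)
                       for ca, cb, band, c in cfg.coupling_pairs
                       if c * coupling_factor > 0],
        artifact_epochs=artifact_epochs,
        artifact_spans=spans,
        line_noise_amplitude=cfg.line_noise_amplitude,
        subject_effect=subject_effect(cfg, subject),
    )
    return rec, gt


# ---------------------------------------------------------------------------
# Sleep night
# ---------------------------------------------------------------------------

def generate_hypnogram(cfg: SimConfig, rng: np.random.Generator,
                       n_epochs: int) -> list[str]:
    """Semi-Markov stage sequence: W latency, then NREM/REM cycles.

    Starts in W; the first NREM run is guaranteed to span >= 15 min
    before the first REM run, matching the downstream cycle criteria.
    """
    stages: list[str] = []
    stages += ["W"] * int(rng.integers(5, 21))
    cycle = 0
    while len(stages) < n_epochs:
        cycle += 1
        n1 = int(rng.integers(2, 9))
        n2 = int(rng.integers(20, 41))
        n3 = int(rng.integers(10, 31)) if cycle <= 3 else int(rng.integers(0, 11))
        n2b = int(rng.integers(5, 16))
        if cycle == 1:
            # first NREM period must comfortably exceed 30 epochs (15 min)
            n2 = max(n2, 35 - n1 - n3)
        rem = (int(rng.integers(2, 11)) if cycle == 1
               else int(rng.integers(10, 31)))
        stages += ["N1"] * n1 + ["N2"] * n2 + ["N3"] * n3 + ["N2"] * n2b
        stages += ["R"] * rem
        if rng.random() < 0.3:
            stages += ["W"] * int(rng.integers(1, 5))
    return stages[:n_epochs]


def simulate_sleep_night(cfg: SimConfig, subject: int, arm: str,
                         hypnogram: list | None = None,
                         ) -> tuple[Recording, list[str], GroundTruth]:
    """One PSG night: Recording, hypnogram, and ground truth.

    Stage-dependent band powers follow ``cfg.stage_gains``; after the
    active arm, the subject's responsiveness additionally scales theta
    (and the other effect bands) by the T6 wake gain times
    ``wake_sleep_coupling``, which is what ties wake ΔPSD to first-cycle
    NREM power. If ``hypnogram`` is given (a forced stage path), it is
    used verbatim. Deterministic under (cfg.seed, subject, arm).
    """
    if arm not in ARMS:
        raise ValidationError(f"arm must be one of {ARMS}, got {arm!r}")
    rng = _rng(cfg, _STREAM_SLEEP, subject, ARMS.index(arm))
    sfreq = cfg.sfreq_sleep
    n_epochs = int(round(cfg.sleep_duration_minutes * 60.0 / SLEEP_EPOCH_S))
    if hypnogram is None:
        hypnogram = generate_hypnogram(cfg, rng, n_epochs)
    hypnogram = list(hypnogram)
    channels = list(cfg.sleep_channel_set)
    n_ch = len(channels)
    n_per = int(round(SLEEP_EPOCH_S * sfreq))

    base_scale = subject_baseline_scale(cfg, subject)
    u = subject_effect(cfg, subject)
    carryover = 1.0
    if arm == "active":
        carryover = 1.0 + cfg.wake_sleep_coupling * (
            cfg.active_effect_ramp[-1] - 1.0) * u

    stage_power: dict = {}
    for stage, gains in cfg.stage_gains.items():
        stage_power[stage] = {}
        for band, level in cfg.band_power_baseline.items():
            p = level * base_scale * gains.get(band, 1.0)
            if stage != "W" and band in cfg.effect_bands:
                p *= carryover
            stage_power[stage][band] = p

    # synthesize per stage run so band powers switch at stage boundaries
    data = np.zeros((n_ch, len(hypnogram) * n_per))
    start = 0
    for stage, s0, s1 in _stage_runs(hypnogram):
        n_run = (s1 - s0) * n_per
        seg = np.zeros((n_ch, n_run))
        for band, level in cfg.band_power_baseline.items():
            comp = band_limited_noise(band, stage_power[stage][band],
                                      n_run, sfreq, rng, size=n_ch)
            seg += comp
        data[:, start:start + n_run] = seg
        start += n_run

    if cfg.line_noise_amplitude > 0:
        t = np.arange(data.shape[1]) / sfreq
        data += cfg.line_noise_amplitude * np.sin(2 * np.pi * 50.0 * t)
    spans, artifact_epochs = ([], [])
    if cfg.artifact_rate > 0:
        spans, artifact_epochs = _insert_artifacts(
            data, cfg, sfreq, rng, SLEEP_EPOCH_S)

    rec = Recording(data, channels, sfreq,
                    meta={"subject": subject, "arm": arm, "kind": "sleep"})
    gt = GroundTruth(
        band_power={}, artifact_epochs=artifact_epochs, artifact_spans=spans,
        line_noise_amplitude=cfg.line_noise_amplitude,
        hypnogram=hypnogram, stage_band_power=stage_power,
        subject_effect=u,
    )
    return rec, hypnogram, gt


def _stage_runs(stages):
    start = 0
    for i in range(1, len(stages) + 1):
        if i == len(stages) or stages[i] != stages[start]:
            yield stages[start], start, i
            start = i
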