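"""Preprocessing chain for wake and sleep EEG.

The chain is: select analysis channels -> common-average reference ->
1-60 Hz band-pass -> 50 Hz notch -> fixed-length segmentation with
amplitude-threshold artifact rejection. All filters are applied
forward-backward (zero net phase shift), which matters downstream: the
phase-locking estimator must not inherit filter phase delays.

Amplitude screening is applied to the filtered, re-referenced signal.
An epoch is rejected iff any retained channel strictly exceeds the
threshold (±100 μV by default) at any sample; channel-wise crossings are
kept so sleep analyses can drop channels that are artifactual for more
than half of the recording and then recompute epoch rejection on the
retained channels.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import NoAnalyzableDataError, ValidationError
from .io import Recording

logger = logging.getLogger(__name__)

ARTIFACT_THRESHOLD_UV = 100.0
BANDPASS_EDGES = (1.0, 60.0)
NOTCH_FREQ = 50.0
NOTCH_Q = 30.0
WAKE_EPOCH_S = 5.0
SLEEP_EPOCH_S = 30.0


@dataclass
class EpochSet:
    """Fixed-length artifact-screened segments of a Recording.

    ``all_epochs`` holds every consecutive segment, shape
    (n_total, n_channels, n_samples), μV, restricted to the retained
    channels. ``kept_indices`` / ``rejected_indices`` partition the
    segmentation; ``epochs`` is the kept subset. ``channel_crossings``
    is the (n_total, n_channels) boolean threshold-crossing table that
    drives the sleep 50 %-channel rule.
    """

    all_epochs: np.ndarray
    epoch_length: float
    sfreq: float
    channel_names: list[str]
    kept_indices: list[int]
    rejected_indices: list[int]
    threshold: float
    channel_crossings: np.ndarray
    excluded_channels: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def epochs(self) -> np.ndarray:
        """Kept epochs only, shape (n_kept, n_channels, n_samples)."""
        return self.all_epochs[self.kept_indices]

    @property
    def n_kept(self) -> int:
        return len(self.kept_indices)

    @property
    def n_total(self) -> int:
        return self.all_epochs.shape[0]

    @property
    def n_samples_per_epoch(self) -> int:
        return self.all_epochs.shape[2]


def select_channels(rec: Recording, subset) -> Recording:
    """Restrict a Recording to ``subset``, in the requested order."""
    subset = list(subset)
    missing = [c for c in subset if c not in rec.channel_names]
    if missing:
        raise ValidationError(f"channels not present in recording: {missing}")
    idx = [rec.channel_names.index(c) for c in subset]
    return Recording(rec.data[idx], subset, rec.sfreq, dict(rec.meta))


def common_average_reference(rec: Recording) -> Recording:
    """Re-reference every sample to the instantaneous mean across channels."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return Recording(data, list(rec.channel_names), rec.sfreq, dict(rec.meta))


def bandpass_notch(rec: Recording,
                   band: tuple = BANDPASS_EDGES,
                   notch_freq: float = NOTCH_FREQ,
                   notch_q: float = NOTCH_Q) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass then IIR notch (Q=30).

    Both filters run forward-backward (filtfilt), so the effective
    magnitude response is squared and the net phase shift is zero.
    """
    nyq = rec.sfreq / 2.0
    if band[1] >= nyq:
        raise ValidationError(
            f"band-pass upper edge {band[1]} Hz requires sfreq > {2 * band[1]} Hz "
            f"(Nyquist is {nyq} Hz at sfreq={rec.sfreq})"
        )
    sos = signal.butter(4, band, btype="bandpass", fs=rec.sfreq, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=-1)
    if notch_freq is not None and notch_freq < nyq:
        b, a = signal.iirnotch(notch_freq, notch_q, fs=rec.sfreq)
        data = signal.filtfilt(b, a, data, axis=-1)
    return Recording(data, list(rec.channel_names), rec.sfreq, dict(rec.meta))


def preprocess_wake(rec: Recording, channels=None) -> Recording:
    """Full wake preprocessing: (select) -> reference -> band-pass -> notch.

    The reference is computed over the analysis channel subset, so
    selection must precede referencing; the pipeline pins this order.
    """
    if rec.sfreq < 200:
        raise ValidationError(
            f"sfreq={rec.sfreq} Hz too low for the 60 Hz band edge "
            "(need >= 200 Hz so the edge clears Nyquist with margin)"
        )
    if channels is not None:
        rec = select_channels(rec, channels)
    return bandpass_notch(common_average_reference(rec))


preprocess_sleep = preprocess_wake  # identical chain; epoch length differs


def _segment(rec: Recording, epoch_length: float):
    n_per = int(round(epoch_length * rec.sfreq))
    if n_per < 1 or rec.n_samples < n_per:
        raise ValidationError(
            f"recording of {rec.duration:.1f} s shorter than one "
            f"{epoch_length} s epoch"
        )
    n_epochs = rec.n_samples // n_per
    cube = rec.data[:, : n_epochs * n_per].reshape(
        rec.n_channels, n_epochs, n_per).transpose(1, 0, 2).copy()
    return cube


def _screen(rec: Recording, epoch_length: float, threshold: float) -> EpochSet:
    cube = _segment(rec, epoch_length)
    crossings = (np.abs(cube) > threshold).any(axis=2)  # (epoch, channel)
    bad = crossings.any(axis=1)
    kept = np.flatnonzero(~bad)
    return EpochSet(
        all_epochs=cube,
        epoch_length=epoch_length,
        sfreq=rec.sfreq,
        channel_names=list(rec.channel_names),
        kept_indices=kept.tolist(),
        rejected_indices=np.flatnonzero(bad).tolist(),
        threshold=threshold,
        channel_crossings=crossings,
        meta=dict(rec.meta),
    )


def segment_and_reject(rec: Recording,
                       epoch_length: float = WAKE_EPOCH_S,
                       threshold: float = ARTIFACT_THRESHOLD_UV) -> EpochSet:
    """Cut consecutive non-overlapping epochs and reject by amplitude.

    An epoch is rejected iff any channel attains ``|x| > threshold``
    (strict) at any sample. The trailing partial segment is discarded,
    never padded.
    """
    es = _screen(rec, epoch_length, threshold)
    if es.n_kept == 0:
        raise NoAnalyzableDataError(
            f"all {es.n_total} epochs exceed ±{threshold} μV; no analyzable data"
        )
    logger.info("segment_and_reject: kept %d / %d epochs (threshold ±%g μV)",
                es.n_kept, es.n_total, threshold)
    return es


def exclude_bad_channels(es: EpochSet,
                         max_artifact_fraction: float = 0.5) -> EpochSet:
    """Drop channels artifactual on > ``max_artifact_fraction`` of epochs.

    The 50 % rule is strict (a channel at exactly half is retained).
    Epoch rejection is recomputed on the retained channels, so epochs
    that were bad only on an excluded channel become kept.
    """
    frac = es.channel_crossings.mean(axis=0)
    drop = frac > max_artifact_fraction
    if not drop.any():
        return es
    keep_ch = np.flatnonzero(~drop)
    if keep_ch.size == 0:
        raise NoAnalyzableDataError(
            "every channel exceeds the artifact fraction limit; no analyzable data"
        )
    excluded = [es.channel_names[i] for i in np.flatnonzero(drop)]
    logger.info("exclude_bad_channels: dropping %s (artifact fractions %s)",
                excluded, np.round(frac[drop], 3).tolist())
    crossings = es.channel_crossings[:, keep_ch]
    bad = crossings.any(axis=1)
    kept = np.flatnonzero(~bad)
    if kept.size == 0:
        raise NoAnalyzableDataError("no clean epochs remain after channel exclusion")
    return EpochSet(
        all_epochs=es.all_epochs[:, keep_ch, :],
        epoch_length=es.epoch_length,
        sfreq=es.sfreq,
        channel_names=[es.channel_names[i] for i in keep_ch],
        kept_indices=kept.tolist(),
        rejected_indices=np.flatnonzero(bad).tolist(),
        threshold=es.threshold,
        channel_crossings=crossings,
        excluded_channels=es.excluded_channels + excluded,
        meta=dict(es.meta),
    )


def segment_reject_exclude(rec: Recording,
                           epoch_length: float = SLEEP_EPOCH_S,
                           threshold: float = ARTIFACT_THRESHOLD_UV,
                           max_artifact_fraction: float = 0.5) -> EpochSet:
    """Sleep-style screening: segment, reject, then apply the 50 % channel
    rule with epoch rejection recomputed on the retained channels.

    Tolerates an intermediate state where every epoch is bad, as long as
    the channel rule recovers clean epochs.
    """
    es = exclude_bad_channels(_screen(rec, epoch_length, threshold),
                              max_artifact_fraction)
    if es.n_kept == 0:
        raise NoAnalyzableDataError("all epochs artifactual; no analyzable data")
    return es
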