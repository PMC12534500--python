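"""Phase-locking value (PLV) connectivity.

Phase extraction: each epoch is zero-phase band-pass filtered to the
band of interest and the instantaneous phase taken from the analytic
signal (Hilbert transform). A guard fraction (10 % of samples at each
epoch end by default) is excluded from the time average, since both the
filter and the transform distort epoch edges.

PLV between channels j and k within one epoch is the modulus of the
time-averaged unit phasor of the phase difference,
``| mean_t exp(i(φ_j(t) − φ_k(t))) |``; the matrix entry is the mean of
per-epoch moduli across epochs (not the modulus of the grand mean),
which respects the epoched structure of resting-state data. The
estimator is amplitude-invariant and lag-invariant, bounded in [0, 1],
symmetric, with unit diagonal.

Its null is biased above zero: for T effectively independent phase
samples the expected modulus is ≈ (1/2)√(π/T), and band-limited signals
have far fewer independent phase samples than time samples, so null
quantiles must come from matched simulation (:func:`simulate_null_plv`).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .bands import BandDefinition, get_band
from .errors import NoAnalyzableDataError, ValidationError
from .preprocess import EpochSet

GUARD_FRACTION = 0.10


@dataclass
class PLVMatrix:
    """Symmetric phase-synchronization adjacency for one band."""

    values: np.ndarray            # (n_channels, n_channels) in [0, 1]
    band: BandDefinition
    n_epochs_used: int
    channel_names: list[str]
    meta: dict = field(default_factory=dict)

    def value(self, chan_a: str, chan_b: str) -> float:
        i = self.channel_names.index(chan_a)
        j = self.channel_names.index(chan_b)
        return float(self.values[i, j])

    def to_edge_table(self) -> pd.DataFrame:
        """Long-form upper-triangle edge list (chan_a, chan_b, band, plv)."""
        rows = []
        n = len(self.channel_names)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({"chan_a": self.channel_names[i],
                             "chan_b": self.channel_names[j],
                             "band": self.band.name,
                             "plv": float(self.values[i, j])})
        out = pd.DataFrame(rows)
        for k, v in self.meta.items():
            out[k] = v
        return out


def _band_sos(band: BandDefinition, sfreq: float):
    nyq = sfreq / 2.0
    if not 0 < band.f_lo < band.f_hi < nyq:
        raise ValidationError(
            f"band [{band.f_lo}, {band.f_hi}) Hz outside (0, Nyquist={nyq}) "
            f"at sfreq={sfreq}"
        )
    try:
        sos = signal.butter(4, (band.f_lo, band.f_hi), btype="bandpass",
                            fs=sfreq, output="sos")
    except ValueError as exc:
        raise ValidationError(
            f"cannot design band-pass for [{band.f_lo}, {band.f_hi}) Hz "
            f"at sfreq={sfreq}: {exc}"
        ) from exc
    return sos


def instantaneous_phase(es: EpochSet, band) -> np.ndarray:
    """Band-limited instantaneous phase, shape (epoch, channel, sample)."""
    band = get_band(band)
    sos = _band_sos(band, es.sfreq)
    filtered = signal.sosfiltfilt(sos, es.epochs, axis=-1)
    return np.angle(signal.hilbert(filtered, axis=-1))


def interior_slice(n_samples: int, guard_fraction: float = GUARD_FRACTION) -> slice:
    """Samples retained for averaging after trimming the edge guard."""
    g = int(np.floor(n_samples * guard_fraction))
    return slice(g, n_samples - g)


def plv_from_phase(phase: np.ndarray,
                   guard_fraction: float = GUARD_FRACTION) -> np.ndarray:
    """PLV matrix from a (epoch, channel, sample) phase array."""
    if phase.ndim != 3 or phase.shape[0] == 0:
        raise NoAnalyzableDataError("need at least one epoch of phases")
    sl = interior_slice(phase.shape[2], guard_fraction)
    z = np.exp(1j * phase[:, :, sl])
    n_ep, n_ch, t = z.shape
    acc = np.zeros((n_ch, n_ch))
    for e in range(n_ep):
        # |mean_t z_j conj(z_k)| via matrix product
        m = z[e] @ z[e].conj().T / t
        acc += np.abs(m)
    plv = acc / n_ep
    plv = (plv + plv.T) / 2.0
    np.fill_diagonal(plv, 1.0)
    return np.clip(plv, 0.0, 1.0)


def plv_matrix(es: EpochSet, band,
               guard_fraction: float = GUARD_FRACTION) -> PLVMatrix:
    """Band-specific PLV adjacency for an EpochSet."""
    band = get_band(band)
    phase = instantaneous_phase(es, band)
    values = plv_from_phase(phase, guard_fraction)
    return PLVMatrix(values=values, band=band, n_epochs_used=es.n_kept,
                     channel_names=list(es.channel_names), meta=dict(es.meta))


def simulate_null_plv(band, sfreq: float, epoch_length: float,
                      n_epochs: int, n_sims: int = 200,
                      seed: int = 0,
                      guard_fraction: float = GUARD_FRACTION) -> np.ndarray:
    """Null PLV distribution for two independent band-limited noise
    channels with matched band, sampling rate, epoch length and count.

    Returns ``n_sims`` PLV values; quantiles of this array are the null
    band for coupling detection.
    """
    band = get_band(band)
    rng = np.random.default_rng(seed)
    sos = _band_sos(band, sfreq)
    n_per = int(round(epoch_length * sfreq))
    sl = interior_slice(n_per, guard_fraction)
    out = np.empty(n_sims)
    for s in range(n_sims):
        x = rng.standard_normal((2, n_epochs * n_per))
        x = signal.sosfiltfilt(sos, x, axis=-1)
        phase = np.angle(signal.hilbert(
            x.reshape(2, n_epochs, n_per), axis=-1))
        dphi = phase[0, :, sl] - phase[1, :, sl]
        out[s] = np.abs(np.exp(1j * dphi).mean(axis=-1)).mean()
    return out
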