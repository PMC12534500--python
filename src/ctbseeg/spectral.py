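"""Welch power spectral density and band power.

One Hamming-windowed modified periodogram is computed per kept epoch
(segment length = the whole epoch, no sub-segmentation, no overlap) and
averaged across epochs. Density normalization: the PSD of unit-variance
white noise integrates to 1 over [0, Nyquist] in expectation, so values
are in μV²/Hz. The frequency resolution is 1/epoch_length.

Band power is the *mean* PSD over the half-open band [f_lo, f_hi),
in μV²/Hz; within-band comparisons are unaffected by the mean-vs-
integral choice, but it is pinned here.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .bands import BANDS
from .errors import NoAnalyzableDataError, ValidationError
from .preprocess import EpochSet


@dataclass
class BandPowerTable:
    """Per-channel, per-band mean PSD (μV²/Hz) for one recording context."""

    values: pd.DataFrame          # index: channel, columns: band names
    n_epochs_used: int
    freq_resolution: float
    meta: dict = field(default_factory=dict)

    def value(self, channel: str, band: str) -> float:
        return float(self.values.loc[channel, band])

    def to_tidy(self) -> pd.DataFrame:
        """Long-form (channel, band, power) table with meta columns."""
        out = self.values.reset_index(names="channel").melt(
            id_vars="channel", var_name="band", value_name="power")
        for k, v in self.meta.items():
            out[k] = v
        return out


def welch_psd(es: EpochSet):
    """Average Hamming-windowed periodogram over kept epochs.

    Returns
    -------
    freqs : ndarray
        One-sided frequency grid, resolution 1/epoch_length Hz.
    psd : ndarray, shape (n_channels, n_freqs)
        Power spectral density in μV²/Hz.
    """
    if es.n_kept == 0:
        raise NoAnalyzableDataError("no kept epochs; no analyzable data")
    nper = es.n_samples_per_epoch
    freqs, psd = signal.welch(
        es.epochs, fs=es.sfreq, window="hamming",
        nperseg=nper, noverlap=0, axis=-1, scaling="density",
    )
    return freqs, psd.mean(axis=0)


def band_power(freqs, psd, bands=BANDS,
               channel_names=None, n_epochs_used: int = 1,
               meta: dict | None = None) -> BandPowerTable:
    """Mean PSD within each half-open band [f_lo, f_hi)."""
    freqs = np.asarray(freqs)
    psd = np.atleast_2d(np.asarray(psd))
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(psd.shape[0])]
    cols = {}
    resolution = float(freqs[1] - freqs[0]) if len(freqs) > 1 else np.nan
    for band in bands:
        mask = band.contains(freqs)
        if not mask.any():
            raise ValidationError(
                f"band {band.name!r} [{band.f_lo}, {band.f_hi}) contains no "
                f"frequency bin at resolution {resolution:g} Hz"
            )
        cols[band.name] = psd[:, mask].mean(axis=1)
    values = pd.DataFrame(cols, index=pd.Index(channel_names, name="channel"))
    return BandPowerTable(values=values, n_epochs_used=n_epochs_used,
                          freq_resolution=resolution, meta=dict(meta or {}))


def band_power_from_epochs(es: EpochSet, bands=BANDS) -> BandPowerTable:
    """Convenience: Welch PSD then band power for an EpochSet."""
    freqs, psd = welch_psd(es)
    return band_power(freqs, psd, bands=bands,
                      channel_names=es.channel_names,
                      n_epochs_used=es.n_kept, meta=es.meta)


@dataclass
class DeltaPSD:
    """Post-minus-baseline band-power change (T6 − T1) at one electrode,
    z-scored across subjects within each band.

    ``table`` columns: subject, band, psd_change, zscore.
    Bands where the across-subject SD is zero are listed in
    ``degenerate_bands`` and carry NaN z-scores.
    """

    table: pd.DataFrame
    channel: str
    arm: str
    degenerate_bands: list[str] = field(default_factory=list)


def delta_psd_zscores(tables: dict, channel: str = "F4",
                      arm: str = "active",
                      baseline: str = "T1", post: str = "T6",
                      log10: bool = False) -> DeltaPSD:
    """ΔPSD = PSD_post − PSD_baseline per subject at one electrode.

    Parameters
    ----------
    tables : dict
        ``{subject: {timepoint: BandPowerTable}}`` for one arm.
    channel : str
        Electrode at which the change is evaluated (F4, the stimulation
        target, by default).
    log10 : bool
        Apply log10 to band powers before differencing.

    Z-scores use the population (n-denominator) standard deviation across
    subjects within each band.
    """
    missing = [s for s, tps in tables.items()
               if baseline not in tps or post not in tps]
    if missing:
        raise ValidationError(
            f"subjects missing {baseline} or {post} tables: {sorted(missing)}"
        )
    rows = []
    for subject, tps in tables.items():
        for band in tps[baseline].values.columns:
            a = tps[baseline].value(channel, band)
            b = tps[post].value(channel, band)
            if log10:
                a, b = np.log10(a), np.log10(b)
            rows.append({"subject": subject, "band": band, "psd_change": b - a})
    df = pd.DataFrame(rows)
    degenerate = []
    zs = np.full(len(df), np.nan)
    for band, grp in df.groupby("band"):
        sd = grp["psd_change"].std(ddof=0)
        if sd == 0:
            degenerate.append(band)
            continue
        zs[grp.index] = (grp["psd_change"] - grp["psd_change"].mean()) / sd
    df["zscore"] = zs
    return DeltaPSD(table=df, channel=channel, arm=arm,
                    degenerate_bands=sorted(degenerate))
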