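"""Hypnogram architecture, NREM–REM cycle detection, and first-cycle
NREM spectra.

Cycle scoring follows the classical Feinberg & Floyd criteria: a cycle
is a NREM period of at least ``min_nrem_minutes`` (default 15) followed
by a REM period of at least ``min_rem_minutes`` (default 5), with the
first REM period exempt from its minimum. NREM periods tolerate W/R
interruptions shorter than ``interruption_tolerance_minutes`` (default
5) without splitting; the tolerance is a disclosed convention, not part
of the published criteria.

Architecture conventions: sleep latency is measured from lights-off to
the first non-W epoch; WASO counts W minutes from sleep onset to
lights-on (no final-awakening trimming).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bands import BANDS
from .errors import NoAnalyzableDataError, ValidationError
from .io import Recording, VALID_STAGES
from .preprocess import preprocess_sleep, segment_reject_exclude
from .spectral import BandPowerTable, band_power_from_epochs
from .connectivity import PLVMatrix, plv_matrix

logger = logging.getLogger(__name__)

EPOCH_S = 30.0
NREM_STAGES = ("N1", "N2", "N3")
SLEEP_STAGES = ("N1", "N2", "N3", "R")
MIN_PLV_CHANNELS = 6


@dataclass
class Hypnogram:
    """AASM stage sequence in 30-s epochs."""

    stages: list[str]
    epoch_length: float = EPOCH_S
    lights_off: int = 0
    lights_on: int | None = None  # exclusive; None = end of record

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValidationError("hypnogram is empty")
        bad = sorted({s for s in self.stages if s not in VALID_STAGES})
        if bad:
            raise ValidationError(f"unknown stage labels: {bad}")
        if self.epoch_length != EPOCH_S:
            raise ValidationError("AASM scoring uses 30-s epochs")
        if self.lights_on is None:
            self.lights_on = len(self.stages)
        if not 0 <= self.lights_off < self.lights_on <= len(self.stages):
            raise ValidationError("need 0 <= lights_off < lights_on <= n_epochs")

    def __len__(self) -> int:
        return len(self.stages)

    def minutes(self, n_epochs: int) -> float:
        return n_epochs * self.epoch_length / 60.0


@dataclass
class SleepArchitecture:
    """Standard sleep-stage summary, all durations in minutes."""

    tib: float
    tst: float
    se: float
    sl: float | None      # None when no sleep epoch exists
    waso: float
    nrem_minutes: float
    rem_minutes: float


def score_architecture(h: Hypnogram) -> SleepArchitecture:
    """TIB, TST, SE, SL, WASO and NREM/REM minutes from a hypnogram."""
    window = h.stages[h.lights_off:h.lights_on]
    ep_min = h.epoch_length / 60.0
    tib = len(window) * ep_min
    nrem = sum(s in NREM_STAGES for s in window) * ep_min
    rem = sum(s == "R" for s in window) * ep_min
    tst = nrem + rem
    sleep_idx = [i for i, s in enumerate(window) if s != "W"]
    if not sleep_idx:
        return SleepArchitecture(tib=tib, tst=0.0, se=0.0, sl=None,
                                 waso=0.0, nrem_minutes=0.0, rem_minutes=0.0)
    onset = sleep_idx[0]
    sl = onset * ep_min
    waso = sum(s == "W" for s in window[onset:]) * ep_min
    return SleepArchitecture(tib=tib, tst=tst, se=tst / tib, sl=sl,
                             waso=waso, nrem_minutes=nrem, rem_minutes=rem)


@dataclass
class SleepCycle:
    """Epoch-index spans of one NREM–REM cycle (ends exclusive)."""

    nrem_start: int
    nrem_end: int
    rem_start: int | None
    rem_end: int | None


@dataclass
class SleepCycleSet:
    cycles: list[SleepCycle]
    min_nrem_minutes: float = 15.0
    min_rem_minutes: float = 5.0
    first_rem_exempt: bool = True
    interruption_tolerance_minutes: float = 5.0

    def __len__(self) -> int:
        return len(self.cycles)


def _runs(stages) -> list[tuple[str, int, int]]:
    """Maximal constant-label runs as (label, start, end-exclusive)."""
    runs = []
    start = 0
    for i in range(1, len(stages) + 1):
        if i == len(stages) or stages[i] != stages[start]:
            runs.append((stages[start], start, i))
            start = i
    return runs


def detect_cycles(h: Hypnogram,
                  min_nrem_minutes: float = 15.0,
                  min_rem_minutes: float = 5.0,
                  first_rem_exempt: bool = True,
                  interruption_tolerance_minutes: float = 5.0,
                  allow_incomplete_final: bool = False) -> SleepCycleSet:
    """Feinberg–Floyd NREM–REM cycle decomposition of a hypnogram.

    Scans for maximal NREM periods (runs of N1/N2/N3, tolerating non-NREM
    interruptions strictly shorter than the tolerance) spanning at least
    ``min_nrem_minutes``; each is paired with the subsequent REM run of at
    least ``min_rem_minutes`` (first REM period exempt when
    ``first_rem_exempt``). A REM run below its minimum is treated as an
    interruption of the ongoing NREM period. A trailing qualifying NREM
    period without terminal REM forms a final incomplete cycle only when
    ``allow_incomplete_final``.
    """
    ep_min = h.epoch_length / 60.0
    min_nrem_ep = int(np.ceil(min_nrem_minutes / ep_min))
    min_rem_ep = int(np.ceil(min_rem_minutes / ep_min))
    tol_ep = int(np.ceil(interruption_tolerance_minutes / ep_min))

    if not any(s in NREM_STAGES for s in h.stages):
        logger.warning("detect_cycles: hypnogram contains no NREM epoch")
        return SleepCycleSet([], min_nrem_minutes, min_rem_minutes,
                             first_rem_exempt, interruption_tolerance_minutes)

    runs = _runs(list(h.stages))
    cycles: list[SleepCycle] = []
    nrem_start: int | None = None
    nrem_end: int | None = None
    seen_rem_period = False

    def nrem_qualifies() -> bool:
        return (nrem_start is not None
                and nrem_end - nrem_start >= min_nrem_ep)

    i = 0
    while i < len(runs):
        label, start, end = runs[i]
        length = end - start
        if label in NREM_STAGES:
            if nrem_start is None:
                nrem_start = start
            nrem_end = end
        elif label == "R":
            accept_rem = (length >= min_rem_ep
                          or (first_rem_exempt and not seen_rem_period))
            if nrem_qualifies() and accept_rem:
                # extend the REM period across tolerated interruptions? —
                # REM periods are taken as single maximal R runs
                cycles.append(SleepCycle(nrem_start, nrem_end, start, end))
                seen_rem_period = True
                nrem_start = nrem_end = None
            elif length >= tol_ep:
                # long REM without a qualifying NREM period resets the scan
                seen_rem_period = seen_rem_period or length >= min_rem_ep
                nrem_start = nrem_end = None
            # short R inside/before a NREM period: interruption, ignore
        else:  # W
            if length >= tol_ep and nrem_start is not None and not nrem_qualifies():
                nrem_start = nrem_end = None
            elif length >= tol_ep and nrem_qualifies():
                # long wake terminates the NREM period; without REM it
                # completes no cycle unless allow_incomplete_final at end
                if allow_incomplete_final and i == len(runs) - 1:
                    cycles.append(SleepCycle(nrem_start, nrem_end, None, None))
                nrem_start = nrem_end = None
        i += 1

    if nrem_qualifies() and allow_incomplete_final:
        cycles.append(SleepCycle(nrem_start, nrem_end, None, None))

    if not cycles:
        logger.warning("detect_cycles: no qualifying NREM period found")
    return SleepCycleSet(cycles, min_nrem_minutes, min_rem_minutes,
                         first_rem_exempt, interruption_tolerance_minutes)


def first_cycle_nrem_spectra(rec: Recording, h: Hypnogram,
                             cycles: SleepCycleSet,
                             bands=BANDS,
                             preprocess: bool = True,
                             threshold: float = 100.0,
                             max_artifact_fraction: float = 0.5,
                             ) -> tuple[BandPowerTable, dict[str, PLVMatrix] | None]:
    """Band power and PLV over the NREM epochs of the first sleep cycle.

    Extracts the N1/N2/N3-staged 30-s epochs inside cycle 1's NREM span
    (REM or W epochs inside the span are excluded), applies the sleep
    screening chain (±threshold μV epoch marking, >50 % channel
    exclusion), then delegates to the spectral and connectivity modules.
    PLV is computed only when at least 6 channels survive (sparser
    montages cannot support a network); the montage size is recorded in
    the outputs' metadata.
    """
    if len(cycles) == 0:
        raise NoAnalyzableDataError("no detected sleep cycle")
    cyc = cycles.cycles[0]
    n_per = int(round(EPOCH_S * rec.sfreq))
    if rec.n_samples < cyc.nrem_end * n_per:
        raise ValidationError("recording does not cover the first cycle span")
    nrem_epochs = [i for i in range(cyc.nrem_start, cyc.nrem_end)
                   if h.stages[i] in NREM_STAGES]
    if not nrem_epochs:
        raise NoAnalyzableDataError("first cycle contains no NREM epoch")
    segs = [rec.data[:, i * n_per:(i + 1) * n_per] for i in nrem_epochs]
    sub = Recording(np.concatenate(segs, axis=1), list(rec.channel_names),
                    rec.sfreq, dict(rec.meta))
    if preprocess:
        sub = preprocess_sleep(sub)
    es = segment_reject_exclude(sub, epoch_length=EPOCH_S,
                                threshold=threshold,
                                max_artifact_fraction=max_artifact_fraction)
    es.meta.update(context="first_cycle_nrem",
                   montage_channels=len(es.channel_names))
    bp = band_power_from_epochs(es, bands=bands)
    plvs: dict[str, PLVMatrix] | None = None
    if len(es.channel_names) >= MIN_PLV_CHANNELS:
        plvs = {b.name: plv_matrix(es, b) for b in bands}
    else:
        logger.warning("first_cycle_nrem_spectra: only %d channel(s) retained; "
                       "PLV requires >= %d", len(es.channel_names),
                       MIN_PLV_CHANNELS)
    return bp, plvs
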