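"""Recording container and file I/O.

Supported on-disk formats:

* EDF (European Data Format, 16-bit): read through :mod:`mne`, written by
  a compact encoder in this module (one data record per second, physical
  units μV).
* Delimited numeric matrices (TSV): one column per channel with a header
  of 10-20 labels, preceded by ``# sfreq=<Hz>`` and optional ``# key=value``
  metadata comment lines.
* Hypnograms: two-column delimited text ``epoch_index<TAB>stage``.
* Simulation / pipeline configuration: YAML.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError

#: The 21-channel 10-20 wake analysis montage, in analysis order.
WAKE_CHANNELS_21: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F3", "Fz", "F4", "C3", "Cz", "C4",
    "P3", "Pz", "P4", "O1", "Oz", "O2", "F7", "F8", "T7", "T8", "P7", "P8",
)

#: 6-channel sleep PSG EEG montage (mastoid-referential derivations,
#: reference dropped from the label).
SLEEP_CHANNELS_6: tuple[str, ...] = ("F4", "C4", "O2", "F3", "C3", "O1")

#: 19-channel sleep PSG montage (full clinical 10-20 set).
SLEEP_CHANNELS_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz",
)

#: Normalization of legacy / referential EDF channel labels to bare 10-20
#: names. Matching is case-insensitive on the stripped label.
CHANNEL_ALIASES: dict[str, str] = {
    "t3": "T7", "t4": "T8", "t5": "P7", "t6": "P8",
    "cz": "Cz", "fpz": "Fpz", "fz": "Fz", "pz": "Pz", "oz": "Oz",
}

VALID_STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")


def normalize_label(label: str) -> str:
    """Normalize an EDF channel label to a bare 10-20 name.

    Strips ``EEG`` prefixes and referential suffixes (``F4-M1`` -> ``F4``)
    and maps legacy temporal names (T3/T4/T5/T6) to the modern T7/T8/P7/P8.
    """
    lab = label.strip()
    if lab.upper().startswith("EEG"):
        lab = lab[3:].strip(" :")
    if "-" in lab:
        lab = lab.split("-", 1)[0].strip()
    low = lab.lower()
    if low in CHANNEL_ALIASES:
        return CHANNEL_ALIASES[low]
    # canonical capitalization: first letter(s) upper, digits kept
    for known in WAKE_CHANNELS_21 + SLEEP_CHANNELS_19:
        if low == known.lower():
            return known
    return lab


@dataclass
class Recording:
    """Continuous multichannel EEG in physical units of μV.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in μV.
    channel_names : list of str
        Unique 10-20 labels, one per row of ``data``.
    sfreq : float
        Sampling frequency in Hz.
    meta : dict
        Free-form context (subject, arm, timepoint, night, montage...).
    """

    data: np.ndarray
    channel_names: list[str]
    sfreq: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("Recording.data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            dupes = sorted({c for c in self.channel_names
                            if self.channel_names.count(c) > 1})
            raise ValidationError(f"duplicate channel labels: {dupes}")
        if not self.sfreq > 0:
            raise ValidationError("sfreq must be positive")
        if np.isnan(self.data).any():
            raise ValidationError("Recording.data contains NaN")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sfreq

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), list(self.channel_names),
                         self.sfreq, dict(self.meta))


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: "str | Path") -> Path:
    """Write a Recording as 16-bit EDF with physical units μV.

    One data record per second; requires an integer sampling rate and a
    whole-second recording length. Quantization step is
    ``2 * phys_max / 65535``.
    """
    path = Path(path)
    sfreq = int(round(rec.sfreq))
    if abs(sfreq - rec.sfreq) > 1e-9:
        raise ValidationError("EDF export requires an integer sampling rate")
    if rec.n_samples % sfreq != 0:
        raise ValidationError(
            "EDF export requires a whole-second recording "
            f"({rec.n_samples} samples at {sfreq} Hz)"
        )
    n_records = rec.n_samples // sfreq
    ns = rec.n_channels
    phys_max = float(np.ceil(max(np.abs(rec.data).max(), 1.0)))
    dig_max, dig_min = 32767, -32768

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + ns), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(ns, 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(c, 16) for c in rec.channel_names),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field("uV", 8) for _ in range(ns)),
        b"".join(_edf_field(f"{-phys_max:.8g}"[:8], 8) for _ in range(ns)),
        b"".join(_edf_field(f"{phys_max:.8g}"[:8], 8) for _ in range(ns)),
        b"".join(_edf_field(dig_min, 8) for _ in range(ns)),
        b"".join(_edf_field(dig_max, 8) for _ in range(ns)),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field(sfreq, 8) for _ in range(ns)),
        b"".join(_edf_field("", 32) for _ in range(ns)),
    ])

    clipped = np.clip(rec.data, -phys_max, phys_max)
    scale = (dig_max - dig_min) / (2.0 * phys_max)
    digital = np.round((clipped + phys_max) * scale + dig_min).astype("<i2")
    # interleave per-record: record r holds ns blocks of sfreq samples
    blocks = digital.reshape(ns, n_records, sfreq).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(blocks.tobytes())
    return path


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne returns volts
    names = [normalize_label(n) for n in raw.ch_names]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate channel labels after normalization: {dupes}")
    return Recording(data_uv, names, float(raw.info["sfreq"]),
                     meta={"source": str(path), "format": "edf"})


# ---------------------------------------------------------------------------
# Delimited matrices
# ---------------------------------------------------------------------------

def write_delimited(rec: Recording, path: "str | Path", sep: str = "\t") -> Path:
    """Write a Recording as a delimited matrix (samples x channels).

    The first lines are ``# sfreq=<Hz>`` plus one ``# key=value`` comment
    per meta entry, followed by a header row of channel labels.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sfreq={rec.sfreq:.10g}\n")
        for k, v in rec.meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write(sep.join(rec.channel_names) + "\n")
        np.savetxt(fh, rec.data.T, fmt="%.6f", delimiter=sep)
    return path


def _read_delimited(path: Path, sep: str = "\t") -> Recording:
    meta: dict = {}
    sfreq = None
    with open(path) as fh:
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                if k.strip() == "sfreq":
                    sfreq = float(v)
                else:
                    meta[k.strip()] = v.strip()
            line = fh.readline()
        header = [normalize_label(c) for c in line.strip().split(sep)]
        try:
            data = np.loadtxt(fh, delimiter=sep, ndmin=2)
        except ValueError as exc:
            raise ValidationError(f"unparseable numeric matrix in {path}: {exc}") from exc
    if sfreq is None:
        raise ValidationError(f"{path}: missing '# sfreq=' comment line")
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValidationError(f"duplicate channel labels: {dupes}")
    if data.shape[1] != len(header):
        raise ValidationError(
            f"{path}: {data.shape[1]} columns for {len(header)} header labels"
        )
    meta.setdefault("source", str(path))
    return Recording(data.T, header, sfreq, meta)


def read_recording(path: "str | Path", format: "str | None" = None) -> Recording:
    """Read a Recording from EDF or a delimited matrix, in μV.

    Parameters
    ----------
    path : path-like
    format : {"edf", "delimited", None}
        ``None`` infers from the file suffix (``.edf`` vs anything else).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path)
    if format == "delimited":
        return _read_delimited(path)
    raise ValidationError(f"unknown format {format!r}; use 'edf' or 'delimited'")


# ---------------------------------------------------------------------------
# Hypnograms, ground truth, configs
# ---------------------------------------------------------------------------

def write_hypnogram(stages, path: "str | Path") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("epoch_index\tstage\n")
        for i, s in enumerate(stages):
            fh.write(f"{i}\t{s}\n")
    return path


def read_hypnogram(path: "str | Path") -> list[str]:
    path = Path(path)
    stages: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("epoch_index"):
            raise ValidationError(f"{path}: expected 'epoch_index\\tstage' header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: malformed hypnogram row")
            stage = parts[1]
            if stage not in VALID_STAGES:
                raise ValidationError(
                    f"{path}:{lineno}: unknown stage {stage!r}; "
                    f"expected one of {VALID_STAGES}"
                )
            stages.append(stage)
    return stages


def save_yaml(obj: dict, path: "str | Path") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path


def load_yaml(path: "str | Path") -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_json(obj, path: "str | Path") -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)
    return path
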