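"""Reading EEG/EMG recordings and splitting them into fixed-length epochs.

Recordings are two simultaneous biopotential channels (EEG and EMG) sampled
at a common rate, stored either as plain CSV/ASCII or as EDF (European Data
Format).  Amplitude units are never interpreted: all downstream processing is
unit-free after the log/normalization step.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class IngestError(Exception):
    """Problem reading or structuring an input recording."""


class ChannelNotFoundError(IngestError):
    """A required EEG or EMG channel is absent from the input."""


@dataclass
class SignalRecord:
    """Paired EEG/EMG sample vectors with a common sampling rate.

    Parameters
    ----------
    eeg, emg
        Amplitude samples, arbitrary units.  Must have equal length.
    sampling_rate_hz
        Samples per second, identical for both channels.
    start_time_s
        Wall-clock offset of the first sample; used only for epoch timing.
    """

    eeg: np.ndarray
    emg: np.ndarray
    sampling_rate_hz: float = 100.0
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.ndim != 1 or self.emg.ndim != 1:
            raise IngestError("EEG and EMG must be one-dimensional sample vectors")
        if len(self.eeg) != len(self.emg):
            raise IngestError(
                f"channel lengths differ: EEG {len(self.eeg)}, EMG {len(self.emg)}"
            )
        if not self.sampling_rate_hz > 0:
            raise IngestError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.eeg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class EpochGrid:
    """Partition of a recording into contiguous fixed-length epochs.

    A trailing partial epoch is discarded: every epoch must contain exactly
    ``samples_per_epoch`` samples so the spectral transform has a fixed size.
    """

    epoch_length_s: float
    n_epochs: int
    samples_per_epoch: int
    sampling_rate_hz: float
    start_time_s: float = 0.0

    def epoch_start_times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_epochs) * self.epoch_length_s


class EmptyGridError(IngestError):
    """Recording shorter than a single epoch."""


def split_epochs(
    record: SignalRecord, epoch_length_s: float = 8.0
) -> tuple[EpochGrid, np.ndarray, np.ndarray]:
    """Split a record into non-overlapping epochs of ``epoch_length_s`` seconds.

    Returns the grid plus two views of shape ``(n_epochs, samples_per_epoch)``
    (EEG then EMG).  Epoch ``i`` covers samples ``[i*spe, (i+1)*spe)``.
    """
    spe = int(round(epoch_length_s * record.sampling_rate_hz))
    if spe <= 0:
        raise IngestError("epoch_length_s too short for the sampling rate")
    n_epochs = record.n_samples // spe
    if n_epochs == 0:
        raise EmptyGridError(
            f"recording has {record.n_samples} samples, fewer than one "
            f"{epoch_length_s}-s epoch ({spe} samples)"
        )
    grid = EpochGrid(
        epoch_length_s=epoch_length_s,
        n_epochs=n_epochs,
        samples_per_epoch=spe,
        sampling_rate_hz=record.sampling_rate_hz,
        start_time_s=record.start_time_s,
    )
    eeg = record.eeg[: n_epochs * spe].reshape(n_epochs, spe)
    emg = record.emg[: n_epochs * spe].reshape(n_epochs, spe)
    return grid, eeg, emg


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def _looks_like_header(fields: list[str]) -> bool:
    for f in fields:
        try:
            float(f)
        except ValueError:
            return True
    return False


def read_csv_record(
    path: str | Path,
    sampling_rate_hz: float = 100.0,
    delimiter: str = ",",
) -> SignalRecord:
    """Read a 2- or 3-column CSV: ``eeg,emg`` or ``time,eeg,emg``.

    A header row is auto-detected; with a header, columns named ``eeg`` and
    ``emg`` (case-insensitive) are used regardless of order.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise IngestError(f"{path}: empty file")
    fields = [f.strip() for f in first.rstrip("\n").split(delimiter)]
    has_header = _looks_like_header(fields)
    df = pd.read_csv(path, sep=delimiter, header=0 if has_header else None)
    if has_header:
        cols = {str(c).strip().lower(): c for c in df.columns}
        if "eeg" not in cols or "emg" not in cols:
            raise ChannelNotFoundError(
                f"{path}: need 'eeg' and 'emg' columns, found {list(df.columns)}"
            )
        eeg, emg = df[cols["eeg"]], df[cols["emg"]]
    else:
        if df.shape[1] == 2:
            eeg, emg = df.iloc[:, 0], df.iloc[:, 1]
        elif df.shape[1] == 3:  # time, eeg, emg
            eeg, emg = df.iloc[:, 1], df.iloc[:, 2]
        else:
            raise IngestError(
                f"{path}: expected 2 or 3 columns, found {df.shape[1]}"
            )
    eeg = pd.to_numeric(eeg, errors="raise").to_numpy(dtype=float)
    emg = pd.to_numeric(emg, errors="raise").to_numpy(dtype=float)
    return SignalRecord(eeg=eeg, emg=emg, sampling_rate_hz=sampling_rate_hz)


def write_csv_record(record: SignalRecord, path: str | Path) -> None:
    """Write a record as ``eeg,emg`` CSV with a header row."""
    pd.DataFrame({"eeg": record.eeg, "emg": record.emg}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_DEFAULT_PATTERNS = {"eeg": r"eeg", "emg": r"emg"}


def read_edf_record(
    path: str | Path,
    channel_patterns: dict[str, str] | None = None,
) -> SignalRecord:
    """Read an EDF file, matching channel names case-insensitively.

    Amplitudes are returned in microvolts (EDF physical units are converted
    to SI volts by the reader backend and rescaled here).
    """
    import mne

    patterns = dict(_DEFAULT_PATTERNS)
    if channel_patterns:
        patterns.update(channel_patterns)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")

    def find(pattern: str) -> str:
        rx = re.compile(pattern, re.IGNORECASE)
        hits = [name for name in raw.ch_names if rx.search(name)]
        if not hits:
            raise ChannelNotFoundError(
                f"{path}: no channel matching {pattern!r} among {raw.ch_names}"
            )
        return hits[0]

    eeg_name = find(patterns["eeg"])
    emg_name = find(patterns["emg"])
    data = raw.get_data(picks=[eeg_name, emg_name]) * 1e6  # V -> uV
    return SignalRecord(
        eeg=data[0], emg=data[1], sampling_rate_hz=float(raw.info["sfreq"])
    )


def write_edf_record(record: SignalRecord, path: str | Path) -> None:
    """Write a two-channel (EEG, EMG) EDF file.

    Minimal single-annotation-free EDF: 16-bit samples, one-second data
    records, physical dimension microvolts.  The sampling rate must be a
    positive integer and the signal is truncated to whole seconds.
    """
    sr = record.sampling_rate_hz
    if abs(sr - round(sr)) > 1e-9 or sr <= 0:
        raise IngestError("EDF writer requires an integer sampling rate")
    sr = int(round(sr))
    n_records = record.n_samples // sr
    if n_records == 0:
        raise IngestError("recording shorter than one EDF data record (1 s)")
    n_keep = n_records * sr
    channels = [record.eeg[:n_keep], record.emg[:n_keep]]
    labels = ["EEG", "EMG"]

    # Symmetric physical range per channel; the header stores the range as a
    # short ASCII literal, so scale by the parsed-back literal to make the
    # write/read pair exact up to 16-bit quantization.
    dig_min, dig_max = -32768, 32767
    phys_str: list[tuple[str, str]] = []
    digital: list[np.ndarray] = []
    for x in channels:
        amp = float(np.max(np.abs(x))) or 1.0
        # round the range literal upward so no sample is clipped
        exp = int(np.floor(np.log10(amp)))
        mant = np.ceil(amp / 10.0**exp * 10.0) / 10.0
        if mant >= 10.0:
            mant, exp = 1.0, exp + 1
        hi_s = f"{mant:.1f}e{exp:+03d}"
        lo_s = "-" + hi_s
        lo, hi = float(lo_s), float(hi_s)
        scale = (dig_max - dig_min) / (hi - lo)
        d = np.round((x - lo) * scale + dig_min)
        digital.append(np.clip(d, dig_min, dig_max).astype("<i2"))
        phys_str.append((lo_s, hi_s))

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise IngestError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    ns = len(channels)
    header = b"".join(
        [
            pad("0", 8),                       # version
            pad("X X X X", 80),                # patient id
            pad("Startdate X X X X", 80),      # recording id
            pad("01.01.00", 8),                # start date
            pad("00.00.00", 8),                # start time
            pad(str(256 * (ns + 1)), 8),       # header bytes
            pad("", 44),                       # reserved
            pad(str(n_records), 8),
            pad("1", 8),                       # record duration, s
            pad(str(ns), 4),
        ]
    )
    fields = [
        b"".join(pad(lab, 16) for lab in labels),
        b"".join(pad("", 80) for _ in labels),                     # transducer
        b"".join(pad("uV", 8) for _ in labels),                    # phys dim
        b"".join(pad(p[0], 8) for p in phys_str),                  # phys min
        b"".join(pad(p[1], 8) for p in phys_str),                  # phys max
        b"".join(pad(str(dig_min), 8) for _ in labels),
        b"".join(pad(str(dig_max), 8) for _ in labels),
        b"".join(pad("", 80) for _ in labels),                     # prefilter
        b"".join(pad(str(sr), 8) for _ in labels),                 # samples/rec
        b"".join(pad("", 32) for _ in labels),                     # reserved
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        for rec in range(n_records):
            for d in digital:
                fh.write(d[rec * sr : (rec + 1) * sr].tobytes())


def read_record(
    path: str | Path,
    format: str | None = None,
    sampling_rate_hz: float = 100.0,
    delimiter: str = ",",
    channel_patterns: dict[str, str] | None = None,
) -> SignalRecord:
    """Read a recording, dispatching on ``format`` or the file suffix."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        return read_csv_record(path, sampling_rate_hz=sampling_rate_hz, delimiter=delimiter)
    if format == "edf":
        return read_edf_record(path, channel_patterns=channel_patterns)
    raise IngestError(f"unknown format {format!r}; expected 'csv' or 'edf'")
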