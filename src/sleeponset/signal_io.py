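"""Recording containers, EDF/CSV round-trip, and epoch segmentation.

A :class:`Recording` holds the two referential EEG derivations (Fpz-Cz and
Pz-Oz, 100 Hz) and the respiration channel (1 Hz), plus optional per-epoch
drowsiness labels.  Recordings round-trip through

* EDF (European Data Format, 16-bit): written by a minimal built-in writer
  and read back through MNE;
* plain CSV: one file for the EEG channels, one for respiration, one for
  labels.

Epochs are 10 s by convention; within an epoch the EEG is tiled into
non-overlapping 128-sample analysis segments (7 per epoch at 100 Hz, the
trailing 104 samples are discarded).  The respiration channel additionally
carries a trailing context window (default 60 s) so its autocorrelation sees
several breathing cycles.
"""

from __future__ import annotations

import csv
import math
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChannelMapError, ValidationError

SEGMENT_LEN = 128

#: default EDF channel labels for the three signals
DEFAULT_CHANNEL_MAP = {"eeg1": "EEG Fpz-Cz", "eeg2": "EEG Pz-Oz", "resp": "Resp"}


@dataclass
class Recording:
    """Synchronised EEG (µV) and respiration (a.u.) channels with optional labels."""

    eeg1: np.ndarray
    eeg2: np.ndarray
    resp: np.ndarray
    eeg_rate: float = 100.0
    resp_rate: float = 1.0
    epoch_s: float = 10.0
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.eeg1 = np.asarray(self.eeg1, dtype=float)
        self.eeg2 = np.asarray(self.eeg2, dtype=float)
        self.resp = np.asarray(self.resp, dtype=float)
        if len(self.eeg1) != len(self.eeg2):
            raise ValidationError("EEG channels differ in length")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)

    @property
    def duration_s(self) -> float:
        return len(self.eeg1) / self.eeg_rate

    @property
    def n_epochs(self) -> int:
        return int(math.floor(self.duration_s / self.epoch_s))


@dataclass
class Epoch:
    """One analysis epoch: raw channel slices plus 128-sample EEG segments."""

    index: int
    eeg1_raw: np.ndarray
    eeg2_raw: np.ndarray
    eeg1_segmented: list[np.ndarray]
    eeg2_segmented: list[np.ndarray]
    resp_window: np.ndarray
    resp_rate: float
    label: int | None = None


def segment_epochs(rec: Recording, resp_context_s: float = 60.0) -> list[Epoch]:
    """Split a recording into epochs of non-overlapping 128-sample segments.

    Each epoch carries ``floor(epoch_s * eeg_rate / 128)`` full segments
    tiled from the epoch start; trailing samples within the epoch are
    discarded.  ``resp_window`` is the trailing ``resp_context_s`` seconds of
    respiration ending at the epoch's end (clipped at recording start).
    A recording shorter than one epoch yields an empty list.
    """
    samples_per_epoch = int(round(rec.epoch_s * rec.eeg_rate))
    if samples_per_epoch < SEGMENT_LEN:
        raise ValidationError(
            f"epoch of {samples_per_epoch} samples is shorter than one {SEGMENT_LEN}-sample segment"
        )
    n_seg = samples_per_epoch // SEGMENT_LEN
    resp_per_epoch = rec.epoch_s * rec.resp_rate
    if abs(resp_per_epoch - round(resp_per_epoch)) > 1e-9:
        raise ValidationError("epoch_s times resp_rate must be an integer sample count")
    resp_per_epoch = int(round(resp_per_epoch))
    resp_ctx = int(round(resp_context_s * rec.resp_rate))

    if rec.labels is not None and len(rec.labels) < rec.n_epochs:
        warnings.warn("fewer labels than epochs; trailing epochs left unlabeled")

    epochs = []
    for i in range(rec.n_epochs):
        start = i * samples_per_epoch
        e1 = rec.eeg1[start : start + samples_per_epoch]
        e2 = rec.eeg2[start : start + samples_per_epoch]
        segs1 = [e1[k * SEGMENT_LEN : (k + 1) * SEGMENT_LEN] for k in range(n_seg)]
        segs2 = [e2[k * SEGMENT_LEN : (k + 1) * SEGMENT_LEN] for k in range(n_seg)]
        resp_end = (i + 1) * resp_per_epoch
        resp_win = rec.resp[max(0, resp_end - resp_ctx) : resp_end]
        label = None
        if rec.labels is not None and i < len(rec.labels):
            label = int(rec.labels[i])
        epochs.append(
            Epoch(
                index=i,
                eeg1_raw=e1,
                eeg2_raw=e2,
                eeg1_segmented=segs1,
                eeg2_segmented=segs2,
                resp_window=resp_win,
                resp_rate=rec.resp_rate,
                label=label,
            )
        )
    return epochs


# ---------------------------------------------------------------------------
# EDF writing (minimal 16-bit writer; EDF is a fixed-layout ASCII+int16 format)
# ---------------------------------------------------------------------------


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _physical_bounds(x: np.ndarray) -> tuple[float, float]:
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:  # flat channel: widen so the gain is non-zero
        lo, hi = lo - 1.0, hi + 1.0
    # round outward to 8-char decimal fields so the stored header bounds
    # still bracket the data
    lo = math.floor(lo * 1000) / 1000
    hi = math.ceil(hi * 1000) / 1000
    return lo, hi


def _write_edf(rec: Recording, path: Path) -> None:
    if int(rec.eeg_rate) != rec.eeg_rate or int(rec.resp_rate) != rec.resp_rate:
        raise ValidationError("EDF export requires integer sampling rates")
    n_records = int(math.floor(rec.duration_s))
    if n_records < 1:
        raise ValidationError("recording shorter than one EDF data record (1 s)")
    channels = [
        (DEFAULT_CHANNEL_MAP["eeg1"], rec.eeg1, int(rec.eeg_rate), "uV"),
        (DEFAULT_CHANNEL_MAP["eeg2"], rec.eeg2, int(rec.eeg_rate), "uV"),
        (DEFAULT_CHANNEL_MAP["resp"], rec.resp, int(rec.resp_rate), ""),
    ]
    for _, x, _, _ in channels:
        if not np.all(np.isfinite(x)):
            raise ValidationError("non-finite samples cannot be written to EDF")

    ns = len(channels)
    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field("X X X X", 80),
            _ascii_field("Startdate 01-JAN-2000 X X X", 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (ns + 1), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field("1", 8),
            _ascii_field(ns, 4),
        ]
    )

    bounds = [_physical_bounds(x) for _, x, _, _ in channels]
    dig_min, dig_max = -32768, 32767
    header += b"".join(_ascii_field(label, 16) for label, _, _, _ in channels)
    header += b"".join(_ascii_field("", 80) for _ in channels)
    header += b"".join(_ascii_field(dim, 8) for _, _, _, dim in channels)
    header += b"".join(_ascii_field(f"{lo:.3f}", 8) for lo, _ in bounds)
    header += b"".join(_ascii_field(f"{hi:.3f}", 8) for _, hi in bounds)
    header += b"".join(_ascii_field(dig_min, 8) for _ in channels)
    header += b"".join(_ascii_field(dig_max, 8) for _ in channels)
    header += b"".join(_ascii_field("", 80) for _ in channels)
    header += b"".join(_ascii_field(rate, 8) for _, _, rate, _ in channels)
    header += b"".join(_ascii_field("", 32) for _ in channels)

    digitized = []
    for (_, x, rate, _), (lo, hi) in zip(channels, bounds):
        gain = (hi - lo) / (dig_max - dig_min)
        d = np.round((x[: n_records * rate] - lo) / gain + dig_min).astype("<i2")
        digitized.append(d.reshape(n_records, rate))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for d in digitized:
                fh.write(struct.pack(f"<{d.shape[1]}h", *d[r]))


def _read_edf(path: Path, channel_map: dict[str, str], epoch_s: float) -> Recording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw_probe = mne.io.read_raw_edf(path, preload=False, verbose="error")
    names = set(raw_probe.ch_names)
    for key in ("eeg1", "eeg2", "resp"):
        if channel_map[key] not in names:
            raise ChannelMapError(
                f"channel '{channel_map[key]}' ({key}) not in EDF file; found {sorted(names)}"
            )
    # EEG and respiration run at different rates; MNE resamples mixed-rate
    # channels to a common rate, so each rate group is read separately.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw_eeg = mne.io.read_raw_edf(
            path, include=[channel_map["eeg1"], channel_map["eeg2"]], preload=True, verbose="error"
        )
        raw_resp = mne.io.read_raw_edf(
            path, include=[channel_map["resp"]], preload=True, verbose="error"
        )
    # MNE rescales channels with a known physical dimension (uV) to volts
    eeg = raw_eeg.get_data(units="uV")
    idx1 = raw_eeg.ch_names.index(channel_map["eeg1"])
    idx2 = raw_eeg.ch_names.index(channel_map["eeg2"])
    resp = raw_resp.get_data()[0]
    return Recording(
        eeg1=eeg[idx1],
        eeg2=eeg[idx2],
        resp=resp,
        eeg_rate=float(raw_eeg.info["sfreq"]),
        resp_rate=float(raw_resp.info["sfreq"]),
        epoch_s=epoch_s,
    )


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------


def _csv_paths(path: Path) -> dict[str, Path]:
    base = path.with_suffix("") if path.suffix == ".csv" else path
    return {
        "eeg": base.with_name(base.name + ".eeg.csv"),
        "resp": base.with_name(base.name + ".resp.csv"),
        "labels": base.with_name(base.name + ".labels.csv"),
    }


def _labels_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.csv") if path.suffix == ".edf" else _csv_paths(path)["labels"]


def write_labels(labels: np.ndarray, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "level"])
        for i, lev in enumerate(labels):
            w.writerow([i, int(lev)])


def read_labels(path: Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df["level"].to_numpy(dtype=int)


def write_recording(rec: Recording, path, fmt: str = "edf") -> None:
    """Write a recording (and its labels, if any) to EDF or CSV.

    EDF output is 16-bit with 1 s data records; labels go to a sibling
    ``<path>.labels.csv``.  CSV output produces ``<base>.eeg.csv``
    (``t,eeg1,eeg2``), ``<base>.resp.csv`` (``t,resp``) and
    ``<base>.labels.csv`` (``epoch_index,level``).
    """
    path = Path(path)
    if len(rec.eeg1) == 0:
        raise ValidationError("refusing to write an empty recording")
    for x in (rec.eeg1, rec.eeg2, rec.resp):
        if not np.all(np.isfinite(x)):
            raise ValidationError("non-finite samples in recording")
    if fmt == "edf":
        _write_edf(rec, path)
    elif fmt == "csv":
        paths = _csv_paths(path)
        t_eeg = np.arange(len(rec.eeg1)) / rec.eeg_rate
        pd.DataFrame({"t": t_eeg, "eeg1": rec.eeg1, "eeg2": rec.eeg2}).to_csv(paths["eeg"], index=False)
        t_resp = np.arange(len(rec.resp)) / rec.resp_rate
        pd.DataFrame({"t": t_resp, "resp": rec.resp}).to_csv(paths["resp"], index=False)
    else:
        raise ValidationError(f"unknown format '{fmt}'")
    if rec.labels is not None:
        write_labels(rec.labels, _labels_path(path))


def _rate_from_time(t: np.ndarray) -> float:
    if len(t) < 2:
        raise ValidationError("cannot infer sampling rate from fewer than 2 samples")
    dt = float(np.median(np.diff(t)))
    return round(1.0 / dt, 6)


def read_recording(
    path,
    fmt: str = "edf",
    channel_map: dict[str, str] | None = None,
    epoch_s: float = 10.0,
) -> Recording:
    """Read a recording from EDF or CSV; sampling rates come from the file.

    Labels are picked up automatically from the sibling labels CSV when it
    exists.
    """
    path = Path(path)
    if fmt == "edf":
        rec = _read_edf(path, channel_map or DEFAULT_CHANNEL_MAP, epoch_s)
    elif fmt == "csv":
        paths = _csv_paths(path)
        eeg = pd.read_csv(paths["eeg"])
        resp = pd.read_csv(paths["resp"])
        for col in ("t", "eeg1", "eeg2"):
            if col not in eeg.columns:
                raise ChannelMapError(f"column '{col}' missing from {paths['eeg']}")
        if "resp" not in resp.columns:
            raise ChannelMapError(f"column 'resp' missing from {paths['resp']}")
        rec = Recording(
            eeg1=eeg["eeg1"].to_numpy(),
            eeg2=eeg["eeg2"].to_numpy(),
            resp=resp["resp"].to_numpy(),
            eeg_rate=_rate_from_time(eeg["t"].to_numpy()),
            resp_rate=_rate_from_time(resp["t"].to_numpy()),
            epoch_s=epoch_s,
        )
    else:
        raise ValidationError(f"unknown format '{fmt}'")
    lbl_path = _labels_path(path)
    if lbl_path.exists():
        rec.labels = read_labels(lbl_path)
    return rec
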