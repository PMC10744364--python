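"""Reading and writing EEG recordings and subject metadata.

Recordings travel as :class:`EEGRecording` (microvolts, channels x samples).
Supported on disk: EDF (read via mne, written by the 16-bit writer below),
continuous EEGLAB SET (read via mne), and a BIDS-style directory layout with
a tab-separated participants table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import LabelingError, normalize_labels

__all__ = [
    "EEGRecording",
    "SubjectRecord",
    "FormatError",
    "read_recording",
    "write_edf",
    "read_subject_table",
    "write_subject_table",
    "read_bids_cohort",
]


class FormatError(IOError):
    """File cannot be parsed as the stated EEG format."""


@dataclass
class EEGRecording:
    """Multi-channel EEG segment.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Channel names, canonical legacy 10-20 spelling.
    reference : str
        One of ``as-recorded``, ``linked-mastoid``, ``average``, ``REST``.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    reference: str = "as-recorded"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.labels = normalize_labels(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} data rows"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(), labels=list(self.labels))

    def pick(self, labels) -> "EEGRecording":
        """Sub-recording with the given channels, in the given order."""
        idx = []
        for lab in normalize_labels(labels):
            if lab not in self.labels:
                raise LabelingError(f"channel {lab!r} not in recording")
            idx.append(self.labels.index(lab))
        return EEGRecording(
            self.data[idx], self.fs, [self.labels[i] for i in idx], self.reference
        )


@dataclass
class SubjectRecord:
    """One row of the subject table."""

    subject_id: str
    group: str
    age: float
    sex: str
    mmse: float | None = None  # None = missing

    def __post_init__(self):
        if self.group not in ("FTD", "CTL"):
            raise ValueError(f"group must be FTD or CTL, got {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.mmse is not None and not (0 <= self.mmse <= 30):
            raise ValueError(f"MMSE out of range [0, 30]: {self.mmse}")


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as a plain EDF file (16-bit, 1-second records).

    The sampling rate must be a whole number of samples per second; trailing
    samples beyond the last full second are dropped. Physical range is set
    per channel to the observed amplitude extreme, so quantization error is
    bounded by range / 2^15.
    """
    path = Path(path)
    fs_int = int(round(rec.fs))
    if abs(rec.fs - fs_int) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate (Hz)")
    n_records = rec.n_samples // fs_int
    if n_records < 1:
        raise ValueError("recording shorter than one EDF record (1 s)")
    ns = rec.n_channels
    data = rec.data[:, : n_records * fs_int]

    phys_max = np.maximum(np.max(np.abs(data), axis=1), 1e-6)
    dig_max = 32767
    scaled = np.round(data / phys_max[:, None] * dig_max).astype("<i2")

    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))
        f.write(_pad(f"Startdate 01-JAN-2000 X X X ref:{rec.reference}", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(256 * (ns + 1)), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_records), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(ns), 4))
        for lab in rec.labels:
            f.write(_pad(f"EEG {lab}", 16))
        f.write(_pad("", 80) * ns)
        f.write(_pad("uV", 8) * ns)
        for pm in phys_max:
            f.write(_pad(f"{-pm:.6g}"[:8], 8))
        for pm in phys_max:
            f.write(_pad(f"{pm:.6g}"[:8], 8))
        f.write(_pad(str(-dig_max), 8) * ns)
        f.write(_pad(str(dig_max), 8) * ns)
        f.write(_pad("", 80) * ns)
        f.write(_pad(str(fs_int), 8) * ns)
        f.write(_pad("", 32) * ns)
        for r in range(n_records):
            block = scaled[:, r * fs_int : (r + 1) * fs_int]
            f.write(block.tobytes())


def _read_edf(path) -> EEGRecording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as EDF: {exc}") from exc
    if not raw.ch_names:
        raise LabelingError(f"{path}: no channel labels")
    labels = [name.removeprefix("EEG ").strip() for name in raw.ch_names]
    data = raw.get_data(units="uV")
    return EEGRecording(data, float(raw.info["sfreq"]), normalize_labels(labels))


def _read_set(path) -> EEGRecording:
    import mne

    try:
        raw = mne.io.read_raw_eeglab(path, preload=True, verbose="error")
    except NotImplementedError as exc:
        raise FormatError(
            f"{path}: epoched or otherwise unsupported SET file; only "
            f"continuous recordings are handled"
        ) from exc
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as EEGLAB SET: {exc}") from exc
    if not raw.ch_names:
        raise LabelingError(f"{path}: no channel labels")
    data = raw.get_data(units="uV")
    return EEGRecording(data, float(raw.info["sfreq"]), normalize_labels(raw.ch_names))


def read_recording(path, format: str | None = None) -> EEGRecording:
    """Read an EEG recording from EDF or EEGLAB SET.

    Amplitudes are returned in microvolts, labels normalized to legacy
    10-20 names, sampling rate taken from the file header.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").upper()
    format = format.upper()
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "EDF":
        return _read_edf(path)
    if format == "SET":
        return _read_set(path)
    raise FormatError(f"unsupported format {format!r}; expected SET or EDF")


# ---------------------------------------------------------------------------
# subject tables
# ---------------------------------------------------------------------------

_ID_ALIASES = ("subject_id", "participant_id")
_REQUIRED = ("group", "age", "sex")


def read_subject_table(path) -> list[SubjectRecord]:
    """Read a tab-separated subject table.

    Requires columns subject_id (or participant_id), group, age, sex; an
    mmse column is optional and may contain blanks (missing). Raises a
    ``ValueError`` naming the offending row on validation failure.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    id_col = next((c for c in _ID_ALIASES if c in df.columns), None)
    if id_col is None:
        raise ValueError(f"{path}: missing subject_id/participant_id column")
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    records = []
    for i, row in df.iterrows():
        mmse_raw = row.get("mmse")
        mmse = None
        if mmse_raw is not None and str(mmse_raw).strip() not in ("", "n/a", "nan"):
            mmse = float(mmse_raw)
        try:
            records.append(
                SubjectRecord(
                    subject_id=str(row[id_col]).strip(),
                    group=str(row["group"]).strip().upper(),
                    age=float(row["age"]),
                    sex=str(row["sex"]).strip().upper()[:1],
                    mmse=mmse,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def write_subject_table(records, path) -> None:
    df = subjects_to_frame(records)
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")


def subjects_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "mmse": [r.mmse if r.mmse is not None else np.nan for r in records],
        }
    )


# ---------------------------------------------------------------------------
# BIDS-style directory layout
# ---------------------------------------------------------------------------

def read_bids_cohort(root) -> tuple[list[EEGRecording], list[SubjectRecord]]:
    """Read a BIDS-EEG style directory: sub-*/eeg/*.{edf,set} + participants.tsv."""
    root = Path(root)
    table = root / "participants.tsv"
    if not table.exists():
        table = root / "subjects.tsv"
    if not table.exists():
        raise FormatError(f"{root}: no participants.tsv or subjects.tsv")
    subjects = read_subject_table(table)
    recordings = []
    for sub in subjects:
        eeg_dir = root / sub.subject_id / "eeg"
        candidates = sorted(eeg_dir.glob("*.edf")) + sorted(eeg_dir.glob("*.set"))
        # flat layout fallback: <root>/<subject_id>.edf
        candidates += sorted(root.glob(f"{sub.subject_id}.edf"))
        candidates += sorted(root.glob(f"{sub.subject_id}.set"))
        if not candidates:
            raise FormatError(f"no EDF or SET recording found for {sub.subject_id}")
        recordings.append(read_recording(candidates[0]))
    return recordings, subjects


def write_bids_cohort(recordings, subjects, root) -> None:
    """Write recordings + participants.tsv in a BIDS-style layout."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    df = subjects_to_frame(subjects).rename(columns={"subject_id": "participant_id"})
    df.to_csv(root / "participants.tsv", sep="\t", index=False, na_rep="n/a")
    for rec, sub in zip(recordings, subjects):
        eeg_dir = root / sub.subject_id / "eeg"
        eeg_dir.mkdir(parents=True, exist_ok=True)
        write_edf(rec, eeg_dir / f"{sub.subject_id}_task-rest_eeg.edf")
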