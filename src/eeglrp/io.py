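"""Reading and writing the formats the pipeline touches.

Signals travel as EDF (European Data Format, the clinical-EEG lingua franca)
or as headered CSV matrices (human-readable, for fixtures); cohorts are
described by a manifest CSV; montages and every numeric result table are CSV;
run configuration is YAML (:mod:`eeglrp.config`).

EDF files are read through MNE.  Writing uses a minimal 16-bit EDF writer
implemented here, so that the write and read paths are independent of each
other.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig  # noqa: F401  (part of this module's surface)
from .montage import Montage

logger = logging.getLogger(__name__)

CONTROL, PATIENT = 0, 1


@dataclass(frozen=True)
class EEGRecording:
    """One subject's multichannel EEG: channels x samples, in microvolts."""

    subject_id: str
    label: int | None  # 0 = control, 1 = patient, None = unknown
    montage: Montage
    fs: float
    signal: np.ndarray  # (n_channels, n_samples), uV

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2:
            raise ValueError(f"signal must be 2-D, got shape {sig.shape}")
        if sig.shape[0] != len(self.montage):
            raise ValueError(
                f"signal has {sig.shape[0]} rows but montage has "
                f"{len(self.montage)} channels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.label not in (None, CONTROL, PATIENT):
            raise ValueError(f"label must be 0, 1 or None, got {self.label}")
        object.__setattr__(self, "signal", sig)

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def pick_channels(self, names) -> "EEGRecording":
        idx = self.montage.indices(names)
        return replace(self, montage=self.montage.subset(names), signal=self.signal[idx])


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_DIG_MAX = 32767


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as 16-bit EDF with 1-second data records.

    The sampling rate must be a positive integer and the signal length a
    whole number of seconds (always true for generated cohorts).
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9 or fs <= 0:
        raise ValueError(f"EDF writer needs an integer sampling rate, got {rec.fs}")
    n_ch, n_samp = rec.signal.shape
    if n_samp % fs != 0:
        raise ValueError(
            f"signal length {n_samp} is not a whole number of 1-s records at {fs} Hz"
        )
    n_records = n_samp // fs

    # per-channel physical range; degenerate (constant) channels get +-1
    pmin = rec.signal.min(axis=1)
    pmax = rec.signal.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)
    scale = (pmax - pmin) / (2 * _EDF_DIG_MAX)
    digital = np.clip(
        np.round((rec.signal - pmin[:, None]) / scale[:, None]) - _EDF_DIG_MAX,
        -_EDF_DIG_MAX,
        _EDF_DIG_MAX,
    ).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF field too long: {text!r}")
        return b.ljust(width)

    header = b"".join(
        [
            pad("0", 8),
            pad(f"X X X {rec.subject_id}"[:80], 80),
            pad("Startdate X X X X"[:80], 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),  # record duration, seconds
            pad(str(n_ch), 4),
        ]
    )
    fields = []
    for width, values in (
        (16, rec.montage.channel_names),
        (80, [""] * n_ch),  # transducer
        (8, ["uV"] * n_ch),
        (8, [f"{v:.6g}"[:8] for v in pmin]),
        (8, [f"{v:.6g}"[:8] for v in pmax]),
        (8, [str(-_EDF_DIG_MAX)] * n_ch),
        (8, [str(_EDF_DIG_MAX)] * n_ch),
        (80, [""] * n_ch),  # prefiltering
        (8, [str(fs)] * n_ch),
        (32, [""] * n_ch),
    ):
        fields.append(b"".join(pad(str(v), width) for v in values))

    records = digital.reshape(n_ch, n_records, fs)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        for r in range(n_records):
            fh.write(records[:, r, :].tobytes())


def _read_edf(path) -> tuple[list[str], float, np.ndarray]:
    import mne

    mne.set_log_level("ERROR")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    # MNE returns volts for channels with a uV physical dimension
    return list(raw.ch_names), float(raw.info["sfreq"]), raw.get_data() * 1e6


# ---------------------------------------------------------------------------
# CSV matrix dialect
# ---------------------------------------------------------------------------


def write_csv_matrix(rec: EEGRecording, path) -> None:
    """Samples x channels CSV with channel names as the header row."""
    pd.DataFrame(rec.signal.T, columns=list(rec.montage.channel_names)).to_csv(
        path, index=False
    )


def _read_csv_matrix(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    return [str(c) for c in df.columns], df.to_numpy(dtype=float).T


# ---------------------------------------------------------------------------
# Recordings and cohorts
# ---------------------------------------------------------------------------


def read_recording(
    path,
    montage: Montage,
    *,
    subject_id: str | None = None,
    label: int | None = None,
    fs: float | None = None,
) -> EEGRecording:
    """Read one EDF or CSV-matrix recording, reordered to montage order.

    ``fs`` is required for the CSV dialect (taken from the manifest there);
    for EDF it is read from the file header and, if also given, must match.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        names, file_fs, signal = _read_edf(path)
        if fs is not None and abs(file_fs - fs) > 1e-6:
            raise ValueError(
                f"{path.name}: EDF sampling rate {file_fs} Hz does not match "
                f"manifest rate {fs} Hz"
            )
        fs = file_fs
    else:
        names, signal = _read_csv_matrix(path)
        if fs is None:
            raise ValueError(f"{path.name}: CSV recordings need a sampling rate")

    missing = [n for n in montage.channel_names if n not in names]
    if missing:
        raise KeyError(f"{path.name}: channels missing from file: {missing}")
    order = [names.index(n) for n in montage.channel_names]
    return EEGRecording(
        subject_id=subject_id or path.stem,
        label=label,
        montage=montage,
        fs=float(fs),
        signal=signal[order],
    )


def write_manifest(rows: list[dict], path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(manifest_path, montage: Montage | None = None) -> list[EEGRecording]:
    """Read all recordings listed in a cohort manifest CSV.

    The manifest needs ``subject_id``, ``class`` and ``filename`` columns
    (``fs`` required for CSV recordings); filenames are resolved relative to
    the manifest.  If no montage is given, ``montage.csv`` next to the
    manifest is used.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "class", "filename"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    if len(df) == 0:
        logger.warning("manifest %s is empty", manifest_path)
        return []
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate subject_id in manifest: {dupes}")
    if montage is None:
        montage = Montage.from_csv(manifest_path.parent / "montage.csv")

    recordings = []
    for row_number, row in enumerate(df.to_dict("records"), start=1):
        fpath = manifest_path.parent / str(row["filename"])
        fs = float(row["fs"]) if "fs" in row and pd.notna(row["fs"]) else None
        try:
            recordings.append(
                read_recording(
                    fpath,
                    montage,
                    subject_id=str(row["subject_id"]),
                    label=int(row["class"]),
                    fs=fs,
                )
            )
        except FileNotFoundError:
            raise FileNotFoundError(
                f"manifest row {row_number} ({row['subject_id']}): "
                f"file {fpath} not found"
            ) from None
    return recordings
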