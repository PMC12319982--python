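"""Reading, writing and epoch-level cleaning of resting-state EEG.

This module covers the plumbing around the microstate computation proper:
reading multichannel EEG from EDF/BDF, EEGLAB ``.set`` or the package's own
HDF5 container, cutting the continuous recording into fixed-length epochs,
rejecting high-amplitude epochs, average re-referencing, the minimum
segment-retention gate, and round-tripping long-format feature tables.

Voltages are microvolts throughout.  Channel positions are unit vectors on
the sensor sphere; they matter only for simulation, template construction
and plotting — global field power and spatial correlations are position-free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("mstates")

#: Columns of the long-format feature table, one value per
#: (subject, visit, class, feature).
FEATURE_COLUMNS = (
    "subject",
    "cohort",
    "visit",
    "age_months",
    "sex",
    "retained_segments",
    "class",
    "feature",
    "value",
)

FEATURE_KEY = ("subject", "visit", "class", "feature")


class FormatError(ValueError):
    """File could not be read as any supported EEG format."""


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class EmptyResultError(ValueError):
    """An operation produced no data (e.g. every epoch was rejected)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : sequence of str
    channel_positions : ndarray, shape (n_channels, 3)
        Unit vectors on the sensor sphere.
    reference : str
        ``"common"`` (common-electrode) or ``"average"``.
    """

    data: np.ndarray
    fs: float
    channel_names: Sequence[str]
    channel_positions: np.ndarray
    reference: str = "common"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_positions = np.asarray(self.channel_positions, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValidationError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_names):
            raise ValidationError(
                f"{self.data.shape[0]} data rows but {len(self.channel_names)} channel names"
            )
        if self.channel_positions.shape != (self.data.shape[0], 3):
            raise ValidationError("channel_positions must be n_channels x 3")
        norms = np.linalg.norm(self.channel_positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValidationError("channel positions must have unit norm")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochedEEG:
    """EEG cut into equal-length epochs.

    ``epochs`` has shape (n_epochs, n_channels, n_samples_per_epoch).
    """

    epochs: np.ndarray
    fs: float
    epoch_length_s: float
    channel_positions: np.ndarray
    channel_names: Sequence[str] = field(default_factory=list)
    reference: str = "common"

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValidationError("epochs must be epoch x channel x sample")
        expected = int(round(self.fs * self.epoch_length_s))
        if self.epochs.shape[0] and self.epochs.shape[2] != expected:
            raise ValidationError(
                f"each epoch must have {expected} samples, got {self.epochs.shape[2]}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples_per_epoch(self) -> int:
        return self.epochs.shape[2]


@dataclass
class FeatureTable:
    """Long-format per-subject-per-visit microstate statistics.

    One row per (subject, visit, class, feature); ``feature`` is one of
    ``duration`` (ms), ``occurrence`` (/s), ``coverage`` (fraction) or
    ``gev`` (fraction).  Sex is coded 0 = female, 1 = male; age in months.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df)
        missing = set(FEATURE_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"feature table missing columns: {sorted(missing)}")
        df = df[list(FEATURE_COLUMNS)].reset_index(drop=True)
        if len(df):
            if (df["age_months"] <= 0).any():
                raise ValidationError("ages must be positive")
            if (df["retained_segments"] < 0).any():
                raise ValidationError("retained_segments must be >= 0")
            dup = df.duplicated(subset=list(FEATURE_KEY))
            if dup.any():
                keys = df.loc[dup, list(FEATURE_KEY)].iloc[0].tolist()
                raise ValidationError(f"duplicate (subject, visit, class, feature) key: {keys}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def equals(self, other: "FeatureTable") -> bool:
        a = self.df.sort_values(list(FEATURE_KEY)).reset_index(drop=True)
        b = other.df.sort_values(list(FEATURE_KEY)).reset_index(drop=True)
        if a.shape != b.shape:
            return False
        for col in FEATURE_COLUMNS:
            if col in ("age_months", "value"):
                if not np.allclose(a[col].astype(float), b[col].astype(float)):
                    return False
            elif not (a[col].astype(str) == b[col].astype(str)).all():
                return False
        return True


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _generic_positions(n_channels: int) -> np.ndarray:
    # deterministic fallback montage; positions only affect simulation/plotting
    from .synthetic import make_montage

    return make_montage(n_channels, seed=0)


def write_eeg(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording to the documented HDF5 container.

    Datasets: ``/data`` (channels x samples, µV), ``/fs``, ``/channels``
    (UTF-8 names), ``/positions`` (n x 3 unit vectors); root attribute
    ``reference``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset(
            "channels", data=np.array([str(c) for c in rec.channel_names], dtype=object),
            dtype=h5py.string_dtype(),
        )
        f.create_dataset("positions", data=rec.channel_positions)
        f.attrs["reference"] = rec.reference


def _read_container(path: Path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        data = np.asarray(f["data"], dtype=float)
        fs = float(np.asarray(f["fs"]))
        names = [c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]]
        if "positions" in f:
            positions = np.asarray(f["positions"], dtype=float)
            if positions.shape[0] != data.shape[0]:
                raise ValidationError(
                    f"sidecar has {positions.shape[0]} positions for {data.shape[0]} channels"
                )
        else:
            logger.warning("container lacks /positions; assigning generic montage")
            positions = _generic_positions(data.shape[0])
        reference = str(f.attrs.get("reference", "common"))
    return EEGRecording(data, fs, names, positions, reference)


def _read_mne(path: Path, kind: str) -> EEGRecording:
    import mne

    readers = {
        "edf": mne.io.read_raw_edf,
        "bdf": mne.io.read_raw_bdf,
        "set": mne.io.read_raw_eeglab,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = readers[kind](str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    names = list(raw.ch_names)
    montage = raw.get_montage()
    positions = None
    if montage is not None:
        pos = montage.get_positions().get("ch_pos", {})
        if all(n in pos and np.all(np.isfinite(pos[n])) for n in names):
            arr = np.array([pos[n] for n in names], dtype=float)
            norms = np.linalg.norm(arr, axis=1)
            if np.all(norms > 0):
                positions = arr / norms[:, None]
    if positions is None:
        logger.warning("%s lacks channel positions; assigning generic montage", path.name)
        positions = _generic_positions(len(names))
    return EEGRecording(data, float(raw.info["sfreq"]), names, positions, "common")


def read_eeg(path: str | Path, format_hint: str | None = None) -> EEGRecording:
    """Read an EEG recording (EDF/BDF, EEGLAB ``.set``, or HDF5 container).

    The format is taken from ``format_hint`` (``"edf"``, ``"bdf"``,
    ``"set"``, ``"container"``) or inferred from the file suffix.  When the
    file carries no usable channel positions, a generic spherical montage is
    substituted and a warning logged.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    kind = (format_hint or path.suffix.lstrip(".")).lower()
    if kind in ("h5", "hdf5", "container"):
        return _read_container(path)
    if kind in ("edf", "bdf", "set"):
        try:
            return _read_mne(path, kind)
        except ValidationError:
            raise
        except Exception as exc:  # pragma: no cover - mne error classes vary
            raise FormatError(f"could not read {path} as {kind}: {exc}") from exc
    raise FormatError(f"unsupported format {kind!r} for {path}")


# ---------------------------------------------------------------------------
# Epoch-level cleaning
# ---------------------------------------------------------------------------

def epoch_recording(rec: EEGRecording, epoch_length_s: float = 2.0) -> EpochedEEG:
    """Cut a recording into consecutive non-overlapping fixed-length epochs.

    A trailing partial epoch is discarded.  Raises if the recording is
    shorter than one epoch.
    """
    n_per = int(round(rec.fs * epoch_length_s))
    n_epochs = rec.n_samples // n_per
    if n_epochs < 1:
        raise EmptyResultError(
            f"recording of {rec.n_samples} samples is shorter than one "
            f"{epoch_length_s} s epoch ({n_per} samples)"
        )
    trimmed = rec.data[:, : n_epochs * n_per]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochedEEG(
        epochs=epochs.copy(),
        fs=rec.fs,
        epoch_length_s=epoch_length_s,
        channel_positions=rec.channel_positions,
        channel_names=list(rec.channel_names),
        reference=rec.reference,
    )


def reject_high_amplitude(
    ep: EpochedEEG, threshold_uv: float = 150.0
) -> tuple[EpochedEEG, list[int]]:
    """Drop epochs where any channel's absolute voltage exceeds the threshold.

    The comparison is strict (an epoch peaking at exactly ``threshold_uv``
    is retained).  Returns the cleaned epochs and the list of removed epoch
    indices.
    """
    if ep.n_epochs == 0:
        raise EmptyResultError("no epochs to screen")
    peak = np.abs(ep.epochs).max(axis=(1, 2))
    bad = np.flatnonzero(peak > threshold_uv)
    if len(bad) == ep.n_epochs:
        raise EmptyResultError(
            f"all {ep.n_epochs} epochs exceeded ±{threshold_uv} µV"
        )
    keep = np.setdiff1d(np.arange(ep.n_epochs), bad)
    return replace(ep, epochs=ep.epochs[keep]), bad.tolist()


def apply_average_reference(ep: EpochedEEG) -> EpochedEEG:
    """Re-reference every sample to the instantaneous channel mean.

    Idempotent; preserves between-channel differences.
    """
    if ep.n_channels < 2:
        raise ValidationError("average reference requires >= 2 channels")
    mean = ep.epochs.mean(axis=1, keepdims=True)
    return replace(ep, epochs=ep.epochs - mean, reference="average")


@dataclass
class RetentionDecision:
    n_epochs: int
    min_segments: int
    passed: bool
    seconds: float


def check_retention(ep: EpochedEEG, min_segments: int = 15) -> RetentionDecision:
    """Gate on the number of retained epochs (strictly more than ``min_segments``).

    The default keeps participants with more than 15 two-second segments,
    i.e. over 30 s of clean data.
    """
    passed = ep.n_epochs > min_segments
    return RetentionDecision(
        n_epochs=ep.n_epochs,
        min_segments=min_segments,
        passed=passed,
        seconds=ep.n_epochs * ep.epoch_length_s,
    )


# ---------------------------------------------------------------------------
# Feature-table persistence
# ---------------------------------------------------------------------------

def persist_features(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV with the documented header."""
    table.df.to_csv(path, index=False)


def load_features(path: str | Path) -> FeatureTable:
    """Read a feature table written by :func:`persist_features`."""
    df = pd.read_csv(
        path,
        dtype={
            "subject": str,
            "cohort": str,
            "visit": int,
            "sex": int,
            "retained_segments": int,
            "class": str,
            "feature": str,
        },
    )
    if len(df) == 0:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in FEATURE_COLUMNS})
    return FeatureTable(df)
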