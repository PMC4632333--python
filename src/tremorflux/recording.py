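"""Tremor recording data model and CSV I/O.

A recording is one subject performing one task: a tri-axial angular-rate
time series at a fixed sampling rate (default 125 samples/s, 10 s -> 1250
rows). The CSV dialect is one header row ``t,gx,gy,gz`` (optional
``ax,ay,az`` accelerometer columns are accepted and ignored), comma
separated, one row per sample, ``t`` in seconds.

Angular-rate units are carried through unchanged; every downstream
statistic is either unit-agnostic or reported in squared signal units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ParameterError, ParseError

TASKS = ("kinetic", "postural", "resting")
AXES = ("x", "y", "z")

#: CSV columns, in order. Accelerometer columns may follow and are ignored.
_REQUIRED_COLUMNS = ("t", "gx", "gy", "gz")
_OPTIONAL_COLUMNS = ("ax", "ay", "az")

DEFAULT_SAMPLING_RATE = 125.0


def validate_axis(axis: str) -> str:
    if axis not in AXES:
        raise ParameterError(f"axis must be one of {AXES}, got {axis!r}")
    return axis


def validate_task(task: str) -> str:
    if task not in TASKS:
        raise ParameterError(f"task must be one of {TASKS}, got {task!r}")
    return task


@dataclass(frozen=True)
class TremorRecording:
    """One subject's one-task tri-axial angular-rate time series.

    Parameters
    ----------
    subject_id : str
        Free-text subject label.
    task : str
        One of ``kinetic``, ``postural``, ``resting``.
    samples : (N, 3) ndarray
        Angular rate, columns in x, y, z order; sensor units.
    sampling_rate : float
        Samples per second, default 125.
    """

    subject_id: str
    task: str
    samples: np.ndarray = field(repr=False)
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        validate_task(self.task)
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ParameterError(
                f"samples must be an (N, 3) array, got shape {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise EmptyInputError("recording must contain at least one sample")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, axis: str) -> np.ndarray:
        """Return the 1-D angular-rate series for one axis."""
        return self.samples[:, AXES.index(validate_axis(axis))]

    def with_samples(self, samples: np.ndarray) -> "TremorRecording":
        """Copy of this recording with the sample matrix replaced."""
        return TremorRecording(
            subject_id=self.subject_id,
            task=self.task,
            samples=samples,
            sampling_rate=self.sampling_rate,
        )


def read_recording(
    path: str | Path,
    subject_id: str,
    task: str,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> TremorRecording:
    """Read one recording from CSV, preserving row order and values exactly.

    Raises
    ------
    FormatError
        Missing or unexpected columns (the offending column is named).
    ParseError
        Non-numeric cell (the 0-based data row index is reported).
    EmptyInputError
        Empty file or header-only file.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    if frame.shape[0] == 0:
        raise EmptyInputError(f"{path} has a header but no data rows")

    columns = list(frame.columns)
    for col in _REQUIRED_COLUMNS:
        if col not in columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    allowed = set(_REQUIRED_COLUMNS) | set(_OPTIONAL_COLUMNS)
    for col in columns:
        if col not in allowed:
            raise FormatError(f"{path}: unexpected column {col!r}")

    numeric: dict[str, np.ndarray] = {}
    for col in _REQUIRED_COLUMNS:
        cells = frame[col].to_numpy()
        try:
            # numpy's parser is correctly rounded (unlike pd.to_numeric)
            numeric[col] = cells.astype(float)
        except (TypeError, ValueError):
            for row, cell in enumerate(cells):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric value {cell!r} "
                        f"in column {col!r} at data row {row}"
                    ) from None
            raise  # pragma: no cover - unreachable
        if np.isnan(numeric[col]).any():
            row = int(np.flatnonzero(np.isnan(numeric[col]))[0])
            raise ParseError(
                f"{path}: missing or non-numeric value in column {col!r} "
                f"at data row {row}"
            )

    _warn_on_rate_mismatch(numeric["t"], sampling_rate, path)

    samples = np.column_stack([numeric["gx"], numeric["gy"], numeric["gz"]])
    return TremorRecording(
        subject_id=subject_id,
        task=task,
        samples=samples,
        sampling_rate=sampling_rate,
    )


def write_recording(recording: TremorRecording, path: str | Path) -> None:
    """Write a recording in the package CSV dialect (inverse of read)."""
    path = Path(path)
    t = np.arange(recording.n_samples) / recording.sampling_rate
    frame = pd.DataFrame(
        {
            "t": t,
            "gx": recording.samples[:, 0],
            "gy": recording.samples[:, 1],
            "gz": recording.samples[:, 2],
        }
    )
    # 17 significant digits round-trips float64 exactly
    frame.to_csv(path, index=False, float_format="%.17g")


def _warn_on_rate_mismatch(t: np.ndarray, declared_rate: float, path: Path) -> None:
    # sampling rate is metadata; a >1% disagreement with the time column is
    # suspicious but not fatal
    if len(t) < 2:
        return
    median_dt = float(np.median(np.diff(t)))
    if median_dt <= 0:
        return
    implied = 1.0 / median_dt
    if abs(implied - declared_rate) / declared_rate > 0.01:
        warnings.warn(
            f"{path}: declared sampling rate {declared_rate:g} /s but the "
            f"time column implies {implied:g} /s",
            stacklevel=3,
        )
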