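"""Reading and writing mitoPO2 traces, label sequences and result files.

The on-disk dialect is deliberately minimal and text-only:

* ``*.trace.csv`` — ``sample_time_s,mitopo2_mmhg``; 1-Hz samples starting at 0.
* ``*.labels.csv`` — ``sample_time_s,label`` with labels in ``{na, start, measurement}``.
* ``*.results.json`` — per-subject fit results (see :func:`write_results`).

Conversion from vendor (COMET) exports is out of scope; sample indices are
0-based and intervals are inclusive of both ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

LABELS = ("na", "start", "measurement")
#: integer codes used throughout the package
NA, START, MEASUREMENT = 0, 1, 2
LABEL_TO_CODE = {"na": NA, "start": START, "measurement": MEASUREMENT}
CODE_TO_LABEL = {v: k for k, v in LABEL_TO_CODE.items()}

TRACE_HEADER = ["sample_time_s", "mitopo2_mmhg"]
LABELS_HEADER = ["sample_time_s", "label"]


class TraceFormatError(ValueError):
    """Raised when an on-disk trace or label file violates the dialect."""


@dataclass
class Trace:
    """One subject's 1-Hz mitoPO2 series (mmHg)."""

    subject_id: str
    mitopo2: np.ndarray  # float64, mmHg
    sample_time: np.ndarray = field(default=None)  # seconds, 0,1,2,...

    def __post_init__(self) -> None:
        self.mitopo2 = np.asarray(self.mitopo2, dtype=float)
        if self.mitopo2.ndim != 1 or self.mitopo2.size < 1:
            raise TraceFormatError("mitopo2 must be a 1-D series of length >= 1")
        if not np.all(np.isfinite(self.mitopo2)):
            bad = int(np.flatnonzero(~np.isfinite(self.mitopo2))[0])
            raise TraceFormatError(f"non-finite mitoPO2 value at row {bad}")
        if self.sample_time is None:
            self.sample_time = np.arange(self.mitopo2.size)
        self.sample_time = np.asarray(self.sample_time)
        if self.sample_time.shape != self.mitopo2.shape:
            raise TraceFormatError("sample_time and mitopo2 lengths differ")
        steps = np.diff(self.sample_time)
        if self.sample_time.size > 1 and not np.all(steps == 1):
            bad = int(np.flatnonzero(steps != 1)[0]) + 1
            raise TraceFormatError(f"non-uniform sampling at row {bad} "
                                   f"(expected step of 1 s)")

    def __len__(self) -> int:
        return self.mitopo2.size


@dataclass
class LabelSeq:
    """Per-sample classification into start / measurement / na.

    Stored as integer codes (:data:`NA`, :data:`START`, :data:`MEASUREMENT`).
    """

    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 1:
            raise TraceFormatError("labels must be 1-D")
        if self.codes.size and not np.all((self.codes >= 0) & (self.codes <= 2)):
            raise TraceFormatError("label codes must be 0 (na), 1 (start) or 2 (measurement)")

    @classmethod
    def from_strings(cls, labels: Sequence[str]) -> "LabelSeq":
        codes = np.empty(len(labels), dtype=np.int8)
        for i, lab in enumerate(labels):
            try:
                codes[i] = LABEL_TO_CODE[lab]
            except KeyError:
                raise TraceFormatError(
                    f"unknown label {lab!r} at row {i}; expected one of {LABELS}"
                ) from None
        return cls(codes)

    def to_strings(self) -> list[str]:
        return [CODE_TO_LABEL[int(c)] for c in self.codes]

    def start_indices(self) -> np.ndarray:
        return np.flatnonzero(self.codes == START)

    def __len__(self) -> int:
        return self.codes.size

    def __eq__(self, other) -> bool:  # type: ignore[override]
        return isinstance(other, LabelSeq) and np.array_equal(self.codes, other.codes)


@dataclass
class MeasurementSegment:
    """One stop-flow measurement: a start sample plus its consecutive
    measurement samples, inclusive on both ends."""

    start_index: int
    end_index: int
    mitopo2: np.ndarray

    def __post_init__(self) -> None:
        if self.end_index < self.start_index:
            raise ValueError("end_index must be >= start_index")
        self.mitopo2 = np.asarray(self.mitopo2, dtype=float)
        if self.mitopo2.size != self.end_index - self.start_index + 1:
            raise ValueError("segment values do not match [start_index, end_index]")

    def __len__(self) -> int:
        return self.mitopo2.size


def read_trace(path: str | Path, subject_id: str | None = None) -> Trace:
    """Read a ``*.trace.csv`` file into a :class:`Trace`.

    ``subject_id`` defaults to the filename stem (with a trailing ``.trace``
    stripped).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != TRACE_HEADER:
        raise TraceFormatError(f"{path}: expected header {','.join(TRACE_HEADER)}")
    for col in TRACE_HEADER:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise TraceFormatError(f"{path}: non-numeric value in column "
                                   f"{col!r} at row {bad}")
    if subject_id is None:
        subject_id = path.stem
        if subject_id.endswith(".trace"):
            subject_id = subject_id[: -len(".trace")]
    try:
        return Trace(subject_id=subject_id,
                     mitopo2=df["mitopo2_mmhg"].to_numpy(dtype=float),
                     sample_time=df["sample_time_s"].to_numpy(dtype=int))
    except TraceFormatError as exc:
        raise TraceFormatError(f"{path}: {exc}") from None


def write_trace(path: str | Path, trace: Trace) -> None:
    df = pd.DataFrame({"sample_time_s": trace.sample_time,
                       "mitopo2_mmhg": trace.mitopo2})
    df.to_csv(path, index=False, float_format="%.6f")


def read_labels(path: str | Path, trace: Trace | None = None) -> LabelSeq:
    """Read a ``*.labels.csv`` file; if ``trace`` is given, enforce alignment."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if list(df.columns) != LABELS_HEADER:
        raise TraceFormatError(f"{path}: expected header {','.join(LABELS_HEADER)}")
    try:
        seq = LabelSeq.from_strings(df["label"].tolist())
    except TraceFormatError as exc:
        raise TraceFormatError(f"{path}: {exc}") from None
    if trace is not None and len(seq) != len(trace):
        raise TraceFormatError(
            f"{path}: {len(seq)} labels do not match trace of {len(trace)} samples"
        )
    return seq


def write_labels(path: str | Path, labels: LabelSeq) -> None:
    df = pd.DataFrame({"sample_time_s": np.arange(len(labels)),
                       "label": labels.to_strings()})
    df.to_csv(path, index=False)


def write_results(path: str | Path, subject_results: list[dict]) -> None:
    """Write per-subject fit results as JSON.

    Each entry has the schema::

        {"subject_id": str,
         "measurements": [{"start_index", "end_index",
                           "params": {"v0","p50","p0","z"},
                           "vmax_mmhg_per_s", "converged"}, ...],
         "mitovo2_mmhg_per_s": float | null}
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(subject_results, fh, indent=2)
        fh.write("\n")


def read_results(path: str | Path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
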