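"""Core domain types shared across the pipeline.

The classification unit of the pipeline is a single-channel ECG recording
carrying one of three rhythm labels:

* ``ARR`` — cardiac arrhythmia,
* ``CHF`` — congestive heart failure,
* ``NSR`` — normal sinus rhythm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: The three rhythm classes, in canonical order.
CLASSES: tuple[str, str, str] = ("ARR", "CHF", "NSR")

#: Default 1-based row ranges of the reference 162-recording matrix:
#: rows 1-96 are ARR, 97-126 CHF, 127-162 NSR.
DEFAULT_LABEL_RANGES: dict[str, tuple[int, int]] = {
    "ARR": (1, 96),
    "CHF": (97, 126),
    "NSR": (127, 162),
}


class FormatError(ValueError):
    """Malformed or unrecognised on-disk data."""


class LabelingError(ValueError):
    """Labels that do not match the data they describe."""


@dataclass
class ECGRecord:
    """One labeled single-channel ECG recording.

    Parameters
    ----------
    record_id:
        Stable identifier; for matrix rows this encodes the 1-based row index.
    samples:
        The signal in millivolts (arbitrary offset), length >= 1.
    sampling_rate_hz:
        Positive sampling rate.
    label:
        One of :data:`CLASSES`.
    meta:
        Free-form provenance (e.g. the synthesis beat log).
    """

    record_id: str
    samples: np.ndarray
    sampling_rate_hz: float
    label: str
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.label not in CLASSES:
            raise LabelingError(
                f"unknown label {self.label!r}; expected one of {CLASSES}"
            )

    def __len__(self) -> int:
        return int(self.samples.size)


def labels_from_ranges(
    n_rows: int, ranges: dict[str, tuple[int, int]]
) -> list[str]:
    """Expand 1-based, inclusive per-class row ranges into a per-row label list.

    Ranges must tile ``1..n_rows`` without gaps or overlaps.
    """
    labels: list[str | None] = [None] * n_rows
    for cls, (lo, hi) in ranges.items():
        if cls not in CLASSES:
            raise FormatError(f"unknown label token {cls!r}")
        if not (1 <= lo <= hi <= n_rows):
            raise LabelingError(
                f"range {lo}-{hi} for {cls} outside matrix with {n_rows} rows"
            )
        for i in range(lo - 1, hi):
            if labels[i] is not None:
                raise LabelingError(f"row {i + 1} labeled twice")
            labels[i] = cls
    if any(l is None for l in labels):
        raise LabelingError("label ranges do not cover every row")
    return labels  # type: ignore[return-value]
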