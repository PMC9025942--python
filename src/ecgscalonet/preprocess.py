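"""Resampling, class balancing and fixed-window segmentation.

The pipeline's classification unit is a blind fixed window ("chunk") of 500
samples cut from the head of each recording: a 65,536-sample recording yields
floor(65536/500) = 131 available chunks of which the first 10 are kept and
the remainder discarded. No QRS detection or beat alignment is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import resample_poly

from .records import CLASSES, ECGRecord

__all__ = [
    "ChunkSet",
    "SegmentationError",
    "BalancingError",
    "resample_record",
    "segment_record",
    "balance_classes",
    "segment_dataset",
]


class SegmentationError(ValueError):
    pass


class BalancingError(ValueError):
    pass


@dataclass
class ChunkSet:
    """The ordered fixed-length windows cut from one recording."""

    record_id: str
    label: str
    chunk_length: int
    chunks: np.ndarray  # (n_chunks, chunk_length)
    source_offset_of_chunk: list[int]
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.chunks = np.atleast_2d(np.asarray(self.chunks, dtype=np.float64))
        if self.chunks.shape[1] != self.chunk_length:
            raise SegmentationError(
                f"chunks have length {self.chunks.shape[1]}, "
                f"expected {self.chunk_length}"
            )
        offs = self.source_offset_of_chunk
        if len(offs) != self.chunks.shape[0]:
            raise SegmentationError("one offset required per chunk")
        if any(o % self.chunk_length for o in offs):
            raise SegmentationError("offsets must be multiples of chunk_length")
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise SegmentationError("offsets must be strictly increasing")

    def __len__(self) -> int:
        return int(self.chunks.shape[0])


def available_chunks(record_length: int, chunk_length: int) -> int:
    """Number of complete non-overlapping windows: floor(length / chunk)."""
    return record_length // chunk_length


def resample_record(record: ECGRecord, target_rate_hz: float) -> ECGRecord:
    """Polyphase-resample a recording to ``target_rate_hz``.

    Output length is round(input_length * target / source). Returns the input
    unchanged (same object) when the rates already match.
    """
    if target_rate_hz <= 0:
        raise ValueError("target_rate_hz must be positive")
    if target_rate_hz == record.sampling_rate_hz:
        return record
    ratio = Fraction(target_rate_hz / record.sampling_rate_hz).limit_denominator(10_000)
    out = resample_poly(record.samples, ratio.numerator, ratio.denominator)
    return ECGRecord(
        record_id=record.record_id,
        samples=out,
        sampling_rate_hz=target_rate_hz,
        label=record.label,
        meta=dict(record.meta),
    )


def segment_record(
    record: ECGRecord, chunk_length: int = 500, max_chunks: int = 10,
    *, offset_strategy: str = "head", seed: int | None = None,
) -> ChunkSet:
    """Cut consecutive non-overlapping ``chunk_length`` windows.

    ``offset_strategy="head"`` (default, reproducible without a seed) keeps
    the first min(max_chunks, available) windows starting at offset 0;
    ``"random"`` samples that many windows without replacement from all
    available ones (sorted by offset), seeded.
    """
    n = len(record)
    if n < chunk_length:
        raise SegmentationError(
            f"record {record.record_id} has {n} samples, "
            f"shorter than one chunk of {chunk_length}"
        )
    available = available_chunks(n, chunk_length)
    count = min(max_chunks, available)
    if offset_strategy == "head":
        picks = np.arange(count)
    elif offset_strategy == "random":
        rng = np.random.default_rng(seed)
        picks = np.sort(rng.choice(available, size=count, replace=False))
    else:
        raise ValueError(f"unknown offset_strategy {offset_strategy!r}")
    offsets = [int(i) * chunk_length for i in picks]
    chunks = np.stack([record.samples[o : o + chunk_length] for o in offsets])
    return ChunkSet(
        record_id=record.record_id,
        label=record.label,
        chunk_length=chunk_length,
        chunks=chunks,
        source_offset_of_chunk=offsets,
        sampling_rate_hz=record.sampling_rate_hz,
    )


def balance_classes(
    records: list[ECGRecord],
    n_per_class: int = 30,
    seed: int | None = None,
    strategy: str = "first",
) -> list[ECGRecord]:
    """Subset to exactly ``n_per_class`` recordings per class.

    ``strategy="first"`` (default) keeps the first n of each class in input
    order — bit-reproducible without a seed; ``"random"`` samples without
    replacement under ``seed``. Output preserves input order.
    """
    by_class: dict[str, list[int]] = {c: [] for c in CLASSES}
    for i, r in enumerate(records):
        by_class[r.label].append(i)
    for cls in CLASSES:
        if len(by_class[cls]) < n_per_class:
            raise BalancingError(
                f"class {cls} has only {len(by_class[cls])} recordings, "
                f"need {n_per_class}"
            )
    keep: set[int] = set()
    rng = np.random.default_rng(seed)
    for cls in CLASSES:
        idx = by_class[cls]
        if strategy == "first":
            chosen = idx[:n_per_class]
        elif strategy == "random":
            chosen = list(rng.choice(len(idx), size=n_per_class, replace=False))
            chosen = [idx[i] for i in sorted(chosen)]
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        keep.update(chosen)
    return [r for i, r in enumerate(records) if i in keep]


def segment_dataset(
    records: list[ECGRecord],
    chunk_length: int = 500,
    max_chunks: int = 10,
    target_rate_hz: float | None = 128.0,
    **segment_kwargs,
) -> list[ChunkSet]:
    """Resample (when requested) then segment every recording, in order."""
    out = []
    for r in records:
        if target_rate_hz is not None:
            r = resample_record(r, target_rate_hz)
        out.append(segment_record(r, chunk_length, max_chunks, **segment_kwargs))
    return out
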