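"""On-disk formats: recordings matrices, signal files, image datasets, reports.

Supported containers for the recordings matrix:

* NumPy ``.npz`` with arrays ``Data`` (N x L) and optionally ``Labels``;
* NumPy ``.npy`` holding just the matrix;
* MATLAB ``.mat`` with fields ``Data`` and ``Labels`` (the layout the
  reference three-database ECG bundle ships in).

Labels may instead be given as 1-based inclusive per-class row ranges
(:data:`ecgscalonet.records.DEFAULT_LABEL_RANGES` reproduces the reference
layout: rows 1-96 ARR, 97-126 CHF, 127-162 NSR).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .records import (
    CLASSES,
    DEFAULT_LABEL_RANGES,
    ECGRecord,
    FormatError,
    LabelingError,
    labels_from_ranges,
)

logger = logging.getLogger(__name__)

MANIFEST_HEADER = ["path", "record_id", "chunk_index", "label"]


@dataclass(frozen=True)
class ManifestEntry:
    image_path: str
    record_id: str
    chunk_index: int
    label: str


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        keys = [(e.record_id, e.chunk_index) for e in self.entries]
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate (record_id, chunk_index) in manifest")

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# recordings matrix
# ---------------------------------------------------------------------------


def _decode_label_token(tok) -> str:
    if isinstance(tok, bytes):
        tok = tok.decode()
    tok = str(tok).strip()
    if tok not in CLASSES:
        raise FormatError(f"unknown label token {tok!r}")
    return tok


def _load_matrix_container(data_path: Path) -> tuple[np.ndarray, list[str] | None]:
    suffix = data_path.suffix.lower()
    if suffix == ".npz":
        with np.load(data_path, allow_pickle=False) as z:
            names = {k.lower(): k for k in z.files}
            if "data" not in names:
                raise FormatError(f"{data_path}: no 'Data' array in archive")
            data = np.asarray(z[names["data"]])
            labels = None
            if "labels" in names:
                labels = [_decode_label_token(t) for t in np.ravel(z[names["labels"]])]
        return data, labels
    if suffix == ".npy":
        return np.load(data_path, allow_pickle=False), None
    if suffix == ".mat":
        from scipy.io import loadmat

        mat = loadmat(data_path)
        names = {k.lower(): k for k in mat if not k.startswith("__")}
        if "data" not in names:
            raise FormatError(f"{data_path}: no 'Data' field in MAT file")
        data = np.asarray(mat[names["data"]])
        labels = None
        if "labels" in names:
            raw = mat[names["labels"]]
            labels = [_decode_label_token(np.squeeze(t)) for t in np.ravel(raw)]
        return data, labels
    raise FormatError(f"unrecognised matrix container extension: {data_path.name}")


def load_recordings_matrix(
    data_path,
    labels=None,
    *,
    sampling_rate_hz: float = 128.0,
) -> list[ECGRecord]:
    """Load an N x L recordings matrix into one :class:`ECGRecord` per row.

    ``labels`` may be: ``None`` (use labels stored in the container, or the
    default row ranges when absent), an explicit per-row sequence of label
    tokens, or a dict of 1-based inclusive ranges ``{class: (lo, hi)}``.
    Row order is preserved; ``record_id`` encodes the 1-based row index.
    """
    data_path = Path(data_path)
    data, stored_labels = _load_matrix_container(data_path)
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if data.size == 0:
        raise FormatError(f"{data_path}: empty recordings matrix")
    n_rows = data.shape[0]

    if labels is None:
        if stored_labels is not None:
            row_labels = stored_labels
        else:
            row_labels = labels_from_ranges(n_rows, DEFAULT_LABEL_RANGES)
    elif isinstance(labels, dict):
        row_labels = labels_from_ranges(n_rows, labels)
    else:
        row_labels = [_decode_label_token(t) for t in labels]

    if len(row_labels) != n_rows:
        raise LabelingError(
            f"{n_rows} matrix rows but {len(row_labels)} labels"
        )
    return [
        ECGRecord(
            record_id=f"row{(i + 1):04d}",
            samples=data[i],
            sampling_rate_hz=sampling_rate_hz,
            label=row_labels[i],
        )
        for i in range(n_rows)
    ]


def save_recordings_matrix(records: Sequence[ECGRecord], out_path) -> None:
    """Write records as an ``.npz`` matrix (fields ``Data`` and ``Labels``)."""
    out_path = Path(out_path)
    if not records:
        raise FormatError("cannot save an empty record list")
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise FormatError("all records must have equal length to form a matrix")
    data = np.stack([r.samples for r in records])
    labels = np.array([r.label for r in records])
    rates = np.array([r.sampling_rate_hz for r in records])
    np.savez(out_path, Data=data, Labels=labels, SamplingRates=rates)


# ---------------------------------------------------------------------------
# image datasets
# ---------------------------------------------------------------------------


def export_image_dataset(
    images: Sequence[np.ndarray],
    labels: Sequence[str],
    out_dir,
    *,
    record_ids: Sequence[str] | None = None,
    chunk_indices: Sequence[int] | None = None,
) -> DatasetManifest:
    """Write one lossless PNG per image plus a ``manifest.csv``.

    Images must share a common HxWx3 shape (227x227x3 in the reference
    pipeline). The manifest round-trips exactly through
    :func:`load_manifest`.
    """
    images = list(images)
    labels = list(labels)
    if len(images) != len(labels):
        raise FormatError(
            f"{len(images)} images but {len(labels)} labels"
        )
    if record_ids is None:
        record_ids = [f"img{i:05d}" for i in range(len(images))]
    if chunk_indices is None:
        chunk_indices = [0] * len(images)

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc

    entries: list[ManifestEntry] = []
    for img, lab, rid, ci in zip(images, labels, record_ids, chunk_indices):
        img = np.asarray(img)
        if img.ndim != 3 or img.shape[2] != 3:
            raise FormatError(f"image for {rid} is not HxWx3 (got {img.shape})")
        lab = _decode_label_token(lab)
        fname = f"{rid}_chunk{int(ci):03d}_{lab}.png"
        Image.fromarray(img.astype(np.uint8), mode="RGB").save(out_dir / fname)
        entries.append(ManifestEntry(fname, rid, int(ci), lab))

    manifest = DatasetManifest(entries)
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MANIFEST_HEADER)
        for e in entries:
            w.writerow([e.image_path, e.record_id, e.chunk_index, e.label])
    return manifest


def load_manifest(manifest_path) -> DatasetManifest:
    manifest_path = Path(manifest_path)
    with open(manifest_path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != MANIFEST_HEADER:
            raise FormatError(f"{manifest_path}: bad manifest header {header}")
        entries = [
            ManifestEntry(row[0], row[1], int(row[2]), _decode_label_token(row[3]))
            for row in reader
        ]
    return DatasetManifest(entries)


def load_image_dataset(manifest_path) -> tuple[np.ndarray, list[str]]:
    """Load all images referenced by a manifest as a (N,H,W,3) uint8 stack."""
    manifest_path = Path(manifest_path)
    manifest = load_manifest(manifest_path)
    root = manifest_path.parent
    imgs, labs = [], []
    for e in manifest.entries:
        with Image.open(root / e.image_path) as im:
            imgs.append(np.asarray(im.convert("RGB"), dtype=np.uint8))
        labs.append(e.label)
    return np.stack(imgs), labs


# ---------------------------------------------------------------------------
# single signal files (CSV / minimal WFDB)
# ---------------------------------------------------------------------------


def read_signal_file(path, format: str) -> ECGRecord:
    """Read a single-channel signal from a CSV or WFDB record.

    CSV: one sample per line; the sampling rate must appear in a
    ``# fs=<hz>`` header line. WFDB: text ``.hea`` header + format-16
    (little-endian int16) ``.dat``; for multi-channel records channel 0 is
    taken and a warning is logged.
    """
    path = Path(path)
    if format == "csv":
        return _read_csv_signal(path)
    if format == "wfdb":
        return _read_wfdb_signal(path)
    raise FormatError(f"unknown signal format {format!r}")


def _read_csv_signal(path: Path) -> ECGRecord:
    fs = None
    samples: list[float] = []
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("fs"):
                fs = float(body.split("=", 1)[1])
            continue
        samples.append(float(line.split(",")[0]))
    if fs is None:
        raise FormatError(f"{path}: missing '# fs=<hz>' sampling-rate header")
    if not samples:
        raise FormatError(f"{path}: no samples")
    return ECGRecord(
        record_id=path.stem, samples=np.array(samples),
        sampling_rate_hz=fs, label="NSR",
    )


def _read_wfdb_signal(path: Path) -> ECGRecord:
    """Minimal WFDB reader: text header + format-16 interleaved int16 samples."""
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    try:
        lines = [
            l.strip() for l in hea.read_text().splitlines()
            if l.strip() and not l.startswith("#")
        ]
    except OSError as exc:
        raise IOError(f"cannot read {hea}: {exc}") from exc
    rec_fields = lines[0].split()
    if len(rec_fields) < 3:
        raise FormatError(f"{hea}: malformed record line")
    name, n_sig = rec_fields[0], int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    if n_sig < 1:
        raise FormatError(f"{hea}: no signals")
    sig_lines = lines[1 : 1 + n_sig]
    first = sig_lines[0].split()
    dat_name, fmt = first[0], first[1]
    if fmt.split("+")[0] != "16":
        raise FormatError(f"{hea}: unsupported WFDB storage format {fmt!r} (only 16)")
    gain = 200.0
    if len(first) > 2:
        try:
            gain = float(first[2].split("(")[0].split("/")[0]) or 200.0
        except ValueError:
            pass
    dat_path = hea.parent / dat_name
    try:
        raw = np.frombuffer(dat_path.read_bytes(), dtype="<i2")
    except OSError as exc:
        raise IOError(f"cannot read {dat_path}: {exc}") from exc
    if n_sig > 1:
        logger.warning(
            "WFDB record %s has %d channels; taking channel 0", name, n_sig
        )
        raw = raw[: (raw.size // n_sig) * n_sig].reshape(-1, n_sig)[:, 0]
    if n_samples:
        raw = raw[:n_samples]
    return ECGRecord(
        record_id=name, samples=raw.astype(np.float64) / gain,
        sampling_rate_hz=fs, label="NSR",
    )


# ---------------------------------------------------------------------------
# metric reports
# ---------------------------------------------------------------------------


def write_metrics_json(report_dict: dict, out_path) -> None:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        json.dump(report_dict, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def read_metrics_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
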