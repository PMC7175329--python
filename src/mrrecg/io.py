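"""Core ECG data model and plain-text I/O.

A record is one subject's multi-lead ECG: a ``[n_leads, n_samples]`` float
array in millivolts, its sampling rate, per-record demographics (age,
gender) and a binary multi-label target. The on-disk reference dialect is
deliberately simple and text-only: one CSV per record (header row = lead
names, one column per lead) plus a JSON metadata sidecar, and a JSON
manifest listing the records of a dataset.

The canonical lead set is the 8 simultaneously acquired leads
I, II, V1..V6 at 500 Hz for 10 s (5000 samples); other lead sets, rates
and durations are accepted as long as the file is internally consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_LEADS",
    "DEFAULT_FS",
    "DEFAULT_DURATION_S",
    "ADC_UNIT_MV",
    "GENDERS",
    "LabelVector",
    "ECGRecord",
    "DatasetManifest",
    "SchemaError",
    "ECGParseError",
    "read_record",
    "write_record",
    "class_counts",
]

#: Canonical 8-lead order; files are reordered to this when possible.
CANONICAL_LEADS: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")
DEFAULT_FS: float = 500.0
DEFAULT_DURATION_S: float = 10.0
#: ADC unit voltage: 4.88 uV per least-significant bit, expressed in mV.
#: Applied at read time when a file declares raw integer units.
ADC_UNIT_MV: float = 4.88e-3
GENDERS = ("male", "female", "unknown")


class SchemaError(ValueError):
    """Raised when a file's shape or declared layout violates the schema."""


class ECGParseError(ValueError):
    """Raised when a record file cannot be parsed; names the offending spot."""


@dataclass(frozen=True)
class LabelVector:
    """Binary multi-label target over an ordered class universe."""

    values: np.ndarray  # int8 vector of length C, entries in {0, 1}
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "class_names", tuple(self.class_names))
        if values.ndim != 1 or values.shape[0] != len(self.class_names):
            raise SchemaError(
                f"label vector length {values.shape} does not match "
                f"{len(self.class_names)} class names"
            )
        if not np.isin(values, (0, 1)).all():
            raise SchemaError("label vector entries must be 0 or 1")

    @classmethod
    def from_names(
        cls, positives: Iterable[str], class_names: Sequence[str]
    ) -> "LabelVector":
        class_names = tuple(class_names)
        index = {name: i for i, name in enumerate(class_names)}
        values = np.zeros(len(class_names), dtype=np.int8)
        for name in positives:
            if name not in index:
                raise SchemaError(f"unknown class name: {name!r}")
            values[index[name]] = 1
        return cls(values, class_names)

    @property
    def positive_names(self) -> tuple[str, ...]:
        return tuple(n for n, v in zip(self.class_names, self.values) if v)

    def __len__(self) -> int:
        return len(self.class_names)


@dataclass
class ECGRecord:
    """One subject's multi-lead ECG with demographics and labels."""

    record_id: str
    signal: np.ndarray  # [n_leads, n_samples], millivolts
    fs: float
    lead_names: tuple[str, ...]
    age: int
    gender: str
    labels: LabelVector

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.lead_names = tuple(self.lead_names)
        self.validate()

    def validate(self) -> None:
        if self.signal.ndim != 2:
            raise SchemaError("signal must be 2-D [n_leads, n_samples]")
        if self.signal.shape[0] != len(self.lead_names):
            raise SchemaError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.lead_names)} lead names"
            )
        if not np.isfinite(self.signal).all():
            raise SchemaError(f"record {self.record_id}: non-finite sample values")
        if self.fs <= 0:
            raise SchemaError("sampling rate must be positive")
        if self.age < 0:
            raise SchemaError("age must be non-negative")
        if self.gender not in GENDERS:
            raise SchemaError(f"gender must be one of {GENDERS}, got {self.gender!r}")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's samples by name (e.g. ``"II"``)."""
        try:
            return self.signal[self.lead_names.index(name)]
        except ValueError:
            raise KeyError(f"record has no lead {name!r}") from None

    def with_signal(self, signal: np.ndarray) -> "ECGRecord":
        return replace(self, signal=np.asarray(signal, dtype=np.float64))


@dataclass
class DatasetManifest:
    """An ordered collection of records sharing one class universe."""

    records: list[ECGRecord]
    class_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.class_names and self.records:
            self.class_names = self.records[0].labels.class_names
        for rec in self.records:
            if rec.labels.class_names != tuple(self.class_names):
                raise SchemaError(
                    f"record {rec.record_id} uses a different class universe"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def label_matrix(self) -> np.ndarray:
        """[n_records, C] binary matrix of targets."""
        return np.stack([r.labels.values for r in self.records]).astype(np.int8)

    @property
    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def save(self, directory: str | Path) -> Path:
        """Write every record plus a JSON manifest; returns the manifest path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = []
        for rec in self.records:
            rel = f"{rec.record_id}.csv"
            write_record(rec, directory / rel)
            entries.append(
                {
                    "record_id": rec.record_id,
                    "path": rel,
                    "age": int(rec.age),
                    "gender": rec.gender,
                    "labels": list(rec.labels.positive_names),
                }
            )
        manifest_path = directory / "manifest.json"
        manifest_path.write_text(
            json.dumps(
                {"class_names": list(self.class_names), "records": entries},
                indent=1,
            )
        )
        return manifest_path

    @classmethod
    def load(cls, manifest_path: str | Path) -> "DatasetManifest":
        manifest_path = Path(manifest_path)
        meta = json.loads(manifest_path.read_text())
        class_names = tuple(meta["class_names"])
        records = []
        for entry in meta["records"]:
            rec = read_record(manifest_path.parent / entry["path"])
            rec = replace(
                rec,
                record_id=entry["record_id"],
                age=int(entry["age"]),
                gender=entry["gender"],
                labels=LabelVector.from_names(entry["labels"], class_names),
            )
            records.append(rec)
        return cls(records, class_names)


def _normalize_lead_order(
    signal: np.ndarray, lead_names: Sequence[str]
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Reorder leads to the canonical order when the lead set matches it."""
    if set(lead_names) == set(CANONICAL_LEADS):
        order = [list(lead_names).index(name) for name in CANONICAL_LEADS]
        return signal[order], CANONICAL_LEADS
    return signal, tuple(lead_names)


def read_record(
    path: str | Path,
    schema: str = "columnar-text",
    *,
    raw_units: bool = False,
    adc_unit_mv: float = ADC_UNIT_MV,
) -> ECGRecord:
    """Read one record from the columnar-text dialect.

    The file is a CSV whose header row names the leads and whose columns
    hold samples, one row per time step. Metadata comes from a JSON
    sidecar (``<path>.meta.json``) when present; otherwise the record
    gets default demographics and an empty label set. ``raw_units=True``
    converts integer ADC counts to millivolts via ``adc_unit_mv``.
    """
    path = Path(path)
    if schema != "columnar-text":
        raise SchemaError(
            f"unsupported schema {schema!r}; supported: 'columnar-text'"
        )
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise ECGParseError(f"{path}: {exc}") from exc
    lead_names = tuple(str(c).strip() for c in table.columns)
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = next(
            c for c in table.columns
            if not np.issubdtype(table[c].dtype, np.number)
        )
        raise ECGParseError(f"{path}: non-numeric samples in column {bad!r}")
    signal = np.asarray(values, dtype=np.float64).T  # [n_leads, n_samples]
    if raw_units:
        signal = signal * adc_unit_mv
    if len(lead_names) != len(CANONICAL_LEADS) and set(lead_names) & set(
        CANONICAL_LEADS
    ) == set(lead_names):
        raise SchemaError(
            f"{path}: expected {len(CANONICAL_LEADS)} leads, found "
            f"{len(lead_names)} ({', '.join(lead_names)})"
        )
    signal, lead_names = _normalize_lead_order(signal, lead_names)

    meta_path = path.with_name(path.name + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        labels = LabelVector.from_names(meta["labels"], meta["class_names"])
        return ECGRecord(
            record_id=meta["record_id"],
            signal=signal,
            fs=float(meta["fs"]),
            lead_names=lead_names,
            age=int(meta["age"]),
            gender=meta["gender"],
            labels=labels,
        )
    return ECGRecord(
        record_id=path.stem,
        signal=signal,
        fs=DEFAULT_FS,
        lead_names=lead_names,
        age=0,
        gender="unknown",
        labels=LabelVector(np.zeros(0, dtype=np.int8), ()),
    )


def write_record(rec: ECGRecord, path: str | Path) -> None:
    """Write one record as CSV plus a JSON metadata sidecar."""
    rec.validate()
    path = Path(path)
    table = pd.DataFrame(rec.signal.T, columns=list(rec.lead_names))
    # full float precision so the read/write round trip is exact
    table.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "record_id": rec.record_id,
        "fs": rec.fs,
        "age": int(rec.age),
        "gender": rec.gender,
        "labels": list(rec.labels.positive_names),
        "class_names": list(rec.labels.class_names),
    }
    path.with_name(path.name + ".meta.json").write_text(json.dumps(meta, indent=1))


def class_counts(manifest: DatasetManifest) -> np.ndarray:
    """Per-class positive-record counts; sums to the total label instances."""
    if len(manifest) == 0:
        return np.zeros(len(manifest.class_names), dtype=np.int64)
    return manifest.label_matrix.sum(axis=0).astype(np.int64)
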