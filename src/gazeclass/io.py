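"""Fixation data model, validation, and CSV/TSV readers/writers.

The on-disk schema is a flat table with a header row and the six columns
``subject_id, group, image_id, x, y, duration_ms``.  Coordinates are screen
pixels (origin top-left, x rightward, y downward); durations are
milliseconds.  Group labels are matched case-insensitively on input and
canonicalized to ``expert`` / ``layman``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "FixationRecord",
    "FixationDataset",
    "SchemaError",
    "ParseError",
    "ConsistencyError",
    "ValidationReport",
    "load_fixations",
    "write_fixations",
    "filter_image",
    "validate",
    "GROUP_LABELS",
    "SCREEN_WIDTH",
    "SCREEN_HEIGHT",
]

GROUP_LABELS = ("expert", "layman")

#: display resolution used when flagging off-screen fixations
SCREEN_WIDTH = 1920
SCREEN_HEIGHT = 1200

COLUMNS = ["subject_id", "group", "image_id", "x", "y", "duration_ms"]

_DIALECT_SEP = {"csv": ",", "tsv": "\t"}


class SchemaError(ValueError):
    """The input table is missing a required column."""


class ParseError(ValueError):
    """A cell of the input table could not be converted to a number."""


class ConsistencyError(ValueError):
    """A subject appears with more than one group label."""


def _canonical_group(raw: str) -> str:
    label = str(raw).strip().lower()
    if label not in GROUP_LABELS:
        raise ValueError(
            f"unknown group label {raw!r}; expected one of {GROUP_LABELS}"
        )
    return label


@dataclass(frozen=True)
class FixationRecord:
    """One detected fixation: who looked where, on which image, for how long."""

    subject_id: str
    group: str
    image_id: str
    x: float
    y: float
    duration: float  # milliseconds

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", _canonical_group(self.group))
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")
        if not (np.isfinite(self.duration) and self.duration > 0):
            raise ValueError(f"duration must be strictly positive, got {self.duration}")


class FixationDataset:
    """Ordered collection of :class:`FixationRecord` with provenance metadata.

    Iteration order is the input order.  Every subject maps to exactly one
    group label; violating records raise :class:`ConsistencyError`.
    """

    def __init__(self, records: Iterable[FixationRecord], provenance: str = ""):
        self.records: list[FixationRecord] = list(records)
        self.provenance = provenance
        groups: dict[str, str] = {}
        for rec in self.records:
            prev = groups.setdefault(rec.subject_id, rec.group)
            if prev != rec.group:
                raise ConsistencyError(
                    f"subject {rec.subject_id!r} labeled both {prev!r} and {rec.group!r}"
                )
        self._groups = groups

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[FixationRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FixationDataset):
            return NotImplemented
        return self.records == other.records

    @property
    def subjects(self) -> list[str]:
        """Subject ids in order of first appearance."""
        return list(self._groups)

    @property
    def images(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.image_id)
        return list(seen)

    def group_of(self, subject_id: str) -> str:
        return self._groups[subject_id]

    def positions(self) -> np.ndarray:
        """N x 2 array of (x, y) fixation positions in record order."""
        return np.array([[r.x, r.y] for r in self.records], dtype=float).reshape(-1, 2)

    def durations(self) -> np.ndarray:
        return np.array([r.duration for r in self.records], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "group": [r.group for r in self.records],
                "image_id": [r.image_id for r in self.records],
                "x": [r.x for r in self.records],
                "y": [r.y for r in self.records],
                "duration_ms": [r.duration for r in self.records],
            }
        )


def load_fixations(path: str | Path, dialect: str = "csv") -> FixationDataset:
    """Read a fixation table from ``path``.

    Raises :class:`SchemaError` for a missing column, :class:`ParseError`
    (citing the 1-based data row) for a non-numeric ``x``/``y``/``duration_ms``
    cell, and :class:`ConsistencyError` when a subject carries two group
    labels.
    """
    path = Path(path)
    sep = _DIALECT_SEP[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        numeric = {}
        for col in ("x", "y", "duration_ms"):
            raw = getattr(row, col)
            try:
                numeric[col] = float(raw)
            except ValueError:
                raise ParseError(
                    f"row {i}: could not parse {col}={raw!r} as a number"
                ) from None
        records.append(
            FixationRecord(
                subject_id=str(row.subject_id),
                group=str(row.group),
                image_id=str(row.image_id),
                x=numeric["x"],
                y=numeric["y"],
                duration=numeric["duration_ms"],
            )
        )
    return FixationDataset(records, provenance=f"loaded from {path}")


def write_fixations(ds: FixationDataset, path: str | Path, dialect: str = "csv") -> None:
    """Write ``ds`` to ``path`` with 6-decimal precision (lossless round-trip)."""
    sep = _DIALECT_SEP[dialect]
    ds.to_dataframe().to_csv(Path(path), sep=sep, index=False, float_format="%.6f")


def filter_image(ds: FixationDataset, image_id: str) -> FixationDataset:
    """Records with matching ``image_id``, order preserved.

    An unknown id yields an empty dataset and a warning, not an error.
    """
    kept = [r for r in ds.records if r.image_id == image_id]
    if not kept:
        warnings.warn(f"no fixations for image {image_id!r}", stacklevel=2)
    return FixationDataset(kept, provenance=f"{ds.provenance} | image={image_id}")


@dataclass
class ValidationReport:
    """Report-only summary of a dataset; never mutates the data."""

    n_records: int
    counts: dict[tuple[str, str], int]  # (subject_id, image_id) -> fixation count
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def per_subject_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (subj, _img), n in self.counts.items():
            out[subj] = out.get(subj, 0) + n
        return out


def validate(ds: FixationDataset) -> ValidationReport:
    """Count fixations per subject/image and flag off-screen or duplicate rows."""
    counts: dict[tuple[str, str], int] = {}
    issues: list[str] = []
    seen: set[tuple] = set()
    for i, rec in enumerate(ds.records):
        key = (rec.subject_id, rec.image_id)
        counts[key] = counts.get(key, 0) + 1
        if not (0 <= rec.x <= SCREEN_WIDTH and 0 <= rec.y <= SCREEN_HEIGHT):
            issues.append(
                f"record {i}: off-screen fixation at ({rec.x}, {rec.y}) "
                f"for subject {rec.subject_id!r}"
            )
        full = (rec.subject_id, rec.image_id, rec.x, rec.y, rec.duration)
        if full in seen:
            issues.append(f"record {i}: duplicate row for subject {rec.subject_id!r}")
        seen.add(full)
    return ValidationReport(n_records=len(ds), counts=counts, issues=issues)
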