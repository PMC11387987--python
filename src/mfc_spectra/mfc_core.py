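"""Data model, tidy-file I/O and normalization for minimum-foot-clearance series.

A minimum-foot-clearance (MFC) series holds one scalar clearance height per
stride for one subject, sampled at one sample per stride, together with an
optional binary training outcome (``improved`` / ``unimproved``).  Cohorts are
carried in long/tidy CSV with columns ``subject_id, stride_index, mfc_value``
and an optional ``label`` column; stride indices are 1-based and must be
consecutive within a subject.
"""

from __future__ import annotations

import dataclasses
from dataclasses import InitVar, dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

LABELS = ("improved", "unimproved")

__all__ = [
    "LABELS",
    "MFCError",
    "FormatError",
    "ValidationError",
    "DegenerateInputError",
    "MFCSeries",
    "Cohort",
    "FeatureTable",
    "read_cohort",
    "write_cohort",
    "normalize_series",
    "read_feature_table",
    "write_feature_table",
]


class MFCError(ValueError):
    """Base class for all domain errors raised by this package."""


class FormatError(MFCError):
    """An input table does not have the expected layout."""


class ValidationError(MFCError):
    """Data violate a series, cohort or feature-table invariant."""


class DegenerateInputError(MFCError):
    """Structurally valid input that is degenerate for the requested operation."""


@dataclass
class MFCSeries:
    """One subject's ordered stride-clearance values.

    Parameters
    ----------
    subject_id:
        Unique subject identifier.
    values:
        Clearance height per stride, ordered by stride.  Raw series are in any
        consistent positive unit (mm, m); normalized series are unitless.
    label:
        Binary training outcome, one of :data:`LABELS`, or ``None`` when unknown.
    normalized:
        Whether the values have been normalized to the unit interval.
    check_range:
        Skip the range invariant (used internally for noise-contaminated
        copies, whose values may leave [0, 1] slightly).
    """

    subject_id: str
    values: np.ndarray
    label: str | None = None
    normalized: bool = False
    meta: dict = field(default_factory=dict)
    check_range: InitVar[bool] = True

    def __post_init__(self, check_range: bool) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError(
                f"series {self.subject_id!r}: need a 1-d sequence of >= 2 strides"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"series {self.subject_id!r}: non-finite values")
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(
                f"series {self.subject_id!r}: label {self.label!r} not in {LABELS}"
            )
        if check_range:
            if self.normalized:
                if self.values.min() < 0.0 or self.values.max() > 1.0:
                    raise ValidationError(
                        f"series {self.subject_id!r}: normalized values outside [0, 1]"
                    )
            elif self.values.min() <= 0.0:
                raise ValidationError(
                    f"series {self.subject_id!r}: raw clearance heights must be "
                    "strictly positive"
                )

    @property
    def n(self) -> int:
        """Number of strides."""
        return int(self.values.size)

    def replace(self, **changes) -> "MFCSeries":
        """Return a copy with ``changes`` applied (values are copied)."""
        out = dataclasses.replace(self, **changes)
        out.values = np.array(out.values, dtype=float, copy=True)
        return out


@dataclass
class Cohort:
    """A list of :class:`MFCSeries` with unique subject ids."""

    series: list[MFCSeries]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.series]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self) -> Iterator[MFCSeries]:
        return iter(self.series)

    def get(self, subject_id: str) -> MFCSeries:
        for s in self.series:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.series:
            if s.label is not None:
                counts[s.label] = counts.get(s.label, 0) + 1
        return counts

    @property
    def labels(self) -> list[str | None]:
        return [s.label for s in self.series]


def read_cohort(path, *, sep: str = ",", normalized: bool = False) -> Cohort:
    """Read a tidy cohort file into a :class:`Cohort`.

    The file must contain columns ``subject_id``, ``stride_index`` and
    ``mfc_value``; a ``label`` column is attached when present.  Stride indices
    must be consecutive integers within each subject (any starting offset), and
    each (subject, stride) pair must occur exactly once.

    Set ``normalized=True`` when the stored values are already normalized to
    [0, 1] (e.g. a round-tripped synthetic cohort).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = ["subject_id", "stride_index", "mfc_value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    if df.empty:
        raise FormatError(f"empty cohort file: {path}")

    values = pd.to_numeric(df["mfc_value"], errors="coerce")
    if values.isna().any():
        bad = df.loc[values.isna()].index[0]
        raise ValidationError(f"non-numeric mfc_value at row {bad}")
    strides = pd.to_numeric(df["stride_index"], errors="coerce")
    if strides.isna().any() or (strides != strides.round()).any():
        raise ValidationError("stride_index must be integer")

    has_label = "label" in df.columns
    series: list[MFCSeries] = []
    # preserve order of first appearance
    for sid in df["subject_id"].drop_duplicates():
        sub = df[df["subject_id"] == sid]
        idx = sub["stride_index"].to_numpy(dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValidationError(f"subject {sid!r}: duplicate stride_index")
        order = np.argsort(idx)
        idx = idx[order]
        if not np.all(np.diff(idx) == 1):
            gap = int(idx[np.flatnonzero(np.diff(idx) != 1)[0]])
            raise ValidationError(
                f"subject {sid!r}: stride_index not consecutive after {gap}"
            )
        vals = sub["mfc_value"].to_numpy(dtype=float)[order]
        label: str | None = None
        if has_label:
            lab = sub["label"].dropna().unique()
            if len(lab) > 1:
                raise ValidationError(f"subject {sid!r}: conflicting labels {lab}")
            if len(lab) == 1:
                label = str(lab[0])
        series.append(
            MFCSeries(str(sid), vals, label=label, normalized=normalized)
        )
    return Cohort(series)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort in the long/tidy CSV layout read by :func:`read_cohort`.

    Float values are written with ``repr`` precision, so a write/read round
    trip reproduces every series bit-exactly.
    """
    rows = []
    for s in cohort:
        for i, v in enumerate(s.values, start=1):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "stride_index": i,
                    "mfc_value": v,
                    "label": s.label if s.label is not None else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def normalize_series(s: MFCSeries, method: str = "minmax") -> MFCSeries:
    """Normalize a series to reduce scale and between-subject level effects.

    ``minmax`` maps the values affinely onto [0, 1]; ``max`` divides by the
    maximum (range (0, 1], no exact zeros, which keeps percentage-index
    operations well defined); ``none`` returns an unchanged copy.
    Normalization is per subject.
    """
    if method == "none":
        return s.replace()
    if s.normalized:
        raise ValidationError(f"series {s.subject_id!r} is already normalized")
    x = s.values
    if method == "minmax":
        rng = x.max() - x.min()
        if rng == 0.0:
            raise DegenerateInputError(
                f"series {s.subject_id!r}: constant series cannot be minmax-normalized"
            )
        vals = (x - x.min()) / rng
    elif method == "max":
        vals = x / x.max()
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return MFCSeries(
        s.subject_id, vals, label=s.label, normalized=True, meta=dict(s.meta)
    )


@dataclass
class FeatureTable:
    """Subjects x named-features matrix with per-subject labels."""

    subject_ids: list[str]
    feature_names: list[str]
    matrix: np.ndarray
    labels: list[str | None]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, p = len(self.subject_ids), len(self.feature_names)
        if self.matrix.shape != (n, p):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} != ({n} subjects, {p} features)"
            )
        if len(self.labels) != n:
            raise ValidationError("labels length does not match subjects")
        if len(set(self.subject_ids)) != n:
            raise ValidationError("duplicate subject ids in feature table")
        if len(set(self.feature_names)) != p:
            raise ValidationError("duplicate feature names")
        if n and p and not np.all(np.isfinite(self.matrix)):
            raise ValidationError("feature matrix contains non-finite entries")

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str | None, Mapping[str, float]]]
    ) -> "FeatureTable":
        """Build from ``(subject_id, label, {feature: value})`` records."""
        if not records:
            raise ValidationError("no records")
        names = list(records[0][2].keys())
        mat = np.array([[rec[2][k] for k in names] for rec in records], dtype=float)
        return cls(
            [rec[0] for rec in records], names, mat, [rec[1] for rec in records]
        )

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.feature_names.index(name)]

    def select(self, names: Sequence[str]) -> "FeatureTable":
        cols = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            list(self.subject_ids), list(names), self.matrix[:, cols], list(self.labels)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_names)
        df.insert(0, "label", [l if l is not None else "" for l in self.labels])
        df.insert(0, "subject_id", self.subject_ids)
        return df


def write_feature_table(t: FeatureTable, path) -> None:
    """Write ``subject_id, label, <features...>`` CSV at full float precision."""
    if not t.subject_ids or not t.feature_names:
        raise ValidationError("refusing to write an empty feature table")
    t.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> FeatureTable:
    """Read a CSV produced by :func:`write_feature_table`."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("subject_id", "label"):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r}")
    names = [c for c in df.columns if c not in ("subject_id", "label")]
    labels = [
        None if (pd.isna(l) or l == "") else str(l) for l in df["label"].tolist()
    ]
    return FeatureTable(
        [str(s) for s in df["subject_id"].tolist()],
        names,
        df[names].to_numpy(dtype=float),
        labels,
    )
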