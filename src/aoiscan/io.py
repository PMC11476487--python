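"""Readers and writers for sequence, fixation, and AOI tables.

File dialects (all UTF-8, comma-separated, header required):

* sequence CSV — columns ``id,sequence``; a sequence cell is either a
  compact single-letter string (``LATITS``) or delimiter-separated tokens
  (``Strips|BRITE|Runway``; delimiter configurable, default ``|``).
* fixation CSV — columns ``participant_id,order_key,x,y,aoi_label``; each
  record needs either coordinates or a pre-assigned label.
* AOI CSV — columns ``label,x_min,y_min,x_max,y_max`` defining labelled
  rectangles for hit-testing.

Coordinates are pixels with origin at the top-left, x rightward and y
downward. Rectangle containment is half-open, ``[min, max)``, so abutting
AOIs never both claim a boundary point; where rectangles genuinely overlap,
the first-defined AOI wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .core import (
    DEFAULT_DELIMITER,
    EmptyScanPathError,
    ScanPath,
    collapse_consecutive,
    make_scanpath,
    tokenize,
    validate_label,
)

__all__ = [
    "FixationRecord",
    "AOIDefinition",
    "read_sequences",
    "write_sequences",
    "read_fixations",
    "read_aois",
    "assign_aoi",
    "fixations_to_scanpaths",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FixationRecord:
    """One fixation: who, when (ordering only), and where.

    ``order_key`` orders fixations within a participant (an index or a
    timestamp). Either screen coordinates or a pre-assigned AOI label must
    be present.
    """

    participant_id: str
    order_key: float
    x: Optional[float] = None
    y: Optional[float] = None
    aoi_label: Optional[str] = None

    def __post_init__(self) -> None:
        has_xy = self.x is not None and self.y is not None
        if not has_xy and self.aoi_label is None:
            raise ValueError(
                f"fixation ({self.participant_id!r}, {self.order_key}) has "
                "neither coordinates nor an AOI label"
            )


@dataclass(frozen=True)
class AOIDefinition:
    """An AOI label bound to a pixel rectangle (half-open on max edges)."""

    label: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        validate_label(self.label)
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"AOI {self.label!r} rectangle is degenerate: "
                f"({self.x_min},{self.y_min})-({self.x_max},{self.y_max})"
            )

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max


def read_sequences(
    path, delimiter: str = DEFAULT_DELIMITER
) -> list[ScanPath]:
    """Read a sequence CSV into collapsed :class:`ScanPath` objects.

    Row order is preserved. Missing ``id``/``sequence`` columns raise a
    format error naming the column; an empty sequence cell raises an
    empty-scan-path error citing the row. A header-only file returns an
    empty list with a logged warning.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("id", "sequence"):
        if col not in frame.columns:
            raise ValueError(f"sequence file {path} is missing column {col!r}")
    if frame.empty:
        logger.warning("sequence file %s contains no data rows", path)
        return []
    paths = []
    for row_num, (pid, seq) in enumerate(
        zip(frame["id"], frame["sequence"]), start=2
    ):
        if seq == "":
            raise EmptyScanPathError(
                f"empty sequence for id {pid!r} at row {row_num} of {path}"
            )
        paths.append(make_scanpath(pid, tokenize(seq, delimiter)))
    return paths


def write_sequences(
    paths: Sequence[ScanPath], out, delimiter: str = DEFAULT_DELIMITER
) -> None:
    """Write scan paths as a sequence CSV (inverse of :func:`read_sequences`)."""
    frame = pd.DataFrame(
        {"id": [p.id for p in paths], "sequence": [p.to_text(delimiter) for p in paths]}
    )
    frame.to_csv(out, index=False)


def _opt_float(value: str) -> Optional[float]:
    return None if value == "" else float(value)


def read_fixations(path) -> list[FixationRecord]:
    """Read a fixation CSV; ``x``, ``y`` and ``aoi_label`` may be blank per row."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("participant_id", "order_key"):
        if col not in frame.columns:
            raise ValueError(f"fixation file {path} is missing column {col!r}")
    records = []
    for _, row in frame.iterrows():
        records.append(
            FixationRecord(
                participant_id=row["participant_id"],
                order_key=float(row["order_key"]),
                x=_opt_float(row.get("x", "")),
                y=_opt_float(row.get("y", "")),
                aoi_label=(row.get("aoi_label", "") or None),
            )
        )
    return records


def read_aois(path) -> list[AOIDefinition]:
    """Read an AOI CSV into rectangle definitions; labels must be unique."""
    frame = pd.read_csv(path, dtype={"label": str})
    needed = ("label", "x_min", "y_min", "x_max", "y_max")
    for col in needed:
        if col not in frame.columns:
            raise ValueError(f"AOI file {path} is missing column {col!r}")
    aois = [
        AOIDefinition(
            label=row["label"],
            x_min=float(row["x_min"]),
            y_min=float(row["y_min"]),
            x_max=float(row["x_max"]),
            y_max=float(row["y_max"]),
        )
        for _, row in frame.iterrows()
    ]
    labels = [a.label for a in aois]
    if len(set(labels)) != len(labels):
        raise ValueError(f"AOI file {path} has duplicate labels")
    return aois


def assign_aoi(
    fix: FixationRecord, aois: Sequence[AOIDefinition]
) -> Optional[str]:
    """Label of the first AOI whose rectangle contains the fixation, else None.

    Containment is half-open ``[min, max)``; the first matching AOI in
    definition order wins when rectangles overlap.
    """
    if fix.x is None or fix.y is None:
        raise ValueError(
            f"fixation ({fix.participant_id!r}, {fix.order_key}) has no coordinates"
        )
    for aoi in aois:
        if aoi.contains(fix.x, fix.y):
            return aoi.label
    return None


def fixations_to_scanpaths(
    records: Sequence[FixationRecord],
    aois: Optional[Sequence[AOIDefinition]] = None,
) -> list[ScanPath]:
    """Build one collapsed scan path per participant from fixations.

    Fixations are grouped by participant and sorted by ``order_key``
    (duplicate keys within a participant are an error). Records carrying a
    pre-assigned label use it directly; otherwise the label is resolved by
    :func:`assign_aoi`, which requires *aois*. Fixations landing outside
    every AOI are dropped; a participant with no in-AOI fixation is dropped
    entirely with a logged warning. Participants are emitted in first-seen
    order.
    """
    by_participant: dict[str, list[FixationRecord]] = {}
    for rec in records:
        by_participant.setdefault(rec.participant_id, []).append(rec)

    paths: list[ScanPath] = []
    for pid, fixes in by_participant.items():
        keys = [f.order_key for f in fixes]
        if len(set(keys)) != len(keys):
            raise ValueError(f"participant {pid!r} has duplicate order keys")
        labels: list[str] = []
        n_outside = 0
        for fix in sorted(fixes, key=lambda f: f.order_key):
            if fix.aoi_label is not None:
                labels.append(fix.aoi_label)
                continue
            if aois is None:
                raise ValueError(
                    f"fixation ({pid!r}, {fix.order_key}) has no AOI label and "
                    "no AOI definitions were provided"
                )
            label = assign_aoi(fix, aois)
            if label is None:
                n_outside += 1
            else:
                labels.append(label)
        if n_outside:
            logger.info(
                "participant %s: %d fixation(s) outside all AOIs excluded",
                pid,
                n_outside,
            )
        if not labels:
            logger.warning(
                "participant %s has no in-AOI fixations and was dropped", pid
            )
            continue
        paths.append(ScanPath(id=pid, labels=tuple(collapse_consecutive(labels))))
    return paths
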