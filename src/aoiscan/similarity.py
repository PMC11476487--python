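"""The two scan-path similarity metrics and their pairwise matrices.

Jaccard coefficient similarity compares *what* was looked at: it is the
intersection-over-union of the two scan paths' distinct-AOI sets,

    J(A, B) = |A ∩ B| / |A ∪ B|,

and is therefore order-insensitive — a sequence and its reversal always
score 1. Normalized string-edit similarity compares *in what order*: with
``d`` the unit-cost Levenshtein distance (minimal insertions + deletions +
substitutions) between the two label sequences and ``n`` the length of the
longer sequence,

    S(A, B) = 1 − d / n,

which lies in [0, 1] because the distance between sequences of lengths
``m ≤ n`` never exceeds ``n``. The two metrics together separate scan
paths that visit the same AOIs in the same order from those that share
content but not order, or neither.

Levenshtein distances are computed by ``edlib`` on the token sequences;
a dynamic-programming fallback handles inputs edlib cannot encode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import edlib
import numpy as np
import pandas as pd

from .core import EmptyScanPathError, ScanPath

__all__ = [
    "Metric",
    "EditDistanceResult",
    "SimilarityMatrix",
    "jaccard_similarity",
    "string_edit_distance",
    "string_edit_similarity",
    "pairwise_matrix",
    "METRIC_FUNCTIONS",
]

Metric = Literal["jaccard", "string_edit"]


@dataclass(frozen=True)
class EditDistanceResult:
    """Minimal unit-cost edit distance and its normalization length.

    ``distance`` is the minimal total number of insertions, deletions and
    substitutions (unit cost each); ``norm_length`` is the length of the
    longer of the two sequences, the ``n`` of the similarity formula.
    """

    distance: int
    norm_length: int

    def __post_init__(self) -> None:
        if not (0 <= self.distance <= self.norm_length):
            raise ValueError(
                f"edit distance {self.distance} outside [0, {self.norm_length}]"
            )

    @property
    def similarity(self) -> float:
        return 1.0 - self.distance / self.norm_length


def _levenshtein_dp(a: Sequence[str], b: Sequence[str]) -> int:
    # standard two-row DP; used only when edlib rejects the input
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        curr = [i]
        for j, cb in enumerate(b, 1):
            curr.append(
                min(prev[j] + 1, curr[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = curr
    return prev[-1]


def _levenshtein(a: Sequence[str], b: Sequence[str]) -> int:
    try:
        return edlib.align(list(a), list(b), task="distance", mode="NW")[
            "editDistance"
        ]
    except (ValueError, TypeError):  # e.g. alphabet too large for edlib
        return _levenshtein_dp(a, b)


def _check_nonempty(*paths: ScanPath) -> None:
    for p in paths:
        if len(p.labels) == 0:  # unreachable for valid ScanPath; belt-and-braces
            raise EmptyScanPathError(f"scan path {p.id!r} is empty")


def jaccard_similarity(a: ScanPath, b: ScanPath) -> float:
    """Jaccard coefficient similarity of the two paths' distinct-AOI sets.

    Symmetric, in [0, 1]; equals 1 iff both paths visited exactly the same
    AOIs (in any order), 0 iff they share none.
    """
    _check_nonempty(a, b)
    sa, sb = a.aoi_set, b.aoi_set
    return len(sa & sb) / len(sa | sb)


def string_edit_distance(a: ScanPath, b: ScanPath) -> EditDistanceResult:
    """Unit-cost Levenshtein distance between the two label sequences.

    Returns the minimal operation count together with the length of the
    longer sequence. Symmetric in its arguments.
    """
    _check_nonempty(a, b)
    dist = _levenshtein(a.labels, b.labels)
    return EditDistanceResult(distance=dist, norm_length=max(len(a), len(b)))


def string_edit_similarity(a: ScanPath, b: ScanPath) -> float:
    """Normalized string-edit similarity ``1 − d/n``; order-sensitive."""
    return string_edit_distance(a, b).similarity


METRIC_FUNCTIONS = {
    "jaccard": jaccard_similarity,
    "string_edit": string_edit_similarity,
}


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise similarities for one metric over a set of scan paths."""

    ids: tuple[str, ...]
    values: np.ndarray  # square, symmetric, unit diagonal, entries in [0, 1]
    metric: Metric

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} ids")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.ids)

    def pair_mean(self) -> float:
        """Mean similarity over the n(n−1)/2 unordered distinct pairs."""
        iu = np.triu_indices(self.n, k=1)
        return float(self.values[iu].mean())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_csv(self, path) -> None:
        """Write as a square CSV with id header row and column."""
        self.to_dataframe().to_csv(path, index_label="id")


def pairwise_matrix(paths: Sequence[ScanPath], metric: Metric) -> SimilarityMatrix:
    """All-pairs similarity matrix for one metric.

    Requires at least two scan paths with unique ids; the id order of the
    input is preserved in the matrix.
    """
    if len(paths) < 2:
        raise ValueError(f"need at least 2 scan paths, got {len(paths)}")
    ids = [p.id for p in paths]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate scan path ids: {sorted(dupes)}")
    if metric not in METRIC_FUNCTIONS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {sorted(METRIC_FUNCTIONS)}")
    fn = METRIC_FUNCTIONS[metric]
    n = len(paths)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fn(paths[i], paths[j])
    return SimilarityMatrix(ids=tuple(ids), values=values, metric=metric)
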