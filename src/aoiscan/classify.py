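"""Four-quadrant classification of scan paths by their average similarities.

Each scan path is summarized by two coordinates: its mean string-edit
similarity to every other path, and its mean Jaccard similarity to every
other path (self-similarity excluded). The population supplies its own
thresholds — the average of each metric over all unordered distinct pairs —
so "high" and "low" similarity are defined by the observed scanning
behavior rather than by a subjective cutoff. A path at or above the
threshold on a metric counts as HIGH on that metric (ties go to HIGH); the
two flags select one of four quadrants:

====================  =========================================================
HIGH_SE_HIGH_J        Observed similar information using similar patterns
HIGH_SE_LOW_J         Observed some similar information using similar patterns
LOW_SE_HIGH_J         Observed similar information using different patterns
LOW_SE_LOW_J          Observed different information using different patterns
====================  =========================================================

Because each pair contributes symmetrically, the mean of the per-path means
equals the pair-average threshold exactly — a useful internal consistency
check.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ScanPath
from .similarity import SimilarityMatrix, pairwise_matrix

__all__ = [
    "Quadrant",
    "Thresholds",
    "PathClassification",
    "ClassificationReport",
    "per_path_means",
    "compute_thresholds",
    "classify",
]


class Quadrant(enum.Enum):
    """The four similarity categories, keyed by (string-edit, Jaccard) flags."""

    HIGH_SE_HIGH_J = "Observed similar information using similar patterns"
    HIGH_SE_LOW_J = "Observed some similar information using similar patterns"
    LOW_SE_HIGH_J = "Observed similar information using different patterns"
    LOW_SE_LOW_J = "Observed different information using different patterns"

    @classmethod
    def from_flags(cls, high_se: bool, high_j: bool) -> "Quadrant":
        return {
            (True, True): cls.HIGH_SE_HIGH_J,
            (True, False): cls.HIGH_SE_LOW_J,
            (False, True): cls.LOW_SE_HIGH_J,
            (False, False): cls.LOW_SE_LOW_J,
        }[(high_se, high_j)]


@dataclass(frozen=True)
class Thresholds:
    """Population-average similarity per metric, used as the HIGH/LOW cutoffs."""

    string_edit_mean: float
    jaccard_mean: float


@dataclass(frozen=True)
class PathClassification:
    id: str
    string_edit_mean: float
    jaccard_mean: float
    quadrant: Quadrant


@dataclass(frozen=True)
class ClassificationReport:
    """Per-path mean similarities, the thresholds, and the quadrant assignments."""

    paths: tuple[PathClassification, ...]
    thresholds: Thresholds
    n_paths: int

    @property
    def quadrant_counts(self) -> dict[str, int]:
        counts = {q.name: 0 for q in Quadrant}
        for p in self.paths:
            counts[p.quadrant.name] += 1
        return counts

    def quadrant_of(self, id: str) -> Quadrant:
        for p in self.paths:
            if p.id == id:
                return p.quadrant
        raise KeyError(id)

    def to_dict(self) -> dict:
        return {
            "n_paths": self.n_paths,
            "thresholds": {
                "string_edit_mean": self.thresholds.string_edit_mean,
                "jaccard_mean": self.thresholds.jaccard_mean,
            },
            "paths": [
                {
                    "id": p.id,
                    "string_edit_mean": p.string_edit_mean,
                    "jaccard_mean": p.jaccard_mean,
                    "quadrant": p.quadrant.name,
                    "quadrant_description": p.quadrant.value,
                }
                for p in self.paths
            ],
            "quadrant_counts": self.quadrant_counts,
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    def to_dataframe(self) -> pd.DataFrame:
        """Flat per-path table: id, both means, quadrant name and description."""
        return pd.DataFrame(
            {
                "id": [p.id for p in self.paths],
                "string_edit_mean": [p.string_edit_mean for p in self.paths],
                "jaccard_mean": [p.jaccard_mean for p in self.paths],
                "quadrant": [p.quadrant.name for p in self.paths],
                "quadrant_description": [p.quadrant.value for p in self.paths],
            }
        )


def per_path_means(matrix: SimilarityMatrix) -> dict[str, float]:
    """Mean similarity of each path to all *other* paths (diagonal excluded)."""
    if matrix.n < 2:
        raise ValueError("per-path means require at least 2 scan paths")
    v = matrix.values
    n = matrix.n
    means = (v.sum(axis=1) - np.diag(v)) / (n - 1)
    return {i: float(m) for i, m in zip(matrix.ids, means)}


def compute_thresholds(
    se_matrix: SimilarityMatrix, j_matrix: SimilarityMatrix
) -> Thresholds:
    """Pair-average thresholds from matched string-edit and Jaccard matrices."""
    if se_matrix.ids != j_matrix.ids:
        raise ValueError("similarity matrices have mismatched ids or ordering")
    if se_matrix.n < 2:
        raise ValueError("thresholds require at least 2 scan paths")
    return Thresholds(
        string_edit_mean=se_matrix.pair_mean(),
        jaccard_mean=j_matrix.pair_mean(),
    )


def classify(paths: Sequence[ScanPath]) -> ClassificationReport:
    """Run the full two-metric classification over a set of scan paths.

    Builds both pairwise matrices, derives the per-path means and pair-average
    thresholds, and assigns each path a quadrant (HIGH on a metric iff its
    mean is >= the threshold). With only two paths both are trivially
    HIGH/HIGH (each path's single similarity is also the threshold); a
    warning flags that degenerate case.
    """
    if len(paths) < 2:
        raise ValueError(f"classification needs at least 2 scan paths, got {len(paths)}")
    if len(paths) == 2:
        warnings.warn(
            "classification of exactly 2 scan paths is uninformative: both "
            "paths equal the thresholds and fall in the HIGH/HIGH quadrant",
            stacklevel=2,
        )
    se = pairwise_matrix(paths, "string_edit")
    jc = pairwise_matrix(paths, "jaccard")
    thresholds = compute_thresholds(se, jc)
    se_means = per_path_means(se)
    j_means = per_path_means(jc)
    records = tuple(
        PathClassification(
            id=p.id,
            string_edit_mean=se_means[p.id],
            jaccard_mean=j_means[p.id],
            quadrant=Quadrant.from_flags(
                se_means[p.id] >= thresholds.string_edit_mean,
                j_means[p.id] >= thresholds.jaccard_mean,
            ),
        )
        for p in paths
    )
    return ClassificationReport(
        paths=records, thresholds=thresholds, n_paths=len(paths)
    )
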