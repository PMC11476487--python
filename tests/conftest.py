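"""Shared fixtures and the independent edit-distance oracle."""

from __future__ import annotations

from functools import lru_cache

import pytest
from hypothesis import HealthCheck, settings

from aoiscan import ScanPath, make_scanpath

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def sp(letters: str, id: str | None = None) -> ScanPath:
    """Build a ScanPath from a compact single-letter string."""
    return make_scanpath(id or letters, list(letters))


def edit_distance_oracle(a: str | tuple, b: str | tuple) -> int:
    """Reference Levenshtein distance from the recursive definition.

    Independent of the package's implementation: straight memoized recursion
    over prefix lengths with unit-cost insert/delete/substitute.
    """

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return d(len(a), len(b))


def collapsed_sequences(alphabet: str, max_len: int) -> list[str]:
    """All sequences over *alphabet* up to *max_len* with no adjacent repeats."""
    out: list[str] = []
    frontier = [c for c in alphabet]
    for _ in range(max_len):
        out.extend(frontier)
        frontier = [s + c for s in frontier for c in alphabet if c != s[-1]]
    return out


@pytest.fixture
def scanpath_factory():
    return sp
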