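"""Domain types for AOI scan paths.

A *scan path* is the time-ordered sequence of areas of interest (AOIs) a
participant fixated, encoded as a sequence of AOI labels. Before any
comparison, runs of consecutive identical labels are collapsed to a single
label (``AAABC`` becomes ``ABC``): a dwell on one AOI counts as a single
visit regardless of how many fixations it comprised. The collapsed,
identified sequence is the unit of comparison throughout this package.

Labels are case-sensitive, non-empty tokens without whitespace. Single
letters are the common convention (each AOI assigned one letter), but
multi-character tokens such as ``Runway`` are fully supported; files and
the CLI separate them with an explicit delimiter (default ``|``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "ScanPathError",
    "EmptyScanPathError",
    "InvalidLabelError",
    "ScanPath",
    "validate_label",
    "collapse_consecutive",
    "make_scanpath",
    "aoi_set",
    "tokenize",
]

#: default token delimiter in files and CLI arguments
DEFAULT_DELIMITER = "|"


class ScanPathError(ValueError):
    """Base error for invalid scan-path input."""


class EmptyScanPathError(ScanPathError):
    """Raised when a scan path would contain no AOI labels."""


class InvalidLabelError(ScanPathError):
    """Raised for AOI labels that are empty or contain whitespace/delimiters."""


def validate_label(token: str, delimiter: str = DEFAULT_DELIMITER) -> str:
    """Validate a single AOI label and return it unchanged.

    A label must be a non-empty string with no whitespace and no occurrence
    of the token delimiter. Comparison elsewhere is exact and case-sensitive.
    """
    if not isinstance(token, str) or token == "":
        raise InvalidLabelError(f"AOI label must be a non-empty string, got {token!r}")
    if any(ch.isspace() for ch in token):
        raise InvalidLabelError(f"AOI label may not contain whitespace: {token!r}")
    if delimiter and delimiter in token:
        raise InvalidLabelError(
            f"AOI label may not contain the delimiter {delimiter!r}: {token!r}"
        )
    return token


def collapse_consecutive(labels: Iterable[str]) -> list[str]:
    """Collapse runs of consecutive identical labels to a single label.

    ``["A", "A", "A", "B", "C"]`` becomes ``["A", "B", "C"]``; non-adjacent
    repeats are kept (``ABBA`` -> ``ABA``). Idempotent. Raises
    :class:`EmptyScanPathError` on empty input.
    """
    out: list[str] = []
    for lab in labels:
        if not out or out[-1] != lab:
            out.append(lab)
    if not out:
        raise EmptyScanPathError("scan path contains no AOI labels")
    return out


@dataclass(frozen=True)
class ScanPath:
    """An identified, collapsed, ordered sequence of AOI labels.

    Construct via :func:`make_scanpath`, which validates labels and collapses
    consecutive duplicates; direct construction enforces the same invariants.
    """

    id: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise EmptyScanPathError(f"scan path {self.id!r} has no labels")
        for a, b in zip(self.labels, self.labels[1:]):
            if a == b:
                raise ScanPathError(
                    f"scan path {self.id!r} has consecutive duplicate label {a!r}; "
                    "use make_scanpath() to collapse"
                )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def aoi_set(self) -> frozenset[str]:
        """The distinct AOI labels visited, order discarded."""
        return frozenset(self.labels)

    def to_text(self, delimiter: str = DEFAULT_DELIMITER) -> str:
        """Render the sequence as text.

        Uses the compact single-letter form (``LATITS``) when every token is
        one character; otherwise tokens are joined with *delimiter*.
        """
        if all(len(t) == 1 for t in self.labels):
            return "".join(self.labels)
        return delimiter.join(self.labels)


def make_scanpath(id: str, labels: Sequence[str]) -> ScanPath:
    """Build a :class:`ScanPath`: validate labels, collapse runs, keep *id*.

    Raises :class:`EmptyScanPathError` for an empty label list and
    :class:`InvalidLabelError` for malformed labels.
    """
    if len(labels) == 0:
        raise EmptyScanPathError(f"scan path {id!r} has no labels")
    validated = [validate_label(t) for t in labels]
    return ScanPath(id=id, labels=tuple(collapse_consecutive(validated)))


def aoi_set(path: ScanPath) -> frozenset[str]:
    """The set of distinct AOIs in *path* — the operand of Jaccard similarity."""
    return path.aoi_set


def tokenize(text: str, delimiter: str = DEFAULT_DELIMITER) -> list[str]:
    """Split a sequence string into AOI tokens.

    If *delimiter* occurs in *text*, the string is split on it
    (``"Strips|BRITE|Runway"`` -> three tokens); otherwise each character is
    one single-letter token (``"LATITS"`` -> six tokens).
    """
    if text == "":
        raise EmptyScanPathError("empty sequence string")
    if delimiter and delimiter in text:
        return [t for t in text.split(delimiter) if t != ""]
    return list(text)
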