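"""In-memory containers: Tableau, SSE distance matrix, StructureEntry.

A tableau for a structure with *n* SSEs is conceptually an n×n symmetric
matrix of two-character orientation codes whose diagonal instead carries the
SSE type of each row/column.  Only the strict lower triangle is stored;
lookups are symmetric.  The companion distance matrix holds the Euclidean
distance in Ångströms between the Cα centroids of each SSE pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .codes import validate_code, validate_sse_type
from .errors import ValidationError

__all__ = ["Tableau", "StructureEntry", "as_distance_matrix"]


class Tableau:
    """Symmetric matrix of orientation codes with SSE types on the diagonal.

    Parameters
    ----------
    types:
        SSE type codes (``e``/``xa``/``xi``/``xg``), one per SSE, in
        N- to C-terminal order.
    codes:
        Strict lower triangle as a nested list: ``codes[i]`` has length
        ``i`` and holds the orientation codes for pairs (i, 0) .. (i, i−1),
        using 0-based indices.
    """

    __slots__ = ("_types", "_codes")

    def __init__(self, types: Sequence[str], codes: Sequence[Sequence[str]]):
        types = [validate_sse_type(t) for t in types]
        n = len(types)
        if n < 1:
            raise ValidationError("a tableau needs at least one SSE")
        codes = [list(row) for row in codes]
        if len(codes) != n:
            raise ValidationError(
                f"expected {n} lower-triangle rows, got {len(codes)}"
            )
        for i, row in enumerate(codes):
            if len(row) != i:
                raise ValidationError(
                    f"lower-triangle row {i} must have {i} codes, has {len(row)}"
                )
            for c in row:
                validate_code(c)
        self._types = types
        self._codes = codes

    @property
    def n(self) -> int:
        return len(self._types)

    @property
    def types(self) -> list[str]:
        return list(self._types)

    def type(self, i: int) -> str:
        """SSE type code on the diagonal at 0-based index *i*."""
        return self._types[i]

    def code(self, i: int, j: int) -> str:
        """Orientation code for the pair (i, j), 0-based; symmetric lookup."""
        if i == j:
            raise ValidationError(
                "the diagonal holds SSE types, not orientation codes; "
                "use Tableau.type(i)"
            )
        if not (0 <= i < self.n and 0 <= j < self.n):
            raise ValidationError(f"index out of range: ({i}, {j}) for n={self.n}")
        if i < j:
            i, j = j, i
        return self._codes[i][j]

    def lower_rows(self) -> list[list[str]]:
        """Copy of the strict lower triangle, row by row."""
        return [list(row) for row in self._codes]

    def restrict(self, indices: Sequence[int]) -> "Tableau":
        """Sub-tableau over the given 0-based SSE indices (kept in order)."""
        idx = list(indices)
        if len(idx) != len(set(idx)):
            raise ValidationError("restriction indices must be distinct")
        types = [self._types[i] for i in idx]
        codes = [[self.code(idx[i], idx[j]) for j in range(i)] for i in range(len(idx))]
        return Tableau(types, codes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Tableau):
            return NotImplemented
        return self._types == other._types and self._codes == other._codes

    def __repr__(self) -> str:
        return f"Tableau(n={self.n}, types={self._types})"


def as_distance_matrix(d, n: int | None = None) -> np.ndarray:
    """Validate and return an SSE centroid distance matrix as float ndarray.

    Requires a square symmetric matrix with non-negative entries and a zero
    diagonal (Ångströms).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError(f"distance matrix must be square, got shape {d.shape}")
    if n is not None and d.shape[0] != n:
        raise ValidationError(
            f"distance matrix dimension {d.shape[0]} does not match tableau n={n}"
        )
    if not np.all(np.isfinite(d)):
        raise ValidationError("distance matrix contains non-finite entries")
    if np.any(d < 0):
        raise ValidationError("distances must be non-negative")
    if np.any(np.abs(np.diag(d)) > 1e-9):
        raise ValidationError("distance matrix diagonal must be zero")
    if not np.allclose(d, d.T, atol=1e-6):
        raise ValidationError("distance matrix must be symmetric")
    return d


@dataclass
class StructureEntry:
    """A database/query entry: identifier, tableau and distance matrix."""

    id: str
    tableau: Tableau
    distances: np.ndarray = field(repr=False)

    def __post_init__(self):
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValidationError(
                f"entry id must be non-empty and contain no whitespace: {self.id!r}"
            )
        self.distances = as_distance_matrix(self.distances, n=self.tableau.n)

    @property
    def n(self) -> int:
        """Number of SSEs (tableau dimension)."""
        return self.tableau.n

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureEntry):
            return NotImplemented
        return (
            self.id == other.id
            and self.tableau == other.tableau
            and np.allclose(self.distances, other.distances, atol=1e-9)
        )
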