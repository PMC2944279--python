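"""Plain-text tableau + distance-matrix database: reader, writer, sorting.

Format, per entry:

    <id> <N>
    N lines of the lower-triangular tableau; line i (1-based) holds the SSE
      type code for SSE i followed by the orientation codes for pairs
      (i,1) .. (i,i−1);
    N lines of the lower-triangular distance matrix; line i holds
      d(i,1) .. d(i,i−1) followed by the diagonal 0.000 (3 decimals, Å);
    a blank line between consecutive entries.

Fields are whitespace-separated on read; the writer emits single spaces, so
write→read→write is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np

from .containers import StructureEntry, Tableau
from .errors import ParseError, ValidationError

__all__ = ["TableauDatabase", "write_db", "read_db", "sort_by_size"]

logger = logging.getLogger(__name__)


@dataclass
class TableauDatabase:
    """Ordered collection of StructureEntry with unique ids."""

    entries: list[StructureEntry] = field(default_factory=list)

    def __post_init__(self):
        self._index: dict[str, int] = {}
        for k, e in enumerate(self.entries):
            if e.id in self._index:
                raise ValidationError(f"duplicate entry id {e.id!r}")
            self._index[e.id] = k

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[StructureEntry]:
        return iter(self.entries)

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self._index

    def get(self, entry_id: str) -> StructureEntry:
        try:
            return self.entries[self._index[entry_id]]
        except KeyError:
            raise KeyError(f"no entry with id {entry_id!r}") from None

    def add(self, entry: StructureEntry) -> None:
        if entry.id in self._index:
            raise ValidationError(f"duplicate entry id {entry.id!r}")
        self._index[entry.id] = len(self.entries)
        self.entries.append(entry)


def write_db(db: TableauDatabase | Iterable[StructureEntry], sink: IO[str]) -> None:
    """Write a database in the canonical text format."""
    first = True
    for entry in db:
        if not first:
            sink.write("\n")
        first = False
        n = entry.n
        sink.write(f"{entry.id} {n}\n")
        tab = entry.tableau
        rows = tab.lower_rows()
        for i in range(n):
            sink.write(" ".join([tab.type(i)] + rows[i]) + "\n")
        for i in range(n):
            vals = [f"{entry.distances[i, j]:.3f}" for j in range(i)] + ["0.000"]
            sink.write(" ".join(vals) + "\n")


def read_db(source: IO[str] | Iterable[str], skip_bad: bool = False) -> TableauDatabase:
    """Parse a database from the canonical text format.

    Malformed entries raise :class:`ParseError` naming the offending line;
    with ``skip_bad=True`` they are logged and skipped instead (the parser
    resynchronizes at the next blank line).
    """
    lines = list(source)
    db = TableauDatabase()
    k = 0
    total = len(lines)

    def next_nonblank(k: int) -> int:
        while k < total and not lines[k].strip():
            k += 1
        return k

    while True:
        k = next_nonblank(k)
        if k >= total:
            break
        header_line = k
        try:
            entry, k = _parse_entry(lines, k)
            if entry.id in db:
                raise ParseError(f"duplicate entry id {entry.id!r}", line=header_line + 1)
            db.add(entry)
        except ParseError as exc:
            if not skip_bad:
                raise
            logger.warning("skipping bad entry at line %d: %s", header_line + 1, exc)
            # resynchronize at the next blank line
            k = header_line
            while k < total and lines[k].strip():
                k += 1
    return db


def _parse_entry(lines: list[str], k: int) -> tuple[StructureEntry, int]:
    header = lines[k].split()
    if len(header) != 2:
        raise ParseError(f"expected '<id> <N>' header, got {lines[k].rstrip()!r}", line=k + 1)
    entry_id, n_str = header
    try:
        n = int(n_str)
    except ValueError:
        raise ParseError(f"entry size {n_str!r} is not an integer", line=k + 1) from None
    if n < 1:
        raise ParseError(f"entry size must be ≥ 1, got {n}", line=k + 1)
    if k + 1 + 2 * n > len(lines):
        raise ParseError(
            f"entry {entry_id!r} truncated: expected {2 * n} matrix lines", line=k + 1
        )

    types: list[str] = []
    codes: list[list[str]] = []
    for i in range(n):
        ln = k + 1 + i
        fields = lines[ln].split()
        if len(fields) != i + 1:
            raise ParseError(
                f"tableau row {i + 1} must have {i + 1} fields, got {len(fields)}",
                line=ln + 1,
            )
        types.append(fields[0])
        codes.append(fields[1:])

    d = np.zeros((n, n))
    for i in range(n):
        ln = k + 1 + n + i
        fields = lines[ln].split()
        if len(fields) != i + 1:
            raise ParseError(
                f"distance row {i + 1} must have {i + 1} fields, got {len(fields)}",
                line=ln + 1,
            )
        for j, f in enumerate(fields):
            try:
                val = float(f)
            except ValueError:
                raise ParseError(f"non-numeric distance {f!r}", line=ln + 1) from None
            if j == i:
                if abs(val) > 1e-9:
                    raise ParseError(
                        f"diagonal distance must be 0, got {f!r}", line=ln + 1
                    )
            else:
                d[i, j] = d[j, i] = val

    try:
        tableau = Tableau(types, codes)
        entry = StructureEntry(id=entry_id, tableau=tableau, distances=d)
    except ValidationError as exc:
        raise ParseError(str(exc), line=k + 1) from exc

    k_end = k + 1 + 2 * n
    if k_end < len(lines) and lines[k_end].strip():
        raise ParseError(
            f"expected blank line after entry {entry_id!r}", line=k_end + 1
        )
    return entry, k_end


def sort_by_size(db: TableauDatabase) -> TableauDatabase:
    """Entries ordered by ascending SSE count, ties broken by id.

    A scheduling aid for batch searches over many structures; search
    results do not depend on database order.
    """
    return TableauDatabase(sorted(db.entries, key=lambda e: (e.n, e.id)))
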