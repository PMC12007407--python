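"""Pedigrees of breeding lines: reading, validation, ordering, tracing, summaries.

A pedigree is a list of records (id, parent1, parent2, crossing_year) held in
topological order: every known parent precedes its offspring.  Input file
order is never trusted; the order is recomputed on construction.  Parents that
are referenced but never listed as records are materialized as founders, which
is routine in breeding pedigrees that cite base-population clones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Tokens (case-insensitive) treated as "parent unknown" when reading files.
DEFAULT_UNKNOWN_TOKENS = ("", "0", "na", "nan", "unknown", "none", ".")

#: Sentinel used internally for an unknown parent.
UNKNOWN = None


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, ...)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One line of a pedigree: an individual and its (possibly unknown) parents."""

    id: str
    parent1: Optional[str] = None
    parent2: Optional[str] = None
    crossing_year: Optional[int] = None

    def __post_init__(self):
        if not self.id:
            raise PedigreeError("pedigree record with empty id")
        if self.parent1 == self.id or self.parent2 == self.id:
            raise PedigreeError(f"record {self.id!r} lists itself as a parent")


@dataclass
class CompletenessSummary:
    """Fractional generation-count completeness of a pedigree.

    ``per_id[i]`` follows the recursion C(i) = sum over known parents p of
    (1 + C(p)) / 2, so an individual with both parents known (and those
    parents founders) has completeness 1, and one with all four grandparents
    known has completeness 2.  Founders score 0.
    """

    per_id: dict
    mean: float
    max: float
    frac_unknown_parents: float


class Pedigree:
    """Topologically ordered pedigree with integer-indexed parent links.

    Attributes
    ----------
    records : list[PedigreeRecord]
        Records in topological order (parents before offspring).
    index : dict[str, int]
        id -> position in ``records``.
    sire, dam : ndarray[int]
        Parent positions, -1 for unknown.
    """

    def __init__(self, records: Iterable[PedigreeRecord]):
        records = list(records)
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise PedigreeError(f"duplicate pedigree id {dup!r}")

        # Materialize referenced-but-absent parents as founders.
        known = set(ids)
        implied = []
        for r in records:
            for p in (r.parent1, r.parent2):
                if p is not None and p not in known:
                    known.add(p)
                    implied.append(p)
        if implied:
            log.info("materialized %d referenced parents as founders: %s%s",
                     len(implied), ", ".join(implied[:5]),
                     "..." if len(implied) > 5 else "")
            records = [PedigreeRecord(p) for p in implied] + records

        self.records = self._toposort(records)
        self.index = {r.id: i for i, r in enumerate(self.records)}
        n = len(self.records)
        self.sire = np.full(n, -1, dtype=np.int64)
        self.dam = np.full(n, -1, dtype=np.int64)
        for i, r in enumerate(self.records):
            if r.parent1 is not None:
                self.sire[i] = self.index[r.parent1]
            if r.parent2 is not None:
                self.dam[i] = self.index[r.parent2]
        self._check_years()

    # ------------------------------------------------------------------
    @staticmethod
    def _toposort(records: Sequence[PedigreeRecord]) -> list:
        """Kahn's algorithm; on failure, report one cycle explicitly."""
        idx = {r.id: i for i, r in enumerate(records)}
        n = len(records)
        children = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i, r in enumerate(records):
            for p in (r.parent1, r.parent2):
                if p is not None:
                    children[idx[p]].append(i)
                    indeg[i] += 1
        # min-index selection keeps an already topologically ordered input
        # unchanged and is deterministic otherwise
        import heapq
        order = []
        heap = [i for i in range(n) if indeg[i] == 0]
        heapq.heapify(heap)
        while heap:
            i = heapq.heappop(heap)
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(heap, c)
        if len(order) < n:
            cycle = Pedigree._find_cycle(records, idx)
            raise PedigreeError(
                "pedigree contains a cycle: " + " -> ".join(cycle))
        return [records[i] for i in order]

    @staticmethod
    def _find_cycle(records, idx) -> list:
        color = {}  # 0 visiting, 1 done

        def parents(i):
            r = records[i]
            return [idx[p] for p in (r.parent1, r.parent2) if p is not None]

        path = []

        def dfs(i):
            color[i] = 0
            path.append(i)
            for p in parents(i):
                if color.get(p) == 0:
                    k = path.index(p)
                    return [records[j].id for j in path[k:]] + [records[p].id]
                if p not in color:
                    res = dfs(p)
                    if res:
                        return res
            path.pop()
            color[i] = 1
            return None

        for i in range(len(records)):
            if i not in color:
                res = dfs(i)
                if res:
                    return res
        return []  # pragma: no cover - only called when a cycle exists

    def _check_years(self):
        for i, r in enumerate(self.records):
            if r.crossing_year is None:
                continue
            for p in (self.sire[i], self.dam[i]):
                if p >= 0:
                    py = self.records[p].crossing_year
                    if py is not None and r.crossing_year < py:
                        warnings.warn(
                            f"crossing_year of {r.id!r} ({r.crossing_year}) "
                            f"precedes parent {self.records[p].id!r} ({py})")

    # ------------------------------------------------------------------
    def __len__(self):
        return len(self.records)

    def __contains__(self, id_):
        return id_ in self.index

    @property
    def ids(self) -> list:
        return [r.id for r in self.records]

    def trace(self, focal_ids) -> "Pedigree":
        """Sub-pedigree of ``focal_ids`` and all their ancestors."""
        focal = list(focal_ids)
        missing = [f for f in focal if f not in self.index]
        if missing:
            raise PedigreeError(f"focal ids not in pedigree: {missing[:5]}")
        keep = np.zeros(len(self), dtype=bool)
        stack = [self.index[f] for f in focal]
        while stack:
            i = stack.pop()
            if keep[i]:
                continue
            keep[i] = True
            for p in (self.sire[i], self.dam[i]):
                if p >= 0 and not keep[p]:
                    stack.append(p)
        return Pedigree([r for i, r in enumerate(self.records) if keep[i]])

    def completeness(self) -> CompletenessSummary:
        """Fractional known-generation count per individual (see class docs)."""
        n = len(self)
        c = np.zeros(n)
        unknown_any = np.zeros(n, dtype=bool)
        for i in range(n):
            s, d = self.sire[i], self.dam[i]
            val = 0.0
            if s >= 0:
                val += (1.0 + c[s]) / 2.0
            if d >= 0:
                val += (1.0 + c[d]) / 2.0
            c[i] = val
            unknown_any[i] = (s < 0) or (d < 0)
        return CompletenessSummary(
            per_id={r.id: c[i] for i, r in enumerate(self.records)},
            mean=float(c.mean()),
            max=float(c.max()),
            frac_unknown_parents=float(unknown_any.mean()),
        )

    def breeding_cycles(self) -> dict:
        """Partition ids by crossing year (one breeding cycle per year)."""
        cycles: dict = {}
        n_missing = 0
        for r in self.records:
            if r.crossing_year is None:
                n_missing += 1
                continue
            cycles.setdefault(int(r.crossing_year), set()).add(r.id)
        if not cycles:
            raise PedigreeError("no record has a crossing_year")
        if n_missing:
            warnings.warn(f"{n_missing} records lack a crossing_year and were "
                          "excluded from breeding cycles")
        return dict(sorted(cycles.items()))

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "parent1": [r.parent1 if r.parent1 is not None else ""
                            for r in self.records],
                "parent2": [r.parent2 if r.parent2 is not None else ""
                            for r in self.records],
                "crossing_year": [r.crossing_year for r in self.records],
            }
        )

    def write(self, path):
        """Write the (ordered) pedigree in the standard CSV dialect."""
        self.to_frame().to_csv(path, index=False)


def read_pedigree(
    path,
    dialect: Optional[Mapping[str, str]] = None,
    unknown_tokens: Sequence[str] = DEFAULT_UNKNOWN_TOKENS,
) -> Pedigree:
    """Read a pedigree CSV (columns id, parent1, parent2[, crossing_year]).

    ``dialect`` maps the standard column names to the file's column names,
    e.g. ``{"id": "Clone", "parent1": "Mother"}``.  Unknown-parent tokens
    (``""``, ``"0"``, ``"NA"``, ... case-insensitive) are normalized to
    unknown.  Referenced parents missing from the file are inserted as
    founder records.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {"id": "id", "parent1": "parent1", "parent2": "parent2",
              "crossing_year": "crossing_year"}
    if dialect:
        colmap.update(dialect)
    for key in ("id", "parent1", "parent2"):
        if colmap[key] not in df.columns:
            raise PedigreeError(f"pedigree file lacks column {colmap[key]!r}")
    toks = {t.lower() for t in unknown_tokens}

    def norm(v: str):
        v = v.strip()
        return None if v.lower() in toks else v

    has_year = colmap["crossing_year"] in df.columns
    records = []
    for _, row in df.iterrows():
        year = None
        if has_year:
            raw = row[colmap["crossing_year"]].strip()
            if raw and raw.lower() not in toks:
                year = int(float(raw))
        records.append(PedigreeRecord(
            id=row[colmap["id"]].strip(),
            parent1=norm(row[colmap["parent1"]]),
            parent2=norm(row[colmap["parent2"]]),
            crossing_year=year,
        ))
    return Pedigree(records)


def trace(pedigree: Pedigree, focal_ids) -> Pedigree:
    """Functional alias for :meth:`Pedigree.trace`."""
    return pedigree.trace(focal_ids)


def completeness(pedigree: Pedigree) -> CompletenessSummary:
    """Functional alias for :meth:`Pedigree.completeness`."""
    return pedigree.completeness()


def breeding_cycles(pedigree: Pedigree) -> dict:
    """Functional alias for :meth:`Pedigree.breeding_cycles`."""
    return pedigree.breeding_cycles()
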