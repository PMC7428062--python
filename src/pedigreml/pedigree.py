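"""Pedigree handling and the additive relationship matrix.

A pedigree links individuals to their sire and dam; unknown parents are
treated as draws from an unrelated, non-inbred base population.  The
expected additive relationship matrix A (numerator relationship matrix)
is what an animal model conditions on: ``Cov(breeding values) = A * V_A``.
Its diagonal is ``1 + F_i`` where ``F_i`` is the inbreeding coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for an unknown parent.  On disk "", "0" and "NA" all mean unknown.
UNKNOWN = "0"

_MISSING_TOKENS = {"", "0", "NA", "NaN", "nan", "<NA>"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class PedigreeEntry:
    individual: str
    sire: str = UNKNOWN
    dam: str = UNKNOWN
    cohort: int | None = None

    @property
    def is_founder(self) -> bool:
        return self.sire == UNKNOWN and self.dam == UNKNOWN


@dataclass
class Pedigree:
    """Ordered collection of pedigree entries.

    Invariants: individual ids are unique, no id equals the UNKNOWN
    sentinel, the parent graph is acyclic, and every named parent has an
    entry (parents without rows are auto-promoted to founders on read).
    """

    entries: list[PedigreeEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.individual in _MISSING_TOKENS:
                raise PedigreeError(f"invalid individual id {e.individual!r}")
            if e.individual in seen:
                raise PedigreeError(f"duplicate individual id: {e.individual}")
            if e.individual in (e.sire, e.dam):
                raise PedigreeError(
                    f"individual is its own parent: {e.individual}"
                )
            seen.add(e.individual)
        for e in self.entries:
            for parent in (e.sire, e.dam):
                if parent != UNKNOWN and parent not in seen:
                    raise PedigreeError(
                        f"parent {parent} of {e.individual} has no entry; "
                        "use read_pedigree/add_founders to promote founders"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e.individual for e in self.entries]

    def entry(self, individual: str) -> PedigreeEntry:
        return self._index()[individual]

    def _index(self) -> dict[str, PedigreeEntry]:
        return {e.individual: e for e in self.entries}

    def founders(self) -> list[str]:
        return [e.individual for e in self.entries if e.is_founder]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [e.individual for e in self.entries],
                "sire": [e.sire for e in self.entries],
                "dam": [e.dam for e in self.entries],
                "cohort": [e.cohort for e in self.entries],
            }
        )


def _normalise_parent(token: object) -> str:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return UNKNOWN
    s = str(token).strip()
    return UNKNOWN if s in _MISSING_TOKENS else s


def _promote_founders(rows: list[tuple[str, str, str, int | None]]) -> list[PedigreeEntry]:
    ids = {r[0] for r in rows}
    entries: list[PedigreeEntry] = []
    promoted: list[str] = []
    for iid, sire, dam, cohort in rows:
        for parent in (sire, dam):
            if parent != UNKNOWN and parent not in ids:
                entries.append(PedigreeEntry(parent))
                ids.add(parent)
                promoted.append(parent)
    if promoted:
        logger.info("promoted %d parents without rows to founders: %s",
                    len(promoted), ", ".join(promoted[:10]))
    entries.extend(
        PedigreeEntry(iid, sire, dam, cohort) for iid, sire, dam, cohort in rows
    )
    return entries


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV with header ``id,sire,dam[,cohort]``.

    Empty fields, ``0`` and ``NA`` denote an unknown parent.  Parents
    that are named but have no row of their own are promoted to founder
    entries (logged).  Duplicate ids and self-parentage are errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(
            f"pedigree file must have columns id,sire,dam; got {list(df.columns)}"
        )
    rows = []
    for _, r in df.iterrows():
        cohort = None
        if "cohort" in df.columns and str(r["cohort"]).strip() not in _MISSING_TOKENS:
            cohort = int(float(r["cohort"]))
        rows.append(
            (str(r["id"]).strip(), _normalise_parent(r["sire"]),
             _normalise_parent(r["dam"]), cohort)
        )
    return topological_sort(Pedigree(_promote_founders(rows)))


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    """Write a pedigree CSV; unknown parents are written as ``0``."""
    df = ped.to_frame()
    df["cohort"] = ["" if c is None else str(c) for c in df["cohort"]]
    df.to_csv(path, index=False)


def topological_sort(ped: Pedigree) -> Pedigree:
    """Reorder entries so every parent precedes all of its offspring.

    The sort is stable: individuals not constrained by ancestry keep
    their input order.  A cycle raises ``PedigreeError`` listing the ids
    on one cycle.
    """
    index = {e.individual: e for e in ped.entries}
    order = {e.individual: i for i, e in enumerate(ped.entries)}
    placed: set[str] = set()
    result: list[PedigreeEntry] = []

    # Kahn-style with a stable scan: repeatedly emit, in input order, every
    # individual whose parents are already placed.  Termination failure
    # implies a cycle, which we then locate by walking parent pointers.
    remaining = list(ped.entries)
    while remaining:
        emitted = [
            e for e in remaining
            if all(p == UNKNOWN or p in placed for p in (e.sire, e.dam))
        ]
        if not emitted:
            cycle = _find_cycle(remaining, index)
            raise PedigreeError(
                "pedigree contains a cycle: " + " -> ".join(cycle)
            )
        result.extend(sorted(emitted, key=lambda e: order[e.individual]))
        placed.update(e.individual for e in emitted)
        remaining = [e for e in remaining if e.individual not in placed]
    return Pedigree(result)


def _find_cycle(entries: list[PedigreeEntry], index) -> list[str]:
    stuck = {e.individual for e in entries}
    start = entries[0].individual
    seen: list[str] = []
    node = start
    while node not in seen:
        seen.append(node)
        e = index[node]
        node = next(
            p for p in (e.sire, e.dam) if p != UNKNOWN and p in stuck
        )
    return seen[seen.index(node):] + [node]


@dataclass
class RelationshipMatrix:
    """Expected additive relatedness among the individuals of a pedigree."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match ids")

    def submatrix(self, ids: list[str]) -> np.ndarray:
        """A restricted to ``ids`` — the correct marginal covariance."""
        pos = {iid: i for i, iid in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids])
        return self.values[np.ix_(idx, idx)]

    def inbreeding(self) -> dict[str, float]:
        return {iid: self.values[i, i] - 1.0 for i, iid in enumerate(self.ids)}


def additive_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Build A by the tabular method.

    Processing parents before offspring:
    ``a_ii = 1 + 0.5 * a(sire, dam)`` and, for earlier j,
    ``a_ij = 0.5 * (a(j, sire) + a(j, dam))`` where any UNKNOWN parent
    contributes zero.  Founders are unrelated and non-inbred.
    """
    ped = topological_sort(ped)
    ids = ped.ids
    pos = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for i, e in enumerate(ped.entries):
        si = pos.get(e.sire, -1) if e.sire != UNKNOWN else -1
        di = pos.get(e.dam, -1) if e.dam != UNKNOWN else -1
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[:i, si]
        if di >= 0:
            row += 0.5 * A[:i, di]
        A[i, :i] = row
        A[:i, i] = row
    return RelationshipMatrix(ids, A)


def inbreeding(ped: Pedigree) -> dict[str, float]:
    """Inbreeding coefficients ``F_i = 0.5 * a(sire_i, dam_i)``.

    Zero for founders and for any individual with an unknown parent.
    Computed by memoised pairwise kinship, so it scales to pedigrees too
    large for the dense tabular A.
    """
    ped = topological_sort(ped)
    parents = {e.individual: (e.sire, e.dam) for e in ped.entries}
    depth: dict[str, int] = {}
    for e in ped.entries:
        depth[e.individual] = 1 + max(
            (depth[p] for p in (e.sire, e.dam) if p != UNKNOWN), default=0)
    memo: dict[tuple[str, str], float] = {}

    def kin(a: str, b: str) -> float:
        """Coefficient of kinship f(a, b); a_ij = 2 f(i, j)."""
        if a == UNKNOWN or b == UNKNOWN:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in memo:
            return memo[key]
        if a == b:
            s, d = parents[a]
            val = 0.5 * (1.0 + kin(s, d))
        else:
            # recurse through the deeper individual so the other is
            # never a descendant of it
            if depth[a] < depth[b]:
                a, b = b, a
            s, d = parents[a]
            val = 0.5 * (kin(s, b) + kin(d, b))
        memo[key] = val
        return val

    out = {}
    for e in ped.entries:
        out[e.individual] = kin(e.sire, e.dam) if not e.is_founder else 0.0
    return out
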