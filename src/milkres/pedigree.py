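"""Pedigree handling and the numerator relationship matrix.

A pedigree is a table of (animal, sire, dam) triples with ``0`` (or the
empty string / NaN) marking an unknown parent.  The additive (numerator)
relationship matrix **A** holds the expected additive-genetic relationship
between every pair of animals; its diagonal is 1 + F where F is the
animal's inbreeding coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNKNOWN = 0

__all__ = ["Pedigree", "PedigreeError", "build_A", "inbreeding_coefficients"]


class PedigreeError(ValueError):
    """Raised for cyclic, unsortable or otherwise invalid pedigrees."""


@dataclass
class Pedigree:
    """Topologically sorted animal–sire–dam triples.

    Parameters
    ----------
    animal, sire, dam
        Integer identifiers; ``0`` means unknown parent.  On construction
        the pedigree is validated (parents exist or are unknown, no animal
        is its own ancestor) and sorted so parents precede offspring.
    """

    animal: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.animal = np.asarray(self.animal, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if not (len(self.animal) == len(self.sire) == len(self.dam)):
            raise PedigreeError("animal/sire/dam columns differ in length")
        if len(np.unique(self.animal)) != len(self.animal):
            dup = pd.Series(self.animal)
            dup = dup[dup.duplicated()].iloc[0]
            raise PedigreeError(f"duplicate animal id {dup}")
        if np.any(self.animal == UNKNOWN):
            raise PedigreeError("0 is reserved for unknown parents")
        known = set(self.animal.tolist()) | {UNKNOWN}
        for name, col in (("sire", self.sire), ("dam", self.dam)):
            missing = set(col.tolist()) - known
            if missing:
                raise PedigreeError(f"{name} ids not in pedigree: {sorted(missing)[:5]}")
        self._topological_sort()
        self._index = {a: i for i, a in enumerate(self.animal.tolist())}

    def _topological_sort(self) -> None:
        """Kahn's algorithm over the parent→offspring DAG; detects cycles."""
        ids = self.animal
        pos = {a: i for i, a in enumerate(ids.tolist())}
        n = len(ids)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=int)
        for i in range(n):
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN:
                    children[pos[p]].append(i)
                    indeg[i] += 1
        order: list[int] = [i for i in range(n) if indeg[i] == 0]
        head = 0
        while head < len(order):
            i = order[head]
            head += 1
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
        if len(order) != n:
            cyc = sorted(ids[i] for i in range(n) if indeg[i] > 0)
            raise PedigreeError(f"pedigree contains a cycle involving animals {cyc[:6]}")
        order = np.asarray(order)
        self.animal = ids[order]
        self.sire = self.sire[order]
        self.dam = self.dam[order]

    # -- convenience ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.animal)

    def index_of(self, animals: Iterable[int]) -> np.ndarray:
        """Row indices (in sorted order) for the given animal ids."""
        try:
            return np.asarray([self._index[a] for a in animals], dtype=np.int64)
        except KeyError as e:
            raise PedigreeError(f"animal {e.args[0]} not in pedigree") from None

    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"animal": self.animal, "sire": self.sire, "dam": self.dam})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        cols = {c.lower(): c for c in df.columns}
        try:
            a = df[cols["animal"]]
            s = df[cols["sire"]]
            d = df[cols["dam"]]
        except KeyError:
            raise PedigreeError("pedigree frame needs animal/sire/dam columns")
        s = s.fillna(UNKNOWN)
        d = d.fillna(UNKNOWN)
        return cls(a.to_numpy(np.int64), s.to_numpy(np.int64), d.to_numpy(np.int64))

    def prune_to(self, animals: Sequence[int]) -> "Pedigree":
        """Subset to the given animals plus all of their ancestors."""
        keep: set[int] = set()
        stack = [a for a in animals]
        while stack:
            a = stack.pop()
            if a == UNKNOWN or a in keep:
                continue
            keep.add(a)
            i = self._index.get(a)
            if i is None:
                raise PedigreeError(f"animal {a} not in pedigree")
            stack.extend((int(self.sire[i]), int(self.dam[i])))
        mask = np.isin(self.animal, sorted(keep))
        return Pedigree(self.animal[mask], self.sire[mask], self.dam[mask])


def build_A(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular (recursive) method.

    ``A[i, i] = 1 + 0.5 * A[sire, dam]`` and
    ``A[i, j] = 0.5 * (A[j, sire] + A[j, dam])`` for j preceding i;
    unknown parents contribute 0.  Founders have diagonal exactly 1.
    """
    n = len(ped)
    idx = ped._index
    A = np.zeros((n, n))
    for i in range(n):
        s = idx.get(int(ped.sire[i]), -1)
        d = idx.get(int(ped.dam[i]), -1)
        row = np.zeros(i)
        if s >= 0:
            row += A[:i, s]
        if d >= 0:
            row += A[:i, d]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficient F = coancestry of the parents.

    Memoized pairwise-kinship recursion; avoids materializing A and is
    cheap on the shallow pedigrees this package simulates.
    """
    idx = ped._index
    sire = ped.sire
    dam = ped.dam
    cache: dict[tuple[int, int], float] = {}

    def kin(i: int, j: int) -> float:
        # i, j are row indices; -1 = unknown
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in cache:
            return cache[key]
        sj = idx.get(int(sire[j]), -1)
        dj = idx.get(int(dam[j]), -1)
        if i == j:
            v = 0.5 * (1.0 + kin(sj, dj))
        else:
            # j is not an ancestor of i because i < j in topological order
            v = 0.5 * (kin(i, sj) + kin(i, dj))
        cache[key] = v
        return v

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(ped) + 1000))
    try:
        F = np.zeros(len(ped))
        for i in range(len(ped)):
            s = idx.get(int(sire[i]), -1)
            d = idx.get(int(dam[i]), -1)
            if s >= 0 and d >= 0:
                F[i] = kin(s, d)
    finally:
        sys.setrecursionlimit(old)
    return F
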