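"""Pedigree handling: validation, inbreeding, relationship matrices.

A pedigree is a list of (animal, sire, dam) triples with unknown parents
encoded by a sentinel.  From it we derive the numerator relationship matrix
A (tabular method, kept dense as a small-pedigree oracle), inbreeding
coefficients by the Meuwissen & Luo algorithm, and the sparse inverse of A
built directly from Henderson's rules with inbreeding accounted for, which
is what the mixed-model equations consume.

Unknown parents are treated as unrelated, non-inbred founders; there is no
genetic-group structure.  Animal identifiers are opaque tokens; an internal
integer coding is assigned in topological order (parents before offspring)
and exposed through :attr:`PedigreeTable.ids`.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Sentinel token for an unknown parent in external files.
UNKNOWN = "0"

_UNKNOWN_TOKENS = {"", "0", "NA", "na", ".", None}


class PedigreeError(ValueError):
    """Raised for malformed pedigrees (duplicates, cycles)."""


def _is_unknown(token) -> bool:
    if token is None:
        return True
    if isinstance(token, float) and np.isnan(token):
        return True
    return str(token).strip() in _UNKNOWN_TOKENS


@dataclass(frozen=True)
class PedigreeTable:
    """Pedigree as parallel arrays over an internal integer coding.

    ``ids[i]`` is the token of animal with code ``i``; ``sire[i]`` and
    ``dam[i]`` are parent codes or ``-1`` for unknown.  The table is not
    necessarily topologically sorted unless produced by
    :func:`topological_sort` (or by constructors that sort).
    """

    ids: tuple
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            dupes = pd.Series(list(self.ids))
            dupes = dupes[dupes.duplicated()].tolist()
            raise PedigreeError(f"duplicate animal ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def code(self) -> dict:
        """Mapping token -> internal code."""
        return {a: i for i, a in enumerate(self.ids)}

    @property
    def entries(self) -> list:
        """(animal, sire, dam) token triples, unknown as the sentinel."""
        out = []
        for i, a in enumerate(self.ids):
            s = self.ids[self.sire[i]] if self.sire[i] >= 0 else UNKNOWN
            d = self.ids[self.dam[i]] if self.dam[i] >= 0 else UNKNOWN
            out.append((a, s, d))
        return out

    @classmethod
    def from_entries(cls, entries) -> "PedigreeTable":
        """Build from (animal, sire, dam) token triples.

        Parents that are referenced but never defined are auto-inserted as
        founders (logged, never silent).
        """
        ids = [str(e[0]).strip() for e in entries]
        defined = set(ids)
        if len(defined) != len(ids):
            seen, dupes = set(), []
            for a in ids:
                if a in seen:
                    dupes.append(a)
                seen.add(a)
            raise PedigreeError(f"duplicate animal ids: {dupes[:5]}")
        extra = []
        for _, s, d in entries:
            for p in (s, d):
                if not _is_unknown(p):
                    p = str(p).strip()
                    if p not in defined:
                        defined.add(p)
                        extra.append(p)
        if extra:
            logger.info(
                "auto-inserted %d undefined parents as founders: %s%s",
                len(extra), extra[:5], "..." if len(extra) > 5 else "",
            )
        all_ids = extra + ids  # founders first (no ordering guarantee yet)
        code = {a: i for i, a in enumerate(all_ids)}
        n = len(all_ids)
        sire = np.full(n, -1, dtype=np.int64)
        dam = np.full(n, -1, dtype=np.int64)
        for a, s, d in entries:
            i = code[str(a).strip()]
            if not _is_unknown(s):
                sire[i] = code[str(s).strip()]
            if not _is_unknown(d):
                dam[i] = code[str(d).strip()]
        return cls(ids=tuple(all_ids), sire=sire, dam=dam)

    def is_sorted(self) -> bool:
        idx = np.arange(len(self))
        ok = True
        for par in (self.sire, self.dam):
            known = par >= 0
            ok = ok and bool(np.all(par[known] < idx[known]))
        return ok


def topological_sort(pedigree: PedigreeTable) -> PedigreeTable:
    """Reorder so every known parent precedes its offspring.

    The input is unchanged; a reordered copy is returned.  A cycle raises
    :class:`PedigreeError` naming one animal on the cycle.  The sort is
    stable: among animals whose constraints are satisfied, original order
    is preserved, so a pedigree that is already sorted round-trips.
    """
    n = len(pedigree)
    children = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (pedigree.sire[i], pedigree.dam[i]):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    order = []
    seen = np.zeros(n, dtype=bool)
    # Kahn's algorithm with a min-heap over original position for stability
    heap = np.flatnonzero(indeg == 0).tolist()
    heapq.heapify(heap)
    while heap:
        i = heapq.heappop(heap)
        order.append(i)
        seen[i] = True
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, c)
    if len(order) != n:
        culprit = pedigree.ids[int(np.flatnonzero(~seen)[0])]
        raise PedigreeError(f"pedigree cycle detected involving animal {culprit!r}")
    old_to_new = np.empty(n, dtype=np.int64)
    old_to_new[np.asarray(order)] = np.arange(n)
    remap = lambda p: np.where(p >= 0, old_to_new[np.maximum(p, 0)], -1)
    return PedigreeTable(
        ids=tuple(pedigree.ids[i] for i in order),
        sire=remap(pedigree.sire)[np.asarray(order)],
        dam=remap(pedigree.dam)[np.asarray(order)],
    )


def _require_sorted(pedigree: PedigreeTable) -> PedigreeTable:
    return pedigree if pedigree.is_sorted() else topological_sort(pedigree)


def inbreeding_coefficients(pedigree: PedigreeTable) -> pd.Series:
    """Inbreeding coefficients f by the Meuwissen & Luo (1992) algorithm.

    f(i) = 0.5 * a(sire, dam); zero when either parent is unknown.
    Returned as a Series indexed by animal token, in the order of the
    (topologically sorted) pedigree.
    """
    ped = _require_sorted(pedigree)
    f, _ = _inbreeding_and_d(ped)
    return pd.Series(f, index=list(ped.ids), name="f")


def _inbreeding_and_d(ped: PedigreeTable):
    """Inbreeding f and Mendelian-sampling variance ratios d (A = LDL').

    Requires a topologically sorted pedigree.  ``d[i]`` is the within-family
    variance ratio: 0.5 - 0.25 (f_s + f_d) with both parents known,
    0.75 - 0.25 f_p with one, 1 with none.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    f = np.zeros(n)
    d = np.ones(n)
    l = np.zeros(n)  # scratch: generation coefficients (row of L)
    for i in range(n):
        s, di_ = sire[i], dam[i]
        if s >= 0 and di_ >= 0:
            d[i] = 0.5 - 0.25 * (f[s] + f[di_])
        elif s >= 0:
            d[i] = 0.75 - 0.25 * f[s]
        elif di_ >= 0:
            d[i] = 0.75 - 0.25 * f[di_]
        else:
            d[i] = 1.0
        if s < 0 or di_ < 0:
            f[i] = 0.0
            continue
        # a_ii = 1 + f_i = sum_j l_j^2 d_j over ancestors j of i, where the
        # generation coefficients l satisfy l_i = 1, l_p += 0.5 l_j.  Codes
        # are processed in decreasing order (parents precede offspring), so
        # a max-heap over touched ancestor codes visits each exactly once.
        l[i] = 1.0
        heap = [-i]
        in_heap = {i}
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = l[j]
            l[j] = 0.0
            aii += lj * lj * d[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    l[p] += 0.5 * lj
                    if p not in in_heap:
                        in_heap.add(p)
                        heapq.heappush(heap, -p)
        f[i] = aii - 1.0
    return f, d


def mendelian_sampling_variances(pedigree: PedigreeTable) -> np.ndarray:
    """Diagonal D of A = LDL' (so log|A| = sum(log d))."""
    ped = _require_sorted(pedigree)
    return _inbreeding_and_d(ped)[1]


def relationship_matrix(pedigree: PedigreeTable, max_size: int = 10_000) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    Intended for small pedigrees (test oracle); refuses above ``max_size``.
    Rows/columns follow the topologically sorted coding of the input
    pedigree (sorted internally if needed).
    """
    ped = _require_sorted(pedigree)
    n = len(ped)
    if n > max_size:
        raise PedigreeError(
            f"tabular A refused for {n} animals (limit {max_size}); "
            "use a_inverse for large pedigrees"
        )
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        a_sd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def a_inverse(pedigree: PedigreeTable) -> sp.csc_matrix:
    """Sparse A⁻¹ by Henderson's rules with inbreeding (Meuwissen–Luo d).

    Exact on any pedigree: A⁻¹ = (I - P)' D⁻¹ (I - P) where P maps animals
    to half their known parents and D holds the Mendelian-sampling variance
    ratios from the inbreeding recursion.
    """
    ped = _require_sorted(pedigree)
    n = len(ped)
    _, d = _inbreeding_and_d(ped)
    rows, cols, vals = [], [], []
    for i in range(n):
        alpha = 1.0 / d[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        rows.append(i); cols.append(i); vals.append(alpha)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * alpha, -0.5 * alpha]
        for p in parents:
            for q in parents:
                rows.append(p); cols.append(q); vals.append(0.25 * alpha)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    return Ainv


def prune_generations(pedigree: PedigreeTable, keep, max_generations: int
                      ) -> PedigreeTable:
    """Restrict the pedigree to ancestors of ``keep`` within a depth limit.

    ``keep`` is an iterable of animal tokens (typically the recorded
    animals); ancestors more than ``max_generations`` above them are
    dropped and the cut parents become unknown.  Pruning is off by default
    throughout the package — deep pedigrees are cheap here — but herdbooks
    recorded over decades sometimes carry more generations than the
    analysis needs.
    """
    ped = _require_sorted(pedigree)
    code = ped.code
    depth = {}
    frontier = []
    for a in keep:
        if a not in code:
            raise PedigreeError(f"unknown animal {a!r} in keep set")
        depth[code[a]] = 0
        frontier.append(code[a])
    while frontier:
        nxt = []
        for i in frontier:
            if depth[i] >= max_generations:
                continue
            for p in (ped.sire[i], ped.dam[i]):
                if p >= 0 and depth.get(p, np.inf) > depth[i] + 1:
                    depth[int(p)] = depth[i] + 1
                    nxt.append(int(p))
        frontier = nxt
    kept = sorted(depth)
    new_code = {old: new for new, old in enumerate(kept)}
    remap = lambda p: new_code.get(int(p), -1) if p >= 0 else -1
    return PedigreeTable(
        ids=tuple(ped.ids[i] for i in kept),
        sire=np.asarray([remap(ped.sire[i]) for i in kept], dtype=np.int64),
        dam=np.asarray([remap(ped.dam[i]) for i in kept], dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# CSV interchange: columns animal,sire,dam; unknown parent as 0 or empty.

def read_pedigree_csv(path) -> PedigreeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"animal", "sire", "dam"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree CSV missing columns: {sorted(missing)}")
    entries = list(df[["animal", "sire", "dam"]].itertuples(index=False, name=None))
    return topological_sort(PedigreeTable.from_entries(entries))


def write_pedigree_csv(pedigree: PedigreeTable, path) -> None:
    df = pd.DataFrame(pedigree.entries, columns=["animal", "sire", "dam"])
    df.to_csv(path, index=False)
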