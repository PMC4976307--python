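"""Pedigree representation and the numerator relationship matrix.

A pedigree is an ordered set of individuals with sire/dam links, sex and
habitat labels. The additive (numerator) relationship matrix A holds the
expected additive-genetic relationship between every pair of pedigree
members; its diagonal is 1 + F_i where F_i is the inbreeding coefficient.
A is built by the recursive tabular method; its inverse is assembled
directly from per-individual Mendelian sampling variances (Henderson's
rules, with inbreeding accounted for).

Founders (both parents unknown) are assumed unrelated and non-inbred, the
standard base-population convention.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "RelationshipMatrix",
    "validate_pedigree",
    "inbreeding_coefficients",
    "inbreeding_array",
    "additive_relationship_matrix",
    "a_inverse",
]

SEXES = ("female", "male", "unknown")
HABITATS = ("urban", "rural", "unknown")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``sire``/``dam`` are ids of the parents, or ``None`` when unknown.
    Individuals with exactly one known parent are allowed (e.g. an unringed
    mate identified through its offspring).
    """

    id: str
    sire: Optional[str] = None
    dam: Optional[str] = None
    sex: str = "unknown"
    habitat: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise PedigreeError("individual id must be non-empty")
        if self.sex not in SEXES:
            raise PedigreeError(f"unknown sex {self.sex!r} for {self.id!r}")
        if self.habitat not in HABITATS:
            raise PedigreeError(f"unknown habitat {self.habitat!r} for {self.id!r}")

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


class Pedigree:
    """Topologically sorted pedigree (every parent precedes its offspring).

    Build via :func:`validate_pedigree`; the constructor trusts its input
    order only after checking the parent-precedes-offspring invariant.
    """

    def __init__(self, individuals: Sequence[Individual]):
        self.individuals: list[Individual] = list(individuals)
        self.index: dict[str, int] = {}
        for k, ind in enumerate(self.individuals):
            if ind.id in self.index:
                raise PedigreeError(f"duplicate id {ind.id!r}")
            self.index[ind.id] = k
        n = len(self.individuals)
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        for k, ind in enumerate(self.individuals):
            for attr, arr in (("sire", self.sire_idx), ("dam", self.dam_idx)):
                pid = getattr(ind, attr)
                if pid is None:
                    continue
                if pid not in self.index:
                    raise PedigreeError(f"{attr} {pid!r} of {ind.id!r} not in pedigree")
                p = self.index[pid]
                if p >= k:
                    raise PedigreeError(
                        f"pedigree not topologically sorted: {attr} {pid!r} "
                        f"does not precede {ind.id!r}"
                    )
                arr[k] = p

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __getitem__(self, id_: str) -> Individual:
        return self.individuals[self.index[id_]]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]


@dataclass(frozen=True)
class RelationshipMatrix:
    """Square symmetric relatedness matrix over a pedigree ordering.

    ``kind`` is ``"A"`` (dense numerator relationship matrix) or
    ``"A_inverse"`` (sparse CSR). ``inbreeding`` holds F_i per individual in
    pedigree order.
    """

    values: Union[np.ndarray, sp.csr_matrix]
    kind: str
    ids: tuple[str, ...]
    inbreeding: np.ndarray

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return self.values

    def inbreeding_by_id(self) -> dict[str, float]:
        return {i: float(f) for i, f in zip(self.ids, self.inbreeding)}


def validate_pedigree(records: Iterable[Individual]) -> Pedigree:
    """Check structural validity and return a topologically sorted Pedigree.

    Errors on: empty input, duplicate ids, self-parentage, a parent id that is
    referenced but absent, cycles, and sex inconsistency (an id used as both
    sire and dam, a declared female used as sire, or a declared male as dam).
    Ties in the sort preserve input order.
    """
    records = list(records)
    if not records:
        raise PedigreeError("pedigree is empty")

    by_id: dict[str, Individual] = {}
    for rec in records:
        if rec.id in by_id:
            raise PedigreeError(f"duplicate id {rec.id!r}")
        by_id[rec.id] = rec

    used_as_sire: set[str] = set()
    used_as_dam: set[str] = set()
    for rec in records:
        for attr, used in (("sire", used_as_sire), ("dam", used_as_dam)):
            pid = getattr(rec, attr)
            if pid is None:
                continue
            if pid == rec.id:
                raise PedigreeError(f"self-parentage: {rec.id!r} is its own {attr}")
            if pid not in by_id:
                raise PedigreeError(
                    f"{attr} {pid!r} of {rec.id!r} referenced but absent"
                )
            used.add(pid)

    both = used_as_sire & used_as_dam
    if both:
        raise PedigreeError(
            f"sex inconsistency: id(s) used as both sire and dam: {sorted(both)}"
        )
    for pid in used_as_sire:
        if by_id[pid].sex == "female":
            raise PedigreeError(f"sex inconsistency: female {pid!r} used as sire")
    for pid in used_as_dam:
        if by_id[pid].sex == "male":
            raise PedigreeError(f"sex inconsistency: male {pid!r} used as dam")

    # Kahn's algorithm; the ready heap is keyed by input position so the
    # order among unconstrained individuals is the input order.
    pos = {rec.id: i for i, rec in enumerate(records)}
    children: dict[str, list[str]] = {rec.id: [] for rec in records}
    n_parents: dict[str, int] = {}
    for rec in records:
        parents = {p for p in (rec.sire, rec.dam) if p is not None}
        n_parents[rec.id] = len(parents)
        for p in parents:
            children[p].append(rec.id)

    ready = [pos[i] for i, k in n_parents.items() if k == 0]
    heapq.heapify(ready)
    ordered: list[Individual] = []
    while ready:
        rec = records[heapq.heappop(ready)]
        ordered.append(rec)
        for child in children[rec.id]:
            n_parents[child] -= 1
            if n_parents[child] == 0:
                heapq.heappush(ready, pos[child])
    if len(ordered) != len(records):
        raise PedigreeError("cycle detected in pedigree")
    return Pedigree(ordered)


def additive_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix A by the recursive tabular method.

    a_ii = 1 + 0.5 a(sire_i, dam_i); a_ij (j earlier in the ordering) =
    0.5 (a(j, sire_i) + a(j, dam_i)); unknown parents contribute 0.
    Dense; intended for pedigrees up to a few thousand individuals.
    """
    n = len(ped)
    A = np.zeros((n, n))
    s_idx, d_idx = ped.sire_idx, ped.dam_idx
    for i in range(n):
        s, d = s_idx[i], d_idx[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    F = np.diag(A) - 1.0
    return RelationshipMatrix(A, "A", tuple(ped.ids), F)


def _kinship_function(ped: Pedigree):
    """Memoised kinship phi(i, j) over pedigree positions (phi = a_ij / 2).

    phi(i, i) = 0.5 (1 + phi(sire_i, dam_i)); for i != j with j earlier in the
    ordering, phi(i, j) = 0.5 (phi(sire_i, j) + phi(dam_i, j)); unknown
    parents contribute 0. Only the ancestor pairs actually reachable are
    evaluated, so inbreeding costs far less than the full tabular matrix.
    """
    memo: dict[tuple[int, int], float] = {}
    s_idx, d_idx = ped.sire_idx, ped.dam_idx

    def phi(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i < j:
            i, j = j, i
        key = (i, j)
        if key in memo:
            return memo[key]
        if i == j:
            val = 0.5 * (1.0 + phi(s_idx[i], d_idx[i]))
        else:
            val = 0.5 * (phi(s_idx[i], j) + phi(d_idx[i], j))
        memo[key] = val
        return val

    return phi


def inbreeding_array(ped: Pedigree) -> np.ndarray:
    """F_i = 0.5 a(sire_i, dam_i) in pedigree order; 0 with an unknown parent."""
    phi = _kinship_function(ped)
    n = len(ped)
    F = np.zeros(n)
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s >= 0 and d >= 0:
            F[i] = phi(s, d)
    return F


def inbreeding_coefficients(ped: Pedigree) -> dict[str, float]:
    """Inbreeding coefficient F_i = 0.5 a(sire_i, dam_i); 0 with an unknown parent."""
    return {i: float(f) for i, f in zip(ped.ids, inbreeding_array(ped))}


def mendelian_sampling_variance(ped: Pedigree, inbreeding: np.ndarray) -> np.ndarray:
    """Per-individual Mendelian sampling variance d_i in units of V_A.

    d_i = 0.5 - 0.25 (F_sire + F_dam) with both parents known; terms for
    unknown parents are dropped (d_i = 1 for founders, 0.75 - 0.25 F for one
    known parent).
    """
    n = len(ped)
    d = np.ones(n)
    for i in range(n):
        for p in (ped.sire_idx[i], ped.dam_idx[i]):
            if p >= 0:
                d[i] -= 0.25 * (1.0 + inbreeding[p])
    return d


def a_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Sparse inverse of A assembled by Henderson's rules with inbreeding.

    Each individual contributes alpha_i = 1/d_i to (i,i), -alpha_i/2 to the
    (i, parent) entries and alpha_i/4 to every (parent, parent') entry, where
    d_i is the Mendelian sampling variance from
    :func:`mendelian_sampling_variance`.
    """
    n = len(ped)
    F = inbreeding_array(ped)
    d = mendelian_sampling_variance(ped, F)
    if np.any(d <= 0):
        raise PedigreeError("non-positive Mendelian sampling variance")
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        alpha = 1.0 / d[i]
        parents = [p for p in (ped.sire_idx[i], ped.dam_idx[i]) if p >= 0]
        rows.append(i)
        cols.append(i)
        vals.append(alpha)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-alpha / 2.0, -alpha / 2.0]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(alpha / 4.0)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(Ainv, "A_inverse", tuple(ped.ids), F)
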