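"""Affine-plane partition design over ``n`` individuals.

Construction
------------
Let ``p`` be the smallest prime with ``p**2 >= n``.  The integers
``1 .. p**2`` are written column-wise into a ``p x p`` matrix ``P``; values
``n+1 .. p**2`` (present only when ``p**2 > n``) are *null* placeholders and
are dropped from every subset they would fall into.

The design's ``p**2 + p`` subsets are, in fixed order:

* the ``p`` columns of ``P``,
* the ``p`` rows of ``P``,
* for each shift level ``k = 1 .. p-1``, the ``p`` rows of a shifted matrix
  ``P_k`` whose column ``i`` is column ``i`` of ``P`` cyclically rotated by
  ``r(i, k) = ((i - 1) * k) mod p`` rows.

Each individual lands in exactly ``p + 1`` subsets (its column, its row, and
one row of each ``P_k``) and every unordered pair of individuals co-occurs in
exactly one subset — the subsets are the lines of an affine plane of order
``p``.  Primality of ``p`` is essential: composite shift strides make the
row residues collide and the exact-once property fails (see the negative
controls in the test suite).

Self-comparisons, when wanted, belong on the first ``p`` subsets only (the
columns of ``P``): each individual appears in exactly one column, so each
self-pair is visited exactly once.

Individuals are indexed 1-based throughout, matching the worked identities
such as ``P_1[p, 2] == P[1, 2]`` that pin down the shift direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import sympy

__all__ = [
    "PartitionDesign",
    "SubsetSpec",
    "smallest_admissible_prime",
    "base_matrix",
    "shift_amount",
    "shifted_matrix",
    "enumerate_subsets",
    "membership",
    "comparison_count",
]

SourceKind = Literal["column-of-P", "row-of-P", "row-of-P_k"]

#: Minimum admissible sample size; the construction is defined for n >= 4.
MIN_N = 4


@dataclass(frozen=True)
class SubsetSpec:
    """One line of the affine plane: a subset of individuals to co-compare.

    Parameters
    ----------
    subset_id
        Ordinal position in the design, ``0 .. p**2 + p - 1``.
    source
        Provenance: ``"column-of-P"``, ``"row-of-P"`` or ``"row-of-P_k"``.
    index
        1-based column/row index within the source matrix.
    k
        Shift level for ``row-of-P_k`` sources; ``0`` otherwise.
    members
        Sorted 1-based individual indices (null cells already removed).
    allows_self_comparison
        True exactly for the first ``p`` subsets (columns of ``P``).
    """

    subset_id: int
    source: SourceKind
    index: int
    k: int
    members: np.ndarray  # sorted int32, 1-based
    allows_self_comparison: bool

    def __len__(self) -> int:
        return int(self.members.size)

    def __repr__(self) -> str:  # members elided: can be p-long
        return (
            f"SubsetSpec(id={self.subset_id}, source={self.source!r}, "
            f"index={self.index}, k={self.k}, size={len(self)}, "
            f"self={self.allows_self_comparison})"
        )


@dataclass(frozen=True)
class PartitionDesign:
    """The full combinatorial object for a sample of ``n`` individuals."""

    n: int
    p: int
    subsets: list[SubsetSpec] = field(repr=False)
    index_base: int = 1

    def __len__(self) -> int:
        return len(self.subsets)

    def __iter__(self) -> Iterator[SubsetSpec]:
        return iter(self.subsets)

    def emitted_subsets(self, allow_self: bool = False) -> list[SubsetSpec]:
        """Subsets that carry actual work units.

        Subsets reduced below two members by null-cell removal stay in the
        design (so counts like ``p**2 + p`` hold) but define no pairwise
        comparison; they are skipped here.  With ``allow_self`` a singleton
        subset on a self-comparison-bearing subset still carries work.
        """
        out = []
        for s in self.subsets:
            if len(s) >= 2 or (allow_self and s.allows_self_comparison and len(s) >= 1):
                out.append(s)
        return out

    def summary(self) -> str:
        sizes = np.array([len(s) for s in self.subsets])
        lines = [
            f"n = {self.n}",
            f"p = {self.p} (smallest prime with p^2 >= n)",
            f"subsets = {len(self.subsets)} (p^2 + p)",
            f"subset sizes: min {sizes.min()}, max {sizes.max()}",
            f"memberships per individual = {self.p + 1} (p + 1)",
            f"pairwise comparisons = {comparison_count(self, include_self=False)}"
            f" (naive (n^2-n)/2 = {(self.n * self.n - self.n) // 2})",
            f"with self-comparisons = {comparison_count(self, include_self=True)}",
        ]
        return "\n".join(lines)


def _check_n(n: int) -> int:
    n = int(n)
    if n < MIN_N:
        raise ValueError(f"sample size n must be >= {MIN_N}, got {n}")
    return n


def smallest_admissible_prime(n: int) -> int:
    """Smallest prime ``p`` with ``p**2 >= n``.

    Uses a deterministic primality test (sympy's, exact in this range) over
    ascending integers starting at ``ceil(sqrt(n))``.
    """
    n = _check_n(n)
    candidate = math.isqrt(n - 1) + 1  # == ceil(sqrt(n))
    while not sympy.isprime(candidate):
        candidate += 1
    return candidate


def base_matrix(n: int, p: int | None = None) -> np.ndarray:
    """Column-wise fill of ``1 .. p**2`` into a ``p x p`` matrix.

    Cell ``(row j, column i)`` (both 1-based) holds ``(i-1)*p + j``.  Values
    greater than ``n`` are null placeholders, returned as ``0``.
    """
    n = _check_n(n)
    if p is None:
        p = smallest_admissible_prime(n)
    vals = np.arange(1, p * p + 1, dtype=np.int64).reshape(p, p, order="F")
    return np.where(vals <= n, vals, 0)


def shift_amount(i: int, k: int, p: int) -> int:
    """Cyclic shift ``r(i, k) = ((i - 1) * k) mod p`` for column ``i`` at level ``k``."""
    if not 1 <= i <= p:
        raise ValueError(f"column index i must be in 1..{p}, got {i}")
    if not 1 <= k <= p - 1:
        raise ValueError(f"shift level k must be in 1..{p - 1}, got {k}")
    return ((i - 1) * k) % p


def shifted_matrix(P: np.ndarray, k: int) -> np.ndarray:
    """Shifted matrix ``P_k``: column ``i`` of ``P`` rotated by ``r(i, k)`` rows.

    ``P_k[j, i] = P[((j - 1 + r(i, k)) mod p) + 1, i]`` in 1-based terms: the
    column contents move downward in a conveyor-belt motion, so e.g. the last
    element of column 2 of ``P_1`` is the first element of column 2 of ``P``.
    """
    p = P.shape[0]
    if P.shape != (p, p):
        raise ValueError("P must be square")
    if not 1 <= k <= p - 1:
        raise ValueError(f"shift level k must be in 1..{p - 1}, got {k}")
    r = (np.arange(p, dtype=np.int64) * k) % p  # r for 1-based column i = i-1 entry
    rows = (np.arange(p, dtype=np.int64)[:, None] + r[None, :]) % p
    return P[rows, np.arange(p)[None, :]]


def _members_from_cells(cells: np.ndarray) -> np.ndarray:
    """Drop null (0) cells and sort; cells are a 1-D slice of a matrix."""
    m = cells[cells > 0]
    return np.sort(m).astype(np.int32)  # int32 keeps ~10^5.5-scale designs small


def enumerate_subsets(n: int, p: int | None = None) -> PartitionDesign:
    """Build the full partition design for ``n`` individuals.

    ``p`` defaults to the smallest admissible prime and should be left alone
    in normal use; overriding it (including with a composite, which breaks
    the exact-once guarantee) exists for negative-control experiments.
    """
    n = _check_n(n)
    if p is None:
        p = smallest_admissible_prime(n)
    else:
        p = int(p)
        if p * p < n:
            raise ValueError(f"override p={p} has p^2 < n={n}")
    P = base_matrix(n, p)
    subsets: list[SubsetSpec] = []
    sid = 0
    # columns of P: the only subsets on which self-comparisons are allowed
    for i in range(p):
        subsets.append(
            SubsetSpec(sid, "column-of-P", i + 1, 0, _members_from_cells(P[:, i]), True)
        )
        sid += 1
    # rows of P
    for j in range(p):
        subsets.append(
            SubsetSpec(sid, "row-of-P", j + 1, 0, _members_from_cells(P[j, :]), False)
        )
        sid += 1
    # rows of each shifted matrix P_k
    for k in range(1, p):
        Pk = shifted_matrix(P, k)
        for j in range(p):
            subsets.append(
                SubsetSpec(sid, "row-of-P_k", j + 1, k, _members_from_cells(Pk[j, :]), False)
            )
            sid += 1
    assert sid == p * p + p
    return PartitionDesign(n=n, p=p, subsets=subsets)


def membership(individual: int, design: PartitionDesign) -> list[int]:
    """Subset ids containing ``individual``; always ``p + 1`` of them."""
    individual = int(individual)
    if not 1 <= individual <= design.n:
        raise ValueError(
            f"individual must be in 1..{design.n}, got {individual}"
        )
    out = [
        s.subset_id
        for s in design.subsets
        if np.searchsorted(s.members, individual) < s.members.size
        and s.members[np.searchsorted(s.members, individual)] == individual
    ]
    return out


def comparison_count(design: PartitionDesign, include_self: bool = False) -> int:
    """Total pairwise comparisons over all subsets.

    Sums ``m*(m-1)/2`` per subset; with ``include_self``, adds one
    self-comparison per member of each of the first ``p`` subsets (each
    individual sits in exactly one column of ``P``, so self-pairs are visited
    once).  By the exact-once cover this always equals the naive
    ``(n**2 - n)/2`` (plus ``n`` self-comparisons when included).
    """
    sizes = np.array([len(s) for s in design.subsets], dtype=np.int64)
    total = int((sizes * (sizes - 1) // 2).sum())
    if include_self:
        total += int(sum(len(s) for s in design.subsets if s.allows_self_comparison))
    return total


def subsets_as_arrays(design: PartitionDesign) -> tuple[np.ndarray, np.ndarray]:
    """Flatten member lists to ``(members, offsets)`` for bulk consumers.

    ``members`` concatenates all subsets' 1-based member indices;
    subset ``s`` spans ``members[offsets[s]:offsets[s+1]]``.
    """
    sizes = np.fromiter((len(s) for s in design.subsets), dtype=np.int64,
                        count=len(design.subsets))
    offsets = np.zeros(sizes.size + 1, dtype=np.int64)
    np.cumsum(sizes, out=offsets[1:])
    members = np.empty(int(offsets[-1]), dtype=np.int64)
    for s, spec in enumerate(design.subsets):
        members[offsets[s]:offsets[s + 1]] = spec.members
    return members, offsets
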