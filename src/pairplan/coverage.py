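"""Brute-force verification of the exact-once pair-coverage property.

The oracle is deliberately independent of the construction logic: it consumes
only the emitted member lists, never the matrices or shift arithmetic.  For
every unordered pair of individuals it counts the number of subsets ``t``
containing both members; the design is an exact-once cover iff ``t == 1``
for all ``n*(n-1)/2`` pairs.

Counting proceeds one individual at a time: for individual ``i``, walk every
subset containing ``i`` (via an inverted index built from the member lists
alone) and tally each co-member ``j > i`` into an ``n``-sized count buffer,
then read the buffer off as the coverage counts of all pairs ``(i, j)``.
This touches every within-subset pair exactly once while keeping the working
set cache-resident, so sweeping thousands of sample sizes — and ``n ~ 10^5``
with its ~5e9 pairs — stays within desk time and memory.  Counts saturate at
255 (a valid design never exceeds 1; near-miss designs stay far below the
cap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .design import PartitionDesign, enumerate_subsets, subsets_as_arrays

__all__ = ["CoverageReport", "pair_coverage", "sweep"]

_SATURATE = 255


@dataclass
class CoverageReport:
    """Per-pair co-occurrence accounting for one design."""

    n: int
    p: int
    #: co-occurrence count t -> number of pairs with that t (t=0 included)
    pair_count_histogram: dict[int, int]
    #: (i, j, t) for pairs with t != 1, truncated at the reporting cap
    offending_pairs: list[tuple[int, int, int]] = field(default_factory=list)
    offending_truncated: bool = False

    @property
    def is_exact_cover(self) -> bool:
        return set(self.pair_count_histogram) == {1}

    @property
    def total_pairs(self) -> int:
        return sum(self.pair_count_histogram.values())

    def __str__(self) -> str:
        status = "EXACT COVER" if self.is_exact_cover else "VIOLATION"
        hist = ", ".join(f"t={t}: {c}" for t, c in sorted(self.pair_count_histogram.items()))
        s = f"n={self.n} p={self.p}: {status} [{hist}]"
        if self.offending_pairs:
            shown = ", ".join(f"({i},{j})x{t}" for i, j, t in self.offending_pairs[:10])
            s += f"; offending pairs e.g. {shown}"
        return s


@njit(cache=True)
def _coverage_scan(members, offsets, inv, inv_offsets, n, max_offending):  # pragma: no cover - jit
    """Count co-occurrences per unordered pair; returns (histogram,
    offending (i, j, t) rows, total number of offending pairs)."""
    hist = np.zeros(_SATURATE + 1, dtype=np.int64)
    counts = np.zeros(n + 1, dtype=np.uint8)  # partner counts for current i
    offending = np.empty((max_offending, 3), dtype=np.int64)
    n_offending = 0
    for i in range(1, n + 1):
        for t in range(inv_offsets[i - 1], inv_offsets[i]):
            s = inv[t]
            # members are sorted: bisect to the first co-member above i
            a, b = offsets[s], offsets[s + 1]
            while a < b:
                mid = (a + b) // 2
                if members[mid] > i:
                    b = mid
                else:
                    a = mid + 1
            for x in range(a, offsets[s + 1]):
                j = members[x]
                c = counts[j]
                if c < _SATURATE:
                    counts[j] = c + 1
        # fast vector scan: in a valid design every count is exactly 1
        bad = 0
        for j in range(i + 1, n + 1):
            bad += counts[j] != 1
        if bad == 0:
            hist[1] += n - i
        else:
            for j in range(i + 1, n + 1):
                c = counts[j]
                hist[c] += 1
                if c != 1:
                    if n_offending < max_offending:
                        offending[n_offending, 0] = i
                        offending[n_offending, 1] = j
                        offending[n_offending, 2] = c
                    n_offending += 1
        counts[i + 1:n + 1] = 0
    return hist, offending, n_offending


def _inverted_index(members: np.ndarray, offsets: np.ndarray, n: int):
    """For each individual, the subset ids containing it, from member lists only."""
    sizes = np.diff(offsets)
    subset_of_position = np.repeat(np.arange(sizes.size, dtype=np.int64), sizes)
    order = np.argsort(members, kind="stable")
    inv = subset_of_position[order]
    inv_offsets = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(members - 1, minlength=n), out=inv_offsets[1:])
    return inv, inv_offsets


def pair_coverage(design: PartitionDesign, max_offending: int = 100) -> CoverageReport:
    """Exhaustively count, for every unordered pair, its within-subset co-occurrences.

    Reads only ``design.subsets[...].members``.  Offending pairs (``t != 1``)
    are reported up to ``max_offending`` so violations are diagnosable without
    unbounded output.
    """
    n = design.n
    members, offsets = subsets_as_arrays(design)
    members = members.astype(np.int32)
    inv, inv_offsets = _inverted_index(members, offsets, n)
    hist_arr, offending_arr, n_offending = _coverage_scan(
        members, offsets, inv, inv_offsets, np.int64(n), np.int64(max_offending)
    )
    histogram = {int(t): int(c) for t, c in enumerate(hist_arr) if c > 0}
    shown = min(n_offending, max_offending)
    offending = [
        (int(offending_arr[r, 0]), int(offending_arr[r, 1]), int(offending_arr[r, 2]))
        for r in range(shown)
    ]
    return CoverageReport(
        n=n,
        p=design.p,
        pair_count_histogram=histogram,
        offending_pairs=offending,
        offending_truncated=n_offending > max_offending,
    )


def sweep(
    n_values,
    fail_fast: bool = True,
    progress: bool = False,
) -> dict[int, CoverageReport]:
    """Run the coverage oracle for each sample size in ``n_values``.

    With ``fail_fast`` a violation raises immediately, naming the first
    offending pair; otherwise all reports are collected.
    """
    reports: dict[int, CoverageReport] = {}
    for n in n_values:
        design = enumerate_subsets(int(n))
        report = pair_coverage(design)
        reports[int(n)] = report
        if progress:
            print(report)
        if fail_fast and not report.is_exact_cover:
            first = report.offending_pairs[0] if report.offending_pairs else None
            raise AssertionError(
                f"coverage violation at n={n}: first offending pair {first}; {report}"
            )
    return reports
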