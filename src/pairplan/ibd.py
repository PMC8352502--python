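"""A small deterministic pairwise IBD caller (exact-match window hashing).

This is not a production IBD caller: it exists to demonstrate, end to end,
that calling segments per subset of the affine-plane design and merging is
bit-identical to calling on the full sample.  That equivalence holds exactly
because the caller is *pairwise-local* — its output for a pair of haplotypes
depends only on those two haplotypes and the configuration, never on who
else is in the batch — and fully deterministic.

Algorithm: markers are cut into consecutive windows of ``window_markers``
markers (default 75); haplotypes with identical window content are grouped
by hashing; for each within-group pair, maximal runs of consecutive shared
windows are extended marker-by-marker at both ends; runs whose genetic
length reaches ``min_length_cM`` (default 3.5 cM) are emitted.  The final
partial window participates in extension but never seeds a match.  Matching
is exact (no error tolerance): allele errors fragment segments, but they do
so identically in full-sample and per-subset runs, so equivalence is
unaffected.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import PartitionDesign
from .manifest import SegmentRecord, merge_records
from .simulate import HaplotypePanel

__all__ = ["CallerConfig", "EquivalenceResult", "call_ibd", "equivalence_check"]


@dataclass(frozen=True)
class CallerConfig:
    """Caller parameters.

    ``window_markers`` is the seeding window length in markers and
    ``min_length_cM`` the minimum reported genetic length; the defaults (75
    markers, 3.5 cM) mirror common hash-based IBD-caller settings for
    SNP-array data.  ``allow_self`` admits the pair formed by one
    individual's own two haplotypes.
    """

    window_markers: int = 75
    min_length_cM: float = 3.5
    allow_self: bool = False

    def __post_init__(self) -> None:
        if self.window_markers < 8:
            raise ValueError(f"window_markers must be >= 8, got {self.window_markers}")
        if self.min_length_cM <= 0:
            raise ValueError(f"min_length_cM must be > 0, got {self.min_length_cM}")


@dataclass
class EquivalenceResult:
    """Outcome of comparing full-sample calls to merged per-subset calls."""

    identical: bool
    n_full: int
    n_merged: int
    n_duplicates: int
    missing: list[SegmentRecord] = field(default_factory=list)  # in full, not merged
    extra: list[SegmentRecord] = field(default_factory=list)  # in merged, not full

    def __str__(self) -> str:
        if self.identical:
            return (f"EQUIVALENT: {self.n_full} segments, full-sample and merged "
                    f"subset calls are identical")
        lines = [
            f"NOT EQUIVALENT: full={self.n_full} merged={self.n_merged} "
            f"duplicates={self.n_duplicates}",
            f"missing from merge ({len(self.missing)}):",
        ]
        lines += [f"  {r.id_a}|{r.haplotype_a} - {r.id_b}|{r.haplotype_b} "
                  f"[{r.start_bp}-{r.end_bp}] {r.length_cM:.3f} cM"
                  for r in self.missing[:20]]
        if self.extra:
            lines.append(f"extra in merge ({len(self.extra)}):")
            lines += [f"  {r}" for r in self.extra[:20]]
        return "\n".join(lines)


def _pair_segments(
    panel: HaplotypePanel,
    row_a: int,
    row_b: int,
    shared_windows: Sequence[int],
    config: CallerConfig,
) -> list[tuple[int, int]]:
    """Extend runs of shared windows into maximal matching marker spans."""
    w = config.window_markers
    m = panel.n_markers
    a = panel.haplotypes[row_a]
    b = panel.haplotypes[row_b]
    mismatches = np.flatnonzero(a != b)
    spans: list[tuple[int, int]] = []
    runs: list[tuple[int, int]] = []
    start = prev = shared_windows[0]
    for win in shared_windows[1:]:
        if win != prev + 1:
            runs.append((start, prev))
            start = win
        prev = win
    runs.append((start, prev))
    for w0, w1 in runs:
        seed_start = w0 * w
        seed_end = (w1 + 1) * w
        # extend to the nearest mismatching marker on each side
        k = int(np.searchsorted(mismatches, seed_start))
        ext_start = int(mismatches[k - 1]) + 1 if k > 0 else 0
        k = int(np.searchsorted(mismatches, seed_end))
        ext_end = int(mismatches[k]) if k < mismatches.size else m
        spans.append((ext_start, ext_end))
    return spans


def call_ibd(
    panel: HaplotypePanel,
    sample_subset: Sequence[int] | None = None,
    config: CallerConfig = CallerConfig(),
) -> list[SegmentRecord]:
    """Call IBD segments among the given individuals (1-based indices).

    ``sample_subset=None`` means the full panel.  Output is canonically
    sorted and fully deterministic; pairs are restricted to the subset, and
    an individual's own haplotype pair is compared only if
    ``config.allow_self``.
    """
    if sample_subset is None:
        subset = list(range(1, panel.n_individuals + 1))
    else:
        subset = [int(i) for i in sample_subset]
        bad = [i for i in subset if not 1 <= i <= panel.n_individuals]
        if bad:
            raise ValueError(f"individuals {bad} outside the panel's 1..{panel.n_individuals}")
        if len(set(subset)) != len(subset):
            raise ValueError("sample_subset contains duplicates")
    if not subset:
        return []

    rows = [(ind, hap) for ind in sorted(subset) for hap in (0, 1)]
    w = config.window_markers
    n_windows = panel.n_markers // w  # final partial window never seeds

    # group haplotypes by exact window content; record shared windows per pair
    shared: dict[tuple[int, int], list[int]] = defaultdict(list)
    haps = panel.haplotypes
    for win in range(n_windows):
        groups: dict[bytes, list[int]] = defaultdict(list)
        for ind, hap in rows:
            row = 2 * (ind - 1) + hap
            groups[haps[row, win * w:(win + 1) * w].tobytes()].append(row)
        for members in groups.values():
            if len(members) < 2:
                continue
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    ra, rb = members[x], members[y]
                    if ra // 2 == rb // 2 and not config.allow_self:
                        continue
                    shared[(ra, rb)].append(win)

    records: list[SegmentRecord] = []
    for (ra, rb), wins in sorted(shared.items()):
        for start, end in _pair_segments(panel, ra, rb, wins, config):
            length = panel.span_cM(start, end)
            if length < config.min_length_cM:
                continue
            records.append(
                SegmentRecord(
                    id_a=panel.ids[ra // 2],
                    haplotype_a=ra % 2,
                    id_b=panel.ids[rb // 2],
                    haplotype_b=rb % 2,
                    chromosome=panel.chromosome,
                    start_bp=int(panel.positions_bp[start]),
                    end_bp=int(panel.positions_bp[end - 1]),
                    start_marker=start,
                    end_marker=end,
                    length_cM=length,
                ).canonical()
            )
    merged, _ = merge_records([records])
    return merged


def equivalence_check(
    panel: HaplotypePanel,
    design: PartitionDesign,
    config: CallerConfig = CallerConfig(),
) -> EquivalenceResult:
    """Compare full-sample calling with subset-parallel calling + merge.

    Runs the caller once on the full sample, then once per design subset
    (self-comparisons, if enabled, only on the subsets that carry them), and
    merges the per-subset outputs.  Because every pair co-occurs in exactly
    one subset the two record sets must be identical; any difference is
    returned as missing/extra lists.
    """
    if design.n != panel.n_individuals:
        raise ValueError(
            f"design covers n={design.n} but panel has {panel.n_individuals} individuals"
        )
    full = call_ibd(panel, None, config)
    per_subset: list[list[SegmentRecord]] = []
    for spec in design.emitted_subsets(allow_self=config.allow_self):
        sub_cfg = CallerConfig(
            window_markers=config.window_markers,
            min_length_cM=config.min_length_cM,
            allow_self=config.allow_self and spec.allows_self_comparison,
        )
        per_subset.append(call_ibd(panel, spec.members.tolist(), sub_cfg))
    merged, n_dup = merge_records(per_subset)
    full_set = set(full)
    merged_set = set(merged)
    missing = sorted(full_set - merged_set)
    extra = sorted(merged_set - full_set)
    return EquivalenceResult(
        identical=(full == merged and n_dup == 0),
        n_full=len(full),
        n_merged=len(merged),
        n_duplicates=n_dup,
        missing=missing,
        extra=extra,
    )
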