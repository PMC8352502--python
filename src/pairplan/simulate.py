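"""Synthetic phased haplotype panels with planted IBD segments.

The generator emulates just enough of a phased SNP-array chromosome to
exercise exact-match IBD machinery end to end with no external data:
independent biallelic markers (no background linkage disequilibrium) with
per-marker allele frequencies drawn from a stated range, a strictly
increasing physical map, and a genetic map at a uniform cM/Mb rate.  IBD is
planted by copying a contiguous allele stretch of the requested genetic
length from one haplotype onto another, recording the planted span as ground
truth; genotyping error is modelled as independent allele flips.

Defaults give a ~100 Mb / ~100 cM chromosome at ~50 kb marker spacing
(roughly SNP-array density), so the default caller threshold of 3.5 cM spans
~70 markers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .manifest import SegmentRecord, read_segments, write_segments

__all__ = [
    "HaplotypePanel",
    "simulate_panel",
    "plant_segments",
    "random_planting",
    "inject_errors",
    "load_panel",
]

#: (ind, hap) haplotype handle: 1-based individual, phased copy 0 or 1
HapRef = tuple[int, int]


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes plus genetic map and planted truth.

    ``haplotypes`` is a ``(2n, m)`` 0/1 matrix; individual ``i`` (1-based)
    owns rows ``2(i-1)`` and ``2(i-1)+1``.
    """

    ids: list[str]
    haplotypes: np.ndarray  # (2n, m) uint8
    positions_bp: np.ndarray  # (m,) int64, strictly increasing
    genetic_map_cM: np.ndarray  # (m,) float64, non-decreasing
    chromosome: str = "1"
    truth_segments: list[SegmentRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        n2, m = self.haplotypes.shape
        if n2 != 2 * len(self.ids):
            raise ValueError("haplotype matrix must have 2 rows per individual")
        if self.positions_bp.shape != (m,) or self.genetic_map_cM.shape != (m,):
            raise ValueError("map length must match marker count")
        if m and np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("physical positions must be strictly increasing")
        if m and np.any(np.diff(self.genetic_map_cM) < 0):
            raise ValueError("genetic map must be non-decreasing")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def haplotype_row(self, ref: HapRef) -> int:
        ind, hap = ref
        if not 1 <= ind <= self.n_individuals:
            raise ValueError(f"individual {ind} outside 1..{self.n_individuals}")
        if hap not in (0, 1):
            raise ValueError(f"haplotype must be 0 or 1, got {hap}")
        return 2 * (ind - 1) + hap

    def span_cM(self, start_marker: int, end_marker: int) -> float:
        """Genetic length of the half-open marker span [start, end)."""
        return float(
            self.genetic_map_cM[end_marker - 1] - self.genetic_map_cM[start_marker]
        )

    # ---- text export / import (matrix, map, ids, truth) ----

    def save(self, out_dir: str | os.PathLike) -> Path:
        """Write the panel as plain text: haplotype matrix (marker rows,
        haplotype columns), two-column (bp, cM) genetic map, sample IDs and
        the planted-truth segment TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "haplotypes.txt", self.haplotypes.T, fmt="%d", delimiter=" ")
        with open(out / "genetic_map.txt", "w") as fh:
            for bp, cm in zip(self.positions_bp, self.genetic_map_cM):
                fh.write(f"{bp}\t{cm:.6f}\n")
        (out / "samples.txt").write_text("".join(s + "\n" for s in self.ids))
        (out / "chromosome.txt").write_text(self.chromosome + "\n")
        write_segments(self.truth_segments, out / "truth_segments.tsv")
        return out

    def to_vcf(self, path: str | os.PathLike) -> Path:
        """Minimal VCF 4.2 export with phased GT records (``0|1`` style)."""
        path = Path(path)
        n = self.n_individuals
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={self.chromosome}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.ids) + "\n")
            for j in range(self.n_markers):
                gts = "\t".join(
                    f"{self.haplotypes[2 * i, j]}|{self.haplotypes[2 * i + 1, j]}"
                    for i in range(n)
                )
                fh.write(f"{self.chromosome}\t{self.positions_bp[j]}\tm{j}\t"
                         f"A\tG\t.\tPASS\t.\tGT\t{gts}\n")
        return path


def simulate_panel(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
    map_cM_per_Mb: float = 1.0,
    seed: int = 0,
    spacing_bp: tuple[int, int] = (25_000, 75_000),
    ids: Sequence[str] | None = None,
    chromosome: str = "1",
) -> HaplotypePanel:
    """Simulate a phased panel of ``n`` individuals at ``m`` independent markers.

    Per-marker minor-allele frequencies are drawn uniformly from
    ``maf_range`` and alleles are independent Bernoulli draws across markers
    and haplotypes (a linkage-free null).  Marker gaps are uniform in
    ``spacing_bp``; the genetic map is ``map_cM_per_Mb`` times the physical
    map.  Fully reproducible for a given ``seed``.
    """
    if n < 4:
        raise ValueError(f"panel needs n >= 4 individuals, got {n}")
    if m < 100:
        raise ValueError(f"panel needs m >= 100 markers, got {m}")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    if map_cM_per_Mb <= 0:
        raise ValueError("map rate must be positive")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=m)
    haplotypes = (rng.random((2 * n, m)) < freqs).astype(np.uint8)
    gaps = rng.integers(spacing_bp[0], spacing_bp[1], size=m)
    positions = np.cumsum(gaps).astype(np.int64)
    genetic_map = positions * (map_cM_per_Mb / 1e6)
    if ids is None:
        ids = [f"I{i:05d}" for i in range(1, n + 1)]
    return HaplotypePanel(
        ids=list(ids),
        haplotypes=haplotypes,
        positions_bp=positions,
        genetic_map_cM=genetic_map.astype(np.float64),
        chromosome=chromosome,
    )


def plant_segments(
    panel: HaplotypePanel,
    pair_list: Sequence[tuple[HapRef, HapRef]],
    length_cM_list: Sequence[float],
    seed: int = 0,
) -> HaplotypePanel:
    """Plant one IBD segment per (haplotype pair, genetic length) at a random
    map location by copying alleles from the first haplotype onto the second.

    The copied span is the shortest marker run whose genetic length reaches
    the requested value, so truth records satisfy ``length_cM >= requested``.
    Planting both haplotypes of one individual (self-IBD) is allowed.
    Returns a new panel; truth records are appended to any existing ones.
    """
    if len(pair_list) != len(length_cM_list):
        raise ValueError("pair_list and length_cM_list must have equal length")
    rng = np.random.default_rng(seed)
    haps = panel.haplotypes.copy()
    truth = list(panel.truth_segments)
    cm = panel.genetic_map_cM
    m = panel.n_markers
    total_cM = float(cm[-1] - cm[0])
    for (ref_a, ref_b), length in zip(pair_list, length_cM_list):
        if length <= 0:
            raise ValueError(f"requested segment length must be > 0, got {length}")
        if length > total_cM:
            raise ValueError(
                f"segment of {length} cM exceeds the {total_cM:.2f} cM chromosome"
            )
        row_a = panel.haplotype_row(ref_a)
        row_b = panel.haplotype_row(ref_b)
        if row_a == row_b:
            raise ValueError("cannot plant a segment from a haplotype onto itself")
        # latest start whose segment still fits on the map
        max_start = int(np.searchsorted(cm, cm[-1] - length, side="right")) - 1
        start = int(rng.integers(0, max_start + 1))
        end = int(np.searchsorted(cm, cm[start] + length, side="left")) + 1
        end = min(end, m)
        haps[row_b, start:end] = haps[row_a, start:end]
        rec = SegmentRecord(
            id_a=panel.ids[ref_a[0] - 1],
            haplotype_a=ref_a[1],
            id_b=panel.ids[ref_b[0] - 1],
            haplotype_b=ref_b[1],
            chromosome=panel.chromosome,
            start_bp=int(panel.positions_bp[start]),
            end_bp=int(panel.positions_bp[end - 1]),
            start_marker=start,
            end_marker=end,
            length_cM=float(cm[end - 1] - cm[start]),
        ).canonical()
        truth.append(rec)
    return replace(panel, haplotypes=haps, truth_segments=truth)


def random_planting(
    n: int,
    n_segments: int,
    length_range: tuple[float, float] = (8.0, 12.0),
    seed: int = 0,
    allow_self: bool = False,
) -> tuple[list[tuple[HapRef, HapRef]], list[float]]:
    """Draw ``n_segments`` haplotype pairs on *disjoint* haplotypes, plus
    segment lengths uniform in ``length_range``.

    Disjointness means no haplotype hosts two planted segments, so no plant
    overwrites another and each truth segment stays independently callable.
    Unless ``allow_self``, the two haplotypes of one individual are never
    paired with each other.
    """
    if 2 * n_segments > 2 * n:
        raise ValueError(f"cannot place {n_segments} disjoint segments on {2 * n} haplotypes")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        chosen = rng.choice(2 * n, size=2 * n_segments, replace=False)
        pairs = [
            ((int(chosen[2 * t]) // 2 + 1, int(chosen[2 * t]) % 2),
             (int(chosen[2 * t + 1]) // 2 + 1, int(chosen[2 * t + 1]) % 2))
            for t in range(n_segments)
        ]
        if allow_self or all(a[0] != b[0] for a, b in pairs):
            lengths = [float(x) for x in rng.uniform(*length_range, size=n_segments)]
            return pairs, lengths
    raise RuntimeError("could not draw a self-free pairing; too few individuals")


def inject_errors(
    panel: HaplotypePanel, error_rate: float, seed: int = 0
) -> HaplotypePanel:
    """Flip each allele independently with probability ``error_rate`` (< 0.05).

    Truth segments are left untouched: they describe the pre-error sharing.
    """
    if not 0.0 <= error_rate < 0.05:
        raise ValueError(f"error_rate must be in [0, 0.05), got {error_rate}")
    if error_rate == 0.0:
        return replace(panel, haplotypes=panel.haplotypes.copy())
    rng = np.random.default_rng(seed)
    flips = rng.random(panel.haplotypes.shape) < error_rate
    haps = np.where(flips, 1 - panel.haplotypes, panel.haplotypes).astype(np.uint8)
    return replace(panel, haplotypes=haps)


def load_panel(panel_dir: str | os.PathLike) -> HaplotypePanel:
    """Load a panel written by :meth:`HaplotypePanel.save`."""
    d = Path(panel_dir)
    haps = np.loadtxt(d / "haplotypes.txt", dtype=np.uint8, ndmin=2).T
    gmap = np.loadtxt(d / "genetic_map.txt", dtype=np.float64, ndmin=2)
    ids = (d / "samples.txt").read_text().split()
    chrom = (d / "chromosome.txt").read_text().strip()
    truth_path = d / "truth_segments.tsv"
    truth = read_segments(truth_path) if truth_path.exists() else []
    return HaplotypePanel(
        ids=ids,
        haplotypes=np.ascontiguousarray(haps),
        positions_bp=gmap[:, 0].astype(np.int64),
        genetic_map_cM=gmap[:, 1],
        chromosome=chrom,
        truth_segments=truth,
    )
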