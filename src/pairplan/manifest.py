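"""Scatter-gather plumbing: keep-files, job manifests and result merging.

Keep-files are plain one-sample-ID-per-line lists (the single-column dialect
PLINK's ``--keep`` and GERMLINE-style extract options accept), one file per
emitted subset, so external pairwise tools can consume the design unchanged.
Job manifests batch subsets into jobs (default 1000 subsets per job) and are
written as YAML.

Segment results travel as a tab-separated table with a fixed header
(``SEGMENT_COLUMNS``).  Because every pair of individuals is compared in
exactly one subset, merging per-subset outputs is pure concatenation — no
cross-window stitching; a duplicate identical row in a merge is therefore
flagged as a coverage-violation warning rather than silently kept.
Marker spans are half-open (``end_marker`` exclusive); base-pair spans are
inclusive of the first and last matching marker.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .design import PartitionDesign

logger = logging.getLogger(__name__)

__all__ = [
    "JobManifest",
    "SegmentRecord",
    "SEGMENT_COLUMNS",
    "write_keep_files",
    "read_keep_files",
    "write_manifest",
    "merge_records",
    "merge_results",
    "write_segments",
    "read_segments",
]

SEGMENT_COLUMNS = (
    "id_a",
    "haplotype_a",
    "id_b",
    "haplotype_b",
    "chromosome",
    "start_bp",
    "end_bp",
    "start_marker",
    "end_marker",
    "length_cM",
)


@dataclass(frozen=True, order=True)
class SegmentRecord:
    """One called (or planted-truth) IBD segment between two haplotypes.

    ``id_a``/``id_b`` are sample identifiers; ``haplotype_a``/``haplotype_b``
    select the phased copy (0 or 1).  Canonical form orders the endpoints
    lexicographically by (id, haplotype); self-IBD (both haplotypes of one
    individual) is allowed and ordered by haplotype.
    """

    id_a: str
    haplotype_a: int
    id_b: str
    haplotype_b: int
    chromosome: str
    start_bp: int
    end_bp: int
    start_marker: int  # inclusive
    end_marker: int  # exclusive
    length_cM: float

    def __post_init__(self) -> None:
        # store genetic length at TSV precision so records survive a
        # write/read round trip bit-identically
        object.__setattr__(self, "length_cM", round(float(self.length_cM), 6))
        if self.end_bp < self.start_bp or self.end_marker < self.start_marker:
            raise ValueError(f"segment end precedes start: {self}")
        if self.length_cM <= 0:
            raise ValueError(f"segment genetic length must be > 0: {self}")
        if (self.id_a, self.haplotype_a) == (self.id_b, self.haplotype_b):
            raise ValueError(f"segment endpoints are the same haplotype: {self}")

    def canonical(self) -> "SegmentRecord":
        if (self.id_a, self.haplotype_a) <= (self.id_b, self.haplotype_b):
            return self
        return replace(
            self,
            id_a=self.id_b,
            haplotype_a=self.haplotype_b,
            id_b=self.id_a,
            haplotype_b=self.haplotype_a,
        )

    def to_row(self) -> str:
        return "\t".join(
            (
                self.id_a,
                str(self.haplotype_a),
                self.id_b,
                str(self.haplotype_b),
                self.chromosome,
                str(self.start_bp),
                str(self.end_bp),
                str(self.start_marker),
                str(self.end_marker),
                f"{self.length_cM:.6f}",
            )
        )


@dataclass(frozen=True)
class JobManifest:
    """One batch of subsets to run as a single scheduler job."""

    job_id: int
    subset_ids: tuple[int, ...]
    keep_file_paths: tuple[str, ...]
    batch_size: int


def _keep_file_name(subset_id: int, width: int) -> str:
    return f"subset_{subset_id:0{width}d}.keep"


def write_keep_files(
    design: PartitionDesign,
    id_list: Sequence[str],
    out_dir: str | os.PathLike,
) -> list[Path]:
    """Write one keep-file per emitted subset (one sample ID per line).

    ``id_list`` maps line ``l`` (1-based) to individual ``l`` of the design;
    it must contain exactly ``n`` unique, non-empty IDs.  Subsets left with
    fewer than two members by null-cell removal carry no pairwise work and
    are skipped with a logged notice.
    """
    ids = [str(s) for s in id_list]
    if len(ids) != design.n:
        raise ValueError(
            f"id list has {len(ids)} entries but the design covers n={design.n}"
        )
    if any(not s or s != s.strip() for s in ids):
        raise ValueError("sample IDs must be non-empty and free of surrounding whitespace")
    if len(set(ids)) != len(ids):
        raise ValueError("sample IDs must be unique")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    width = len(str(len(design.subsets) - 1))
    paths: list[Path] = []
    for spec in design.subsets:
        if len(spec) < 2:
            logger.info(
                "subset %d has %d member(s) after null removal; no keep-file emitted",
                spec.subset_id, len(spec),
            )
            continue
        path = out / _keep_file_name(spec.subset_id, width)
        path.write_text("".join(ids[m - 1] + "\n" for m in spec.members))
        paths.append(path)
    return paths


def read_keep_files(paths: Iterable[str | os.PathLike]) -> dict[int, list[str]]:
    """Read keep-files back into ``{subset_id: [sample IDs]}``."""
    out: dict[int, list[str]] = {}
    for p in paths:
        p = Path(p)
        sid = int(p.stem.split("_")[-1])
        lines = p.read_text().splitlines()
        if any(not ln.strip() for ln in lines):
            raise ValueError(f"{p}: empty ID line")
        out[sid] = [ln.strip() for ln in lines]
    return out


def write_manifest(
    design: PartitionDesign,
    batch_size: int = 1000,
    keep_dir: str | os.PathLike | None = None,
    manifest_path: str | os.PathLike | None = None,
) -> list[JobManifest]:
    """Batch the emitted subsets into jobs of ``batch_size`` subsets each.

    Assignment is stable: subsets in ``subset_id`` order, ``ceil(emitted /
    batch_size)`` jobs.  If ``manifest_path`` is given the manifest is also
    written as YAML (``job_id -> subset ids and keep-file paths``).
    """
    batch_size = int(batch_size)
    if batch_size < 1:
        raise ValueError(f"batch_size must be >= 1, got {batch_size}")
    emitted = design.emitted_subsets()
    width = len(str(len(design.subsets) - 1))
    keep_dir = Path(keep_dir) if keep_dir is not None else Path(".")
    jobs: list[JobManifest] = []
    for j in range(math.ceil(len(emitted) / batch_size)):
        batch = emitted[j * batch_size:(j + 1) * batch_size]
        jobs.append(
            JobManifest(
                job_id=j,
                subset_ids=tuple(s.subset_id for s in batch),
                keep_file_paths=tuple(
                    str(keep_dir / _keep_file_name(s.subset_id, width)) for s in batch
                ),
                batch_size=batch_size,
            )
        )
    if manifest_path is not None:
        doc = {
            "n": design.n,
            "p": design.p,
            "batch_size": batch_size,
            "n_jobs": len(jobs),
            "jobs": [
                {
                    "job_id": job.job_id,
                    "subset_ids": list(job.subset_ids),
                    "keep_files": list(job.keep_file_paths),
                }
                for job in jobs
            ],
        }
        Path(manifest_path).write_text(yaml.safe_dump(doc, sort_keys=False))
    return jobs


def write_segments(records: Iterable[SegmentRecord], path: str | os.PathLike) -> Path:
    """Write segments as TSV with the fixed header.

    A leading comment line documents the span conventions (marker spans
    half-open, bp spans inclusive).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# start_marker inclusive, end_marker exclusive; "
                 "start_bp/end_bp inclusive of first/last matching marker\n")
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for rec in records:
            fh.write(rec.to_row() + "\n")
    return path


def _parse_row(fields: list[str]) -> SegmentRecord:
    return SegmentRecord(
        id_a=fields[0],
        haplotype_a=int(fields[1]),
        id_b=fields[2],
        haplotype_b=int(fields[3]),
        chromosome=fields[4],
        start_bp=int(fields[5]),
        end_bp=int(fields[6]),
        start_marker=int(fields[7]),
        end_marker=int(fields[8]),
        length_cM=float(fields[9]),
    )


def read_segments(path: str | os.PathLike) -> list[SegmentRecord]:
    """Read one segment TSV; rows are canonicalized on read.

    Malformed rows raise with the file and 1-based line number.
    """
    path = Path(path)
    records: list[SegmentRecord] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != SEGMENT_COLUMNS:
                    raise ValueError(
                        f"{path}:{lineno}: unexpected header {fields!r}"
                    )
                header_seen = True
                continue
            try:
                rec = _parse_row(fields)
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            records.append(rec.canonical())
    return records


def merge_records(
    record_lists: Iterable[Iterable[SegmentRecord]],
) -> tuple[list[SegmentRecord], int]:
    """Concatenate, canonicalize and sort segment records.

    Returns ``(merged, n_duplicates)``.  Exact duplicate rows should be
    impossible when the inputs come from an exact-once cover, so each one is
    logged as a warning and only a single copy kept.
    """
    merged: list[SegmentRecord] = []
    for records in record_lists:
        merged.extend(r.canonical() for r in records)
    merged.sort(key=lambda r: (
        r.id_a, r.id_b, r.chromosome, r.start_bp,
        r.haplotype_a, r.haplotype_b, r.start_marker,
    ))
    deduped: list[SegmentRecord] = []
    n_dup = 0
    for rec in merged:
        if deduped and rec == deduped[-1]:
            n_dup += 1
            logger.warning(
                "duplicate segment row (possible coverage violation): %s", rec
            )
            continue
        deduped.append(rec)
    return deduped, n_dup


def merge_results(
    result_files: Iterable[str | os.PathLike],
) -> list[SegmentRecord]:
    """Merge per-subset segment TSVs into one sorted, deduplicated list."""
    merged, _ = merge_records(read_segments(f) for f in result_files)
    return merged
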