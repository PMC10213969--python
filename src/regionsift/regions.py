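"""Expressed-region calling from pooled coverage, and region read counting.

The "find" half of find-then-annotate: contiguous runs of bases whose pooled
(across-sample) depth clears a cutoff become expressed regions, without any
reference to gene annotation.  Runs separated by short sub-cutoff gaps can be
bridged, and short runs discarded, spanning the parameter space of the
coverage-threshold callers used for small RNA (a minimum pooled depth of 1,
no gap bridging, and an 18-nt floor by default so mature miRNAs pass).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .alignio import AlignedRead, CountingPolicy, CoverageTrack

__all__ = [
    "Region",
    "RegionSet",
    "SegmentationParams",
    "call_regions",
    "count_regions",
    "count_intervals",
]


@dataclass(frozen=True)
class Region:
    """One expressed region; coordinates 0-based half-open, ID 1-based inclusive."""

    region_id: str
    contig: str
    start: int
    end: int
    mean_coverage: float = 0.0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"region {self.region_id}: start >= end")

    @property
    def length(self) -> int:
        return self.end - self.start

    @staticmethod
    def make_id(contig: str, start: int, end: int) -> str:
        return f"{contig}:{start + 1}-{end}"


@dataclass
class RegionSet:
    """Sorted collection of regions with BED6 round-tripping."""

    regions: list[Region] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate region IDs: {dupes}")
        self.regions = sorted(self.regions, key=lambda r: (r.contig, r.start, r.end))

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, i) -> Region:
        return self.regions[i]

    @property
    def ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def to_bed(self, path: str) -> None:
        # BED6; score = mean coverage x10, truncated, capped at 1000
        with open(path, "w") as fh:
            for r in self.regions:
                score = min(int(r.mean_coverage * 10), 1000)
                fh.write(
                    f"{r.contig}\t{r.start}\t{r.end}\t{r.region_id}\t{score}\t.\n"
                )

    @classmethod
    def from_bed(cls, path: str) -> "RegionSet":
        regions = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                contig, start, end = parts[0], int(parts[1]), int(parts[2])
                rid = parts[3] if len(parts) > 3 else Region.make_id(contig, start, end)
                score = float(parts[4]) / 10 if len(parts) > 4 and parts[4] != "." else 0.0
                regions.append(Region(rid, contig, start, end, score))
        return cls(regions)


@dataclass(frozen=True)
class SegmentationParams:
    """Coverage segmentation knobs: depth cutoff, gap bridging, length floor."""

    cutoff: float = 1.0
    max_gap: int = 0
    min_length: int = 18

    def __post_init__(self):
        if self.cutoff < 1:
            raise ValueError("cutoff must be >= 1 (depth units)")
        if self.max_gap < 0 or self.min_length < 1:
            raise ValueError("max_gap must be >= 0 and min_length >= 1")


def _runs_above(depth: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """Maximal [start, end) runs with depth >= cutoff."""
    mask = np.asarray(depth) >= cutoff
    if mask.size == 0 or not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def call_regions(track: CoverageTrack, params: SegmentationParams | None = None) -> RegionSet:
    """Segment pooled coverage into expressed regions.

    Maximal runs of pooled depth >= cutoff; runs separated by <= max_gap
    sub-cutoff bases are merged; merged runs shorter than min_length are
    discarded.  Region IDs are ``contig:start-end`` in 1-based inclusive form.
    """
    params = params or SegmentationParams()
    regions: list[Region] = []
    for contig in sorted(track.pooled):
        depth = track.pooled[contig]
        runs = _runs_above(depth, params.cutoff)
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= params.max_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s < params.min_length:
                continue
            regions.append(
                Region(Region.make_id(contig, s, e), contig, s, e,
                       float(np.mean(depth[s:e])))
            )
    return RegionSet(regions)


def count_intervals(
    intervals: Iterable[tuple[str, str, int, int]],
    reads_by_sample: Mapping[str, Iterable[AlignedRead]],
    policy: CountingPolicy | None = None,
) -> pd.DataFrame:
    """Count reads overlapping arbitrary intervals by >= min_overlap bases.

    ``intervals`` yields (id, contig, start, end).  A read overlapping k
    intervals each by >= min_overlap counts toward all k (the "count every
    qualifying feature" convention).  Returns an int64 DataFrame with one row
    per interval (input order) and one column per sample.
    """
    policy = policy or CountingPolicy()
    ids: list[str] = []
    trees: dict[str, IntervalTree] = {}
    for iid, contig, start, end in intervals:
        if iid in ids:
            raise ValueError(f"duplicate interval ID {iid!r}")
        ids.append(iid)
        trees.setdefault(contig, IntervalTree()).addi(start, end, iid)

    index = {iid: i for i, iid in enumerate(ids)}
    samples = list(reads_by_sample)
    counts = np.zeros((len(ids), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        for read in reads_by_sample[sample]:
            tree = trees.get(read.contig)
            if tree is None:
                continue
            for iv in tree.overlap(read.start, read.end):
                overlap = min(read.end, iv.end) - max(read.start, iv.begin)
                if overlap >= policy.min_overlap:
                    counts[index[iv.data], j] += 1
    return pd.DataFrame(counts, index=pd.Index(ids, name="id"), columns=samples)


def count_regions(
    regions: RegionSet,
    reads_by_sample: Mapping[str, Iterable[AlignedRead]],
    policy: CountingPolicy | None = None,
) -> pd.DataFrame:
    """Per-region, per-sample read counts under the counting policy."""
    return count_intervals(
        ((r.region_id, r.contig, r.start, r.end) for r in regions),
        reads_by_sample,
        policy,
    )
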