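"""SAM/BAM ingestion and per-base coverage tracks.

Reads are filtered under an explicit :class:`CountingPolicy` mirroring the
featureCounts/HTSeq parameter conventions used for small RNA work:
duplicate-flagged records dropped, multi-mappers (secondary alignments)
kept, a minimum feature overlap of 5 bases, and strand ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pysam

__all__ = [
    "AlignedRead",
    "CountingPolicy",
    "CoverageTrack",
    "AlignmentParseError",
    "read_alignments",
    "build_coverage",
]


class AlignmentParseError(ValueError):
    pass


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read reduced to its reference span (0-based half-open)."""

    name: str
    contig: str
    start: int
    end: int
    strand: str
    is_duplicate: bool = False
    mapq: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise AlignmentParseError(
                f"read {self.name}: empty reference span [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class CountingPolicy:
    """Which alignment records count, and how much overlap counts.

    Defaults follow the small RNA convention: drop PCR/optical duplicates,
    keep multi-mapping (secondary) alignments, require >= 5 bases of overlap
    with a feature/region, ignore strand.
    """

    ignore_duplicates: bool = True
    count_multimappers: bool = True
    min_overlap: int = 5
    stranded: bool = False

    def __post_init__(self):
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


def read_alignments(path: str, policy: CountingPolicy | None = None) -> Iterator[AlignedRead]:
    """Stream mapped reads from a SAM/BAM file under a counting policy.

    Unmapped records are always skipped; duplicate-flagged records are
    skipped iff ``policy.ignore_duplicates``; secondary alignments are kept
    iff ``policy.count_multimappers``.  The reference span comes from POS and
    CIGAR reference consumption (soft clips consume nothing), so spans are
    0-based half-open.
    """
    policy = policy or CountingPolicy()
    try:
        fh = pysam.AlignmentFile(path, check_sq=True)
    except ValueError as exc:
        raise AlignmentParseError(f"{path}: {exc}") from exc
    with fh:
        if not fh.header.get("SQ"):
            raise AlignmentParseError(f"{path}: missing @SQ header lines")
        for i, rec in enumerate(fh, start=1):
            if rec.is_unmapped:
                continue
            if rec.is_duplicate and policy.ignore_duplicates:
                continue
            if rec.is_secondary and not policy.count_multimappers:
                continue
            end = rec.reference_end
            if end is None:
                raise AlignmentParseError(
                    f"{path}: record {i} ({rec.query_name}): no CIGAR on a mapped read"
                )
            yield AlignedRead(
                name=rec.query_name or f"record{i}",
                contig=rec.reference_name,
                start=rec.reference_start,
                end=end,
                strand="-" if rec.is_reverse else "+",
                is_duplicate=rec.is_duplicate,
                mapq=rec.mapping_quality,
            )


class CoverageTrack:
    """Per-contig, per-base read depth for each sample plus the pooled sum.

    ``per_sample[sample][contig]`` is an int64 vector of depths; ``pooled``
    is the elementwise sum over samples.
    """

    def __init__(self, per_sample: dict[str, dict[str, np.ndarray]]):
        self.per_sample = per_sample
        self.samples = list(per_sample)

    @property
    def pooled(self) -> dict[str, np.ndarray]:
        pooled: dict[str, np.ndarray] = {}
        for tracks in self.per_sample.values():
            for contig, depth in tracks.items():
                if contig in pooled:
                    pooled[contig] = pooled[contig] + depth
                else:
                    pooled[contig] = depth.copy()
        return pooled


def build_coverage(
    reads_by_sample: Mapping[str, Iterable[AlignedRead]],
    contig_lengths: Mapping[str, int],
) -> CoverageTrack:
    """Stack read spans into per-base depth vectors.

    Depth at base b = number of retained reads whose span contains b.
    A read extending past its contig end is a bounds error.
    """
    per_sample: dict[str, dict[str, np.ndarray]] = {}
    for sample, reads in reads_by_sample.items():
        tracks = {c: np.zeros(n, dtype=np.int64) for c, n in contig_lengths.items()}
        for read in reads:
            if read.contig not in tracks:
                raise AlignmentParseError(
                    f"read {read.name}: contig {read.contig!r} not in contig lengths"
                )
            n = contig_lengths[read.contig]
            if read.start < 0 or read.end > n:
                raise AlignmentParseError(
                    f"read {read.name}: span [{read.start}, {read.end}) outside "
                    f"contig {read.contig} of length {n}"
                )
            tracks[read.contig][read.start:read.end] += 1
        per_sample[sample] = tracks
    return CoverageTrack(per_sample)
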