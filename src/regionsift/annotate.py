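"""Post-hoc annotation: region-to-feature assignment and count summation.

Expressed regions are detected with no annotation at all; this module
assigns each region afterwards to the known gene it overlaps most (largest
overlap wins, ties to the lexicographically smallest gene ID, overlaps below
the policy minimum ignored), sums region counts to gene level, and keeps the
unassigned remainder as candidate novel loci.  A direct read-to-gene counter
is also provided as the classical read-summarization baseline.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

from .alignio import AlignedRead, CountingPolicy
from .regions import RegionSet, count_intervals

__all__ = [
    "UNANNOTATED",
    "AnnotationParseError",
    "load_annotation",
    "assign_regions",
    "summarize_to_features",
    "count_features_direct",
    "biotype_fractions",
]

UNANNOTATED = "UNANNOTATED"

logger = logging.getLogger(__name__)


class AnnotationParseError(ValueError):
    pass


def load_annotation(gtf_path: str, feature_kind: str = "gene") -> pd.DataFrame:
    """Load gene-kind records from a GTF into a feature table.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Only records of ``feature_kind`` are kept.  Returns a DataFrame indexed
    by ``gene_id`` with columns contig, start, end, strand, biotype (from
    ``gene_type``/``gene_biotype`` when present, else "unknown").  A
    duplicated gene_id is an error: gene-level GTFs have unique IDs and a
    silent merge would hide malformed input.
    """
    rows = []
    seen: dict[str, int] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise AnnotationParseError(
                    f"{gtf_path}:{lineno}: malformed GTF record: {exc}"
                ) from exc
            if feat.featuretype != feature_kind:
                continue
            gene_ids = feat.attributes.get("gene_id")
            if not gene_ids:
                raise AnnotationParseError(
                    f"{gtf_path}:{lineno}: {feature_kind} record without gene_id"
                )
            gid = gene_ids[0]
            if gid in seen:
                raise AnnotationParseError(
                    f"{gtf_path}:{lineno}: duplicate gene_id {gid!r} "
                    f"(first seen at line {seen[gid]})"
                )
            seen[gid] = lineno
            biotype = (
                feat.attributes.get("gene_type")
                or feat.attributes.get("gene_biotype")
                or ["unknown"]
            )[0]
            rows.append((gid, feat.seqid, feat.start - 1, feat.end, feat.strand, biotype))
    if not rows:
        logger.warning("%s: no %r records found; annotation is empty", gtf_path, feature_kind)
        return pd.DataFrame(
            columns=["contig", "start", "end", "strand", "biotype"],
            index=pd.Index([], name="gene_id"),
        )
    ann = pd.DataFrame(
        rows, columns=["gene_id", "contig", "start", "end", "strand", "biotype"]
    ).set_index("gene_id")
    if (ann["start"] >= ann["end"]).any():
        bad = ann.index[ann["start"] >= ann["end"]][0]
        raise AnnotationParseError(f"{gtf_path}: empty interval for gene {bad!r}")
    return ann


def _feature_trees(ann: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gid, row in ann.iterrows():
        trees.setdefault(row["contig"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]), gid
        )
    return trees


def assign_regions(
    regions: RegionSet,
    ann: pd.DataFrame,
    policy: CountingPolicy | None = None,
) -> pd.DataFrame:
    """Assign every region to its largest-overlap feature, or UNANNOTATED.

    A region is assigned to the overlapping feature with the largest overlap
    in bases, provided that overlap is >= policy.min_overlap; ties break to
    the lexicographically smallest feature ID.  Strand is ignored unless
    ``policy.stranded`` (strict same-strand matching; strand-less regions
    never match in stranded mode).

    Returns a DataFrame indexed by region_id with columns feature_id,
    overlap_bp, biotype.  Every region appears exactly once.
    """
    policy = policy or CountingPolicy()
    trees = _feature_trees(ann)
    rows = []
    for region in regions:
        best_gid, best_ov = UNANNOTATED, 0
        tree = trees.get(region.contig)
        if tree is not None:
            for iv in tree.overlap(region.start, region.end):
                if policy.stranded:
                    continue  # regions carry no strand; nothing can match strictly
                ov = min(region.end, iv.end) - max(region.start, iv.begin)
                if ov < policy.min_overlap:
                    continue
                if ov > best_ov or (ov == best_ov and iv.data < best_gid):
                    best_gid, best_ov = iv.data, ov
        biotype = ann.at[best_gid, "biotype"] if best_gid != UNANNOTATED else ""
        rows.append((region.region_id, best_gid, best_ov, biotype))
    return pd.DataFrame(
        rows, columns=["region_id", "feature_id", "overlap_bp", "biotype"]
    ).set_index("region_id")


def summarize_to_features(
    counts: pd.DataFrame, assignment: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum region counts to feature level; keep unannotated rows separate.

    Each feature's row is the elementwise sum of its assigned regions' rows.
    Returns (feature_counts, unannotated_region_counts).
    """
    missing = counts.index.difference(assignment.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} region(s) in the count matrix have no assignment, "
            f"e.g. {missing[0]!r}"
        )
    fid = assignment.loc[counts.index, "feature_id"]
    annotated = counts.loc[fid != UNANNOTATED]
    orphan = counts.loc[fid == UNANNOTATED]
    if annotated.empty:
        feature_counts = pd.DataFrame(
            columns=counts.columns, index=pd.Index([], name="id"), dtype=int
        )
    else:
        feature_counts = annotated.groupby(fid.loc[annotated.index]).sum()
        feature_counts.index.name = "id"
        feature_counts = feature_counts.sort_index()
    return feature_counts, orphan


def count_features_direct(
    reads_by_sample: Mapping[str, Iterable[AlignedRead]],
    ann: pd.DataFrame,
    policy: CountingPolicy | None = None,
) -> pd.DataFrame:
    """Classical read summarization: count reads straight onto features.

    Cell (feature, sample) = reads overlapping the feature by >=
    policy.min_overlap bases; a read qualifying for several features counts
    toward all of them.
    """
    return count_intervals(
        (
            (gid, row["contig"], int(row["start"]), int(row["end"]))
            for gid, row in ann.iterrows()
        ),
        reads_by_sample,
        policy,
    )


def biotype_fractions(
    counts: pd.DataFrame, assignment: pd.DataFrame
) -> pd.Series:
    """Fraction of total counted reads per RNA class, plus "unannotated".

    Fractions sum to 1 over assigned biotypes plus the unannotated bucket
    (when any reads were counted at all).
    """
    totals = counts.sum(axis=1)
    label = assignment.loc[counts.index].apply(
        lambda row: "unannotated" if row["feature_id"] == UNANNOTATED else row["biotype"],
        axis=1,
    )
    grand = totals.sum()
    if grand == 0:
        return pd.Series(dtype=float)
    return totals.groupby(label).sum() / grand
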