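"""Consensus-based triage of unannotated expressed regions into biomarker
candidates.

The discovery workflow feeds the same alignments through several region
callers (or caller parameterizations), keeps only intervals that multiple
callers agree on (reciprocal-overlap matching), and then filters the
consensus down to candidate biomarkers: unannotated, not attributable to
exogenous organisms, at least 21 nt long (more than 20 nucleotides),
abundant, and significant at a deliberately permissive FDR threshold
(alpha = 0.1) in every supporting caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotate import UNANNOTATED
from .regions import Region, RegionSet

__all__ = [
    "TriageParams",
    "CandidateRegion",
    "consensus_regions",
    "candidate_filter",
]


@dataclass(frozen=True)
class TriageParams:
    """Candidate-selection thresholds.

    alpha is intentionally permissive (0.1) to maximize the candidate pool
    before wet-lab validation; min_length = 21 keeps regions longer than
    20 nt; abundance_floor is a mean normalized count.
    """

    alpha: float = 0.1
    min_length: int = 21
    min_tools: int = 3
    min_reciprocal_overlap: float = 0.5
    abundance_floor: float = 10.0


@dataclass(frozen=True)
class CandidateRegion:
    """One triaged biomarker candidate with its per-caller evidence."""

    region: Region
    supporting_callers: tuple[str, ...]
    length: int
    mean_abundance: float
    log2fc: float
    fdr_per_caller: Mapping[str, float] = field(default_factory=dict)

    @property
    def worst_fdr(self) -> float:
        return max(self.fdr_per_caller.values())


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def consensus_regions(
    region_sets: Mapping[str, RegionSet],
    min_tools: int | None = None,
    min_reciprocal_overlap: float = 0.5,
) -> tuple[RegionSet, pd.DataFrame]:
    """Intersect region calls from several callers into consensus intervals.

    Regions from different callers match when their reciprocal overlap (the
    intersection as a fraction of each region) reaches the threshold;
    matching is transitive (connected components).  Each component supported
    by at least ``min_tools`` distinct callers yields one consensus region:
    the intersection of the component's spans.  Components whose spans have
    an empty common intersection are dropped.

    Returns the consensus RegionSet and a membership table mapping each
    consensus region to its supporting callers and member region IDs.
    """
    names = list(region_sets)
    if not names:
        raise ValueError("need at least one region set")
    if min_tools is None:
        min_tools = len(names)
    if min_tools > len(names):
        raise ValueError(
            f"min_tools={min_tools} exceeds the {len(names)} region sets supplied"
        )

    nodes = [
        (name, r) for name in names for r in region_sets[name]
    ]
    # union-find over reciprocal-overlap matches between different sets
    parent = list(range(len(nodes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    trees: dict[str, IntervalTree] = {}
    for idx, (_, r) in enumerate(nodes):
        trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end, idx)
    for idx, (name, r) in enumerate(nodes):
        for iv in trees[r.contig].overlap(r.start, r.end):
            jdx = iv.data
            if jdx <= idx:
                continue
            other_name, other = nodes[jdx]
            if other_name == name:
                continue
            if _reciprocal_overlap(r.start, r.end, other.start, other.end) >= min_reciprocal_overlap:
                union(idx, jdx)

    components: dict[int, list[int]] = {}
    for idx in range(len(nodes)):
        components.setdefault(find(idx), []).append(idx)

    out_regions: list[Region] = []
    rows = []
    for members in components.values():
        callers = sorted({nodes[i][0] for i in members})
        if len(callers) < min_tools:
            continue
        start = max(nodes[i][1].start for i in members)
        end = min(nodes[i][1].end for i in members)
        if start >= end:
            continue
        contig = nodes[members[0]][1].contig
        mean_cov = sum(nodes[i][1].mean_coverage for i in members) / len(members)
        rid = Region.make_id(contig, start, end)
        out_regions.append(Region(rid, contig, start, end, mean_cov))
        rows.append(
            (rid, ",".join(callers), ",".join(sorted(nodes[i][1].region_id for i in members)))
        )

    membership = pd.DataFrame(
        rows, columns=["consensus_id", "callers", "member_regions"]
    ).set_index("consensus_id")
    return RegionSet(out_regions), membership


def candidate_filter(
    consensus: RegionSet,
    membership: pd.DataFrame,
    assignment: pd.DataFrame,
    de_results: Mapping[str, pd.DataFrame],
    abundance: pd.Series,
    exogenous_flags: Mapping[str, bool] | pd.Series,
    params: TriageParams | None = None,
    missing_de: str = "error",
) -> list[CandidateRegion]:
    """Apply the biomarker filters to consensus regions.

    Keeps regions that are UNANNOTATED, not flagged exogenous, at least
    ``min_length`` nt long, have mean normalized abundance >=
    ``abundance_floor``, and show FDR < alpha in *every* supporting caller's
    DE table (indexed by that caller's member region ID).  The result is
    sorted by worst-caller FDR, most significant first.

    ``missing_de`` controls what happens when a supporting caller has no DE
    row for any member region: "error" (a consistency error, the default) or
    "drop" (the region simply fails the significance filter — appropriate
    when DE tables were low-count filtered upstream).
    """
    if missing_de not in ("error", "drop"):
        raise ValueError("missing_de must be 'error' or 'drop'")
    params = params or TriageParams()
    exo = pd.Series(exogenous_flags, dtype=bool) if not isinstance(exogenous_flags, pd.Series) else exogenous_flags

    candidates: list[CandidateRegion] = []
    for region in consensus:
        rid = region.region_id
        if rid not in membership.index:
            raise ValueError(f"consensus region {rid} missing from membership table")
        if rid not in assignment.index:
            raise ValueError(f"consensus region {rid} has no annotation assignment")
        if assignment.at[rid, "feature_id"] != UNANNOTATED:
            continue
        if bool(exo.get(rid, False)):
            continue
        if region.length < params.min_length:
            continue
        mean_abund = float(abundance.get(rid, 0.0))
        if mean_abund < params.abundance_floor:
            continue

        callers = membership.at[rid, "callers"].split(",")
        members = membership.at[rid, "member_regions"].split(",")
        fdrs: dict[str, float] = {}
        ok = True
        for caller in callers:
            table = de_results[caller]
            member_fdrs = [
                float(table.at[m, "FDR"]) for m in members if m in table.index
            ]
            if not member_fdrs:
                if missing_de == "drop":
                    ok = False
                    break
                raise ValueError(
                    f"consensus region {rid}: no DE row for caller {caller!r}"
                )
            fdrs[caller] = min(member_fdrs)
            if fdrs[caller] >= params.alpha:
                ok = False
        if not ok:
            continue

        fcs = []
        for caller in callers:
            member_in = [m for m in members if m in de_results[caller].index]
            if member_in:
                fcs.append(float(de_results[caller].loc[member_in, "logFC"].mean()))
        log2fc = float(np.mean(fcs)) if fcs else float("nan")
        candidates.append(
            CandidateRegion(
                region=region,
                supporting_callers=tuple(callers),
                length=region.length,
                mean_abundance=mean_abund,
                log2fc=log2fc,
                fdr_per_caller=fdrs,
            )
        )
    candidates.sort(key=lambda c: c.worst_fdr)
    return candidates


def candidates_to_frame(candidates: Sequence[CandidateRegion]) -> pd.DataFrame:
    """Tabular candidate report (one row per candidate)."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "region_id": c.region.region_id,
                "contig": c.region.contig,
                "start": c.region.start,
                "end": c.region.end,
                "length_nt": c.length,
                "callers": ",".join(c.supporting_callers),
                "mean_abundance": c.mean_abundance,
                "log2FC": c.log2fc,
                "worst_FDR": c.worst_fdr,
            }
        )
    return pd.DataFrame(rows)
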