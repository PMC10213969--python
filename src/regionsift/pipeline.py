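"""End-to-end pipeline orchestration: the two workflows behind the CLI.

``feature`` mode is the classical route — count reads directly on annotated
genes and run differential expression.  ``discovery`` mode is the
annotation-agnostic route — segment pooled coverage into expressed regions,
count and test regions, annotate them post hoc, and triage the unannotated
remainder into biomarker candidates using three region-caller
parameterizations as the consensus panel.  All intermediates are plain
TSV/BED so any stage can be swapped for an external tool's output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import pysam

from . import __version__
from .alignio import CountingPolicy, build_coverage, read_alignments
from .annotate import (
    UNANNOTATED,
    assign_regions,
    count_features_direct,
    load_annotation,
    summarize_to_features,
)
from .de import DEParams, run_de
from .regions import SegmentationParams, call_regions, count_regions
from .triage import TriageParams, candidate_filter, candidates_to_frame, consensus_regions

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs: paths, groups, and stage knobs."""

    alignments: dict[str, str]  # sample name -> SAM/BAM path
    groups: dict[str, int]  # sample name -> 1 (control) or 2 (treatment)
    outdir: str
    gtf: str | None = None
    exogenous_flags: str | None = None  # TSV: region_id <tab> bool
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    policy: CountingPolicy = field(default_factory=CountingPolicy)
    de_params: DEParams = field(default_factory=DEParams)
    triage_params: TriageParams = field(default_factory=TriageParams)
    seed: int = 0
    # consensus panel: caller name -> segmentation parameters
    caller_panel: dict[str, SegmentationParams] = field(default_factory=dict)

    def validate(self, mode: str) -> None:
        if not self.alignments:
            raise PipelineError("config: no alignment files given")
        for sample, path in self.alignments.items():
            if not os.path.exists(path):
                raise PipelineError(f"config: alignment for {sample!r} missing: {path}")
        if set(self.alignments) != set(self.groups):
            raise PipelineError("config: samples in alignments and groups differ")
        if self.gtf is None:
            raise PipelineError(f"config: {mode} mode needs a GTF annotation")
        if not os.path.exists(self.gtf):
            raise PipelineError(f"config: GTF not found: {self.gtf}")


def _default_panel() -> dict[str, SegmentationParams]:
    # three caller parameterizations standing in for three independent tools
    return {
        "strict": SegmentationParams(cutoff=2, max_gap=0, min_length=18),
        "default": SegmentationParams(cutoff=1, max_gap=0, min_length=18),
        "bridged": SegmentationParams(cutoff=1, max_gap=5, min_length=18),
    }


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _contig_lengths(path: str) -> dict[str, int]:
    with pysam.AlignmentFile(path) as fh:
        return dict(zip(fh.references, fh.lengths))


def run_pipeline(config: PipelineConfig, mode: str = "both") -> dict:
    """Run feature-level quantification, discovery triage, or both.

    Writes all artifacts under ``config.outdir`` and a ``manifest.json``
    recording version, parameters, seed and per-file SHA-256 checksums.
    Returns the manifest dict.
    """
    if mode not in ("feature", "discovery", "both"):
        raise PipelineError(f"unknown mode {mode!r}")
    config.validate(mode)
    os.makedirs(config.outdir, exist_ok=True)
    artifacts: dict[str, str] = {}
    t0 = time.time()

    def _stage(name):
        logger.info("[%s] starting (t=%.1fs)", name, time.time() - t0)

    def _write(df: pd.DataFrame, name: str) -> str:
        path = os.path.join(config.outdir, name)
        df.to_csv(path, sep="\t")
        artifacts[name] = path
        return path

    try:
        _stage("load")
        ann = load_annotation(config.gtf)
        contig_lengths = _contig_lengths(next(iter(config.alignments.values())))
        reads = {
            sample: list(read_alignments(path, config.policy))
            for sample, path in sorted(config.alignments.items())
        }
        groups = [config.groups[s] for s in reads]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'load' failed: {exc}") from exc

    if mode in ("feature", "both"):
        try:
            _stage("feature-counts")
            feat_counts = count_features_direct(reads, ann, config.policy)
            _write(feat_counts, "feature_counts.tsv")
            _stage("feature-de")
            feat_de = run_de(feat_counts, groups, config.de_params)
            _write(feat_de, "feature_de.tsv")
        except Exception as exc:
            raise PipelineError(f"stage 'feature' failed: {exc}") from exc

    if mode in ("discovery", "both"):
        try:
            _stage("coverage")
            track = build_coverage(reads, contig_lengths)
            panel = config.caller_panel or _default_panel()

            region_sets = {}
            region_de = {}
            for caller, seg in panel.items():
                _stage(f"call-regions[{caller}]")
                rset = call_regions(track, seg)
                region_sets[caller] = rset
                bed = os.path.join(config.outdir, f"regions_{caller}.bed")
                rset.to_bed(bed)
                artifacts[f"regions_{caller}.bed"] = bed
                rcounts = count_regions(rset, reads, config.policy)
                _write(rcounts, f"region_counts_{caller}.tsv")
                region_de[caller] = run_de(rcounts, groups, config.de_params)
                _write(region_de[caller], f"region_de_{caller}.tsv")

            _stage("annotate")
            primary = next(iter(panel))
            assignment = assign_regions(region_sets[primary], ann, config.policy)
            _write(assignment, "region_assignment.tsv")
            primary_counts = pd.read_csv(
                artifacts[f"region_counts_{primary}.tsv"], sep="\t", index_col=0
            )
            feat_from_regions, orphan_counts = summarize_to_features(
                primary_counts, assignment
            )
            _write(feat_from_regions, "feature_counts_from_regions.tsv")
            _write(orphan_counts, "unannotated_region_counts.tsv")

            _stage("triage")
            consensus, membership = consensus_regions(
                region_sets,
                min_tools=config.triage_params.min_tools,
                min_reciprocal_overlap=config.triage_params.min_reciprocal_overlap,
            )
            cons_bed = os.path.join(config.outdir, "consensus_regions.bed")
            consensus.to_bed(cons_bed)
            artifacts["consensus_regions.bed"] = cons_bed
            cons_assign = assign_regions(consensus, ann, config.policy)
            cons_counts = count_regions(consensus, reads, config.policy)
            abundance = cons_counts.mean(axis=1)

            exo: dict[str, bool] = {}
            if config.exogenous_flags:
                flags = pd.read_csv(
                    config.exogenous_flags, sep="\t", index_col=0
                ).iloc[:, 0].astype(bool)
                exo = flags.to_dict()

            candidates = candidate_filter(
                consensus,
                membership,
                cons_assign,
                region_de,
                abundance,
                exo,
                config.triage_params,
                missing_de="drop",
            )
            _write(candidates_to_frame(candidates).set_index(
                pd.Index(range(len(candidates)), name="rank")
            ), "candidates.tsv")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'discovery' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "mode": mode,
        "seed": config.seed,
        "parameters": {
            "segmentation": vars(config.segmentation),
            "policy": vars(config.policy),
            "de": {k: v for k, v in vars(config.de_params).items()},
            "triage": vars(config.triage_params),
        },
        "elapsed_s": round(time.time() - t0, 2),
        "artifacts": {name: _sha256(path) for name, path in sorted(artifacts.items())},
    }
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
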