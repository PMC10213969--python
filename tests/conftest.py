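import numpy as np
import pandas as pd
import pytest

import regionsift as rs
from regionsift.de import DEParams, run_de
from regionsift.pipeline import _default_panel
from regionsift.simulate import locus_for_regions

SAMPLES = [f"s{i}" for i in range(12)]
GROUPS = [1] * 6 + [2] * 6


def nb_matrix(rng, mu, phi, shape):
    """NB(mu, phi) draws with variance mu + phi*mu^2 (phi=0 -> Poisson)."""
    if phi == 0:
        return rng.poisson(mu, shape)
    r = 1 / phi
    return rng.negative_binomial(r, r / (r + mu), shape)


def make_reads(spans, contig="c1", sample_prefix="r"):
    """AlignedReads from a list of (start, end) spans."""
    return [
        rs.AlignedRead(name=f"{sample_prefix}{i}", contig=contig, start=s, end=e, strand="+")
        for i, (s, e) in enumerate(spans)
    ]


@pytest.fixture(scope="session")
def small_experiment(tmp_path_factory):
    """One deep-coverage simulated experiment shared across tests.

    Small enough to segment and count quickly, deep enough (baseline 500)
    that every locus is fully tiled by called regions.
    """
    design = rs.SimDesign(
        n_features=30, n_orphans=6, baseline_mean=500, dispersion=0.1, seed=42
    )
    outdir = tmp_path_factory.mktemp("sim")
    manifest = rs.simulate_experiment(design, str(outdir))
    policy = rs.CountingPolicy()
    reads = {s: list(rs.read_alignments(p, policy)) for s, p in manifest["sam"].items()}
    manifest["reads"] = reads
    manifest["policy"] = policy
    manifest["track"] = rs.build_coverage(reads, manifest["genome"].contig_lengths)
    return manifest


@pytest.fixture(scope="session")
def discovery_run(tmp_path_factory):
    """Low-dispersion discovery experiment pushed through the full
    region-calling / consensus / triage chain (shared across tests)."""
    design = rs.SimDesign(
        n_features=25, n_orphans=6, baseline_mean=500, dispersion=0.02, seed=5
    )
    outdir = tmp_path_factory.mktemp("disc")
    manifest = rs.simulate_experiment(design, str(outdir))
    policy = rs.CountingPolicy()
    reads = {s: list(rs.read_alignments(p, policy)) for s, p in manifest["sam"].items()}
    track = rs.build_coverage(reads, manifest["genome"].contig_lengths)

    region_sets, region_de = {}, {}
    for name, seg in _default_panel().items():
        rset = rs.call_regions(track, seg)
        region_sets[name] = rset
        region_de[name] = run_de(
            rs.count_regions(rset, reads, policy), design.groups, DEParams()
        )
    consensus, membership = rs.consensus_regions(region_sets, 3, 0.5)
    ann = rs.load_annotation(manifest["gtf"])
    assignment = rs.assign_regions(consensus, ann, policy)
    abundance = rs.count_regions(consensus, reads, policy).mean(axis=1)
    locus_map = locus_for_regions(consensus, manifest["genome"])
    truth = manifest["truth"]
    exogenous = {
        rid: bool(truth.at[locus, "exogenous"]) if locus and locus.startswith("orphan") else False
        for rid, locus in locus_map.items()
    }
    candidates = rs.candidate_filter(
        consensus, membership, assignment, region_de, abundance, exogenous,
        rs.TriageParams(), missing_de="drop",
    )
    manifest.update(
        design=design, reads=reads, policy=policy, region_sets=region_sets,
        region_de=region_de, consensus=consensus, membership=membership,
        assignment=assignment, abundance=abundance, locus_map=locus_map,
        exogenous=exogenous, candidates=candidates,
    )
    return manifest
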