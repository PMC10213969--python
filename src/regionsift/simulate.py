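"""Synthetic small RNA-seq experiments with planted differential expression.

Generates a complete desk-scale experiment — random genome, gene annotation,
ground-truth fold changes, and per-sample aligned reads in SAM — emulating a
two-group small RNA-seq design: 22-nt reads, two groups of six samples, 20 %
of features upregulated two-fold and 20 % downregulated two-fold in the
treatment group, with negative-binomial count noise.  On top of the annotated
features the generator plants "orphan" loci that carry expression but appear
in no annotation, a fraction of which are flagged as exogenous contaminants;
these exercise the unannotated-biomarker discovery path.

All randomness flows from a single integer seed; a fixed design yields
byte-identical output files.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pysam
import yaml

__all__ = [
    "SimDesign",
    "GenomeModel",
    "DesignError",
    "SizingError",
    "build_genome",
    "assign_truth",
    "simulate_counts",
    "simulate_reads",
    "simulate_experiment",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class DesignError(ValueError):
    """An internally inconsistent simulation design."""


class SizingError(ValueError):
    """Requested loci do not fit on the contig."""


@dataclass
class SimDesign:
    """Parameters of one simulated two-group small RNA-seq experiment.

    ``fold_change`` is the linear treatment:control ratio planted in
    upregulated features (downregulated features get its reciprocal).
    ``dispersion`` is the NB dispersion phi with variance = mu + phi*mu**2;
    phi = 0 degenerates to Poisson counts.
    """

    n_samples_per_group: int = 6
    n_features: int = 100
    read_length: int = 22
    frac_up: float = 0.20
    frac_down: float = 0.20
    fold_change: float = 2.0
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    n_orphans: int = 10
    frac_orphan_exogenous: float = 0.5
    seed: int = 0
    contig_name: str = "sim1"
    contig_length: int | None = None  # None = auto-size to fit the layout
    feature_length_range: tuple[int, int] = (60, 300)
    orphan_length_range: tuple[int, int] = (60, 120)

    def validate(self) -> None:
        if self.frac_up + self.frac_down > 1:
            raise DesignError(
                f"frac_up + frac_down = {self.frac_up + self.frac_down:g} > 1"
            )
        if self.fold_change < 1:
            raise DesignError("fold_change must be >= 1 (use frac_down for decreases)")
        if self.read_length < 15:
            raise DesignError("read_length must be >= 15 nt")
        for name in ("n_samples_per_group", "n_features", "n_orphans"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if not 0 <= self.frac_orphan_exogenous <= 1:
            raise DesignError("frac_orphan_exogenous must be in [0, 1]")
        if self.feature_length_range[0] < self.read_length:
            raise DesignError(
                f"minimum feature length {self.feature_length_range[0]} is shorter "
                f"than the read length {self.read_length}"
            )
        if self.dispersion < 0 or self.baseline_mean < 0:
            raise DesignError("dispersion and baseline_mean must be >= 0")

    @property
    def sample_names(self) -> list[str]:
        n = self.n_samples_per_group
        return [f"ctrl{i + 1}" for i in range(n)] + [f"treat{i + 1}" for i in range(n)]

    @property
    def groups(self) -> list[int]:
        """Group label per sample: 1 = control, 2 = treatment."""
        n = self.n_samples_per_group
        return [1] * n + [2] * n


@dataclass
class GenomeModel:
    """A synthetic genome: contig sequences plus feature and orphan layout.

    Coordinates are 0-based half-open.  Features never overlap and are
    separated by at least one read length of intergenic spacer; orphan loci
    live in that intergenic space and overlap no feature.
    """

    contigs: dict[str, str]
    features: list[tuple[str, str, int, int, str]] = field(default_factory=list)
    orphan_loci: list[tuple[str, str, int, int, bool]] = field(default_factory=list)

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}


def _rng(design: SimDesign, stream: int) -> np.random.Generator:
    # independent, reproducible streams per simulation stage
    return np.random.default_rng(np.random.SeedSequence([design.seed, stream]))


def build_genome(design: SimDesign) -> GenomeModel:
    """Lay out features and orphan loci left-to-right on one random contig.

    Loci are placed in a seeded random order with intergenic spacers of at
    least ``read_length`` bases, so every locus hosts full-length reads and
    no read can straddle two loci.
    """
    design.validate()
    rng = _rng(design, 0)

    lo, hi = design.feature_length_range
    feat_lens = rng.integers(lo, hi + 1, size=design.n_features)
    olo, ohi = design.orphan_length_range
    orph_lens = rng.integers(olo, ohi + 1, size=design.n_orphans)

    # interleave features and orphans in a seeded order
    kinds = ["f"] * design.n_features + ["o"] * design.n_orphans
    order = rng.permutation(len(kinds))

    pos = 0
    features: list[tuple[str, str, int, int, str]] = []
    orphans: list[tuple[str, str, int, int, bool]] = []
    fi = oi = 0
    for idx in order:
        spacer = design.read_length + int(rng.integers(10, 51))
        pos += spacer
        if kinds[idx] == "f":
            length = int(feat_lens[fi])
            fid = f"gene{fi + 1:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            features.append((fid, design.contig_name, pos, pos + length, strand))
            fi += 1
        else:
            length = int(orph_lens[oi])
            oid = f"orphan{oi + 1:03d}"
            orphans.append((oid, design.contig_name, pos, pos + length, False))
            oi += 1
        pos += length
    pos += design.read_length  # trailing spacer

    total = design.contig_length if design.contig_length is not None else pos
    if total < pos:
        raise SizingError(
            f"contig_length={total} too short: layout of {design.n_features} "
            f"features + {design.n_orphans} orphans needs {pos} bases "
            f"(short by {pos - total})"
        )
    seq = rng.choice(_BASES, size=total).tobytes().decode("ascii")

    features.sort(key=lambda f: f[2])
    orphans.sort(key=lambda o: o[2])
    return GenomeModel(
        contigs={design.contig_name: seq}, features=features, orphan_loci=orphans
    )


def assign_truth(design: SimDesign, genome: GenomeModel):
    """Plant fold changes: floor(frac_up*n) features up, floor(frac_down*n) down.

    The up/down assignment is a seeded permutation of the feature list;
    leftover fractional features are never planted.  All orphan loci are
    planted as upregulated at the design fold change — the discovery use case
    is loci overexpressed in the treatment group — and the first
    floor(frac_orphan_exogenous * n_orphans) orphans of a second seeded
    permutation carry the exogenous flag.

    Returns a pandas DataFrame indexed by locus ID with columns
    ``kind`` (feature/orphan), ``de_class`` (up/down/unchanged), ``fold_change``
    (linear, treatment vs control), ``exogenous``, ``mean_control``,
    ``mean_treatment``.
    """
    import pandas as pd

    design.validate()
    n = design.n_features
    n_up = math.floor(design.frac_up * n)
    n_down = math.floor(design.frac_down * n)

    rng = _rng(design, 1)
    perm = rng.permutation(n)
    classes = np.full(n, "unchanged", dtype=object)
    classes[perm[:n_up]] = "up"
    classes[perm[n_up:n_up + n_down]] = "down"

    n_exo = math.floor(design.frac_orphan_exogenous * design.n_orphans)
    operm = rng.permutation(design.n_orphans)
    exo = np.zeros(design.n_orphans, dtype=bool)
    exo[operm[:n_exo]] = True

    rows = []
    for (fid, *_), cls in zip(genome.features, classes):
        if cls == "up":
            fc = design.fold_change
        elif cls == "down":
            fc = 1.0 / design.fold_change
        else:
            fc = 1.0
        rows.append((fid, "feature", cls, fc, False))
    for (oid, *_), is_exo in zip(genome.orphan_loci, exo):
        rows.append((oid, "orphan", "up", design.fold_change, bool(is_exo)))

    truth = pd.DataFrame(
        rows, columns=["id", "kind", "de_class", "fold_change", "exogenous"]
    ).set_index("id")
    truth["mean_control"] = design.baseline_mean
    truth["mean_treatment"] = design.baseline_mean * truth["fold_change"]
    return truth


def _nb_draw(rng: np.random.Generator, mean: float, phi: float, size: int):
    """NB(mean, dispersion phi) with variance mu + phi*mu^2; phi=0 -> Poisson."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if phi == 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_counts(design: SimDesign, truth) -> "pd.DataFrame":
    """Draw the per-locus, per-sample read counts of the experiment.

    Cell (locus, sample) ~ NB(mean = mean_control or mean_treatment by the
    sample's group, dispersion = design.dispersion), independently.
    """
    import pandas as pd

    rng = _rng(design, 2)
    groups = design.groups
    counts = np.zeros((len(truth), len(groups)), dtype=np.int64)
    for i, (_, row) in enumerate(truth.iterrows()):
        for j, g in enumerate(groups):
            mu = row["mean_control"] if g == 1 else row["mean_treatment"]
            counts[i, j] = _nb_draw(rng, mu, design.dispersion, 1)[0]
    return pd.DataFrame(counts, index=truth.index, columns=design.sample_names)


def _sam_header(genome: GenomeModel) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": length}
                for name, length in genome.contig_lengths.items()
            ],
        }
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_reads(
    genome: GenomeModel, truth, design: SimDesign, outdir: str
) -> dict[str, str]:
    """Emit one coordinate-sorted SAM per sample with reads placed in loci.

    For every locus and sample the count drawn by :func:`simulate_counts` is
    realized as that many full-length reads placed uniformly at random fully
    inside the locus, on a uniformly random strand.  Reads are exact genome
    substrings (no sequencing-error model) with full-match CIGAR.

    Returns a mapping sample name -> SAM path.
    """
    counts = simulate_counts(design, truth)
    rng = _rng(design, 3)
    os.makedirs(outdir, exist_ok=True)
    header = _sam_header(genome)

    loci = {fid: (c, s, e) for fid, c, s, e, _ in genome.features}
    loci.update({oid: (c, s, e) for oid, c, s, e, _ in genome.orphan_loci})
    L = design.read_length

    sam_paths: dict[str, str] = {}
    for sample in design.sample_names:
        records = []
        for locus_id, (contig, start, end) in loci.items():
            if end - start < L:
                raise SizingError(
                    f"locus {locus_id} ({end - start} nt) shorter than the "
                    f"read length {L}"
                )
            k = int(counts.at[locus_id, sample])
            if k == 0:
                continue
            starts = start + rng.integers(0, end - start - L + 1, size=k)
            rev = rng.random(k) < 0.5
            for r, (pos, is_rev) in enumerate(zip(starts, rev)):
                records.append((contig, int(pos), bool(is_rev), f"{sample}:{locus_id}:{r}"))
        records.sort(key=lambda t: (t[0], t[1], t[3]))

        path = os.path.join(outdir, f"{sample}.sam")
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for contig, pos, is_rev, name in records:
                a = pysam.AlignedSegment(header)
                a.query_name = name
                a.reference_id = header.get_tid(contig)
                a.reference_start = pos
                a.mapping_quality = 42
                a.cigarstring = f"{L}M"
                a.flag = 16 if is_rev else 0
                seq = genome.contigs[contig][pos:pos + L]
                a.query_sequence = _revcomp(seq) if is_rev else seq
                out.write(a)
        sam_paths[sample] = path
    return sam_paths


def locus_for_regions(regions, genome: GenomeModel):
    """Map each called region to the simulated locus it falls in, if any.

    Returns a dict region_id -> locus_id (feature or orphan) for regions
    overlapping exactly one simulated locus; regions in intergenic space map
    to None.  Useful for scoring region callers against the planted layout
    and for deriving exogenous-flag tables keyed by region ID.
    """
    loci = [(fid, c, s, e) for fid, c, s, e, _ in genome.features]
    loci += [(oid, c, s, e) for oid, c, s, e, _ in genome.orphan_loci]
    out = {}
    for region in regions:
        hit = None
        for lid, contig, s, e in loci:
            if contig == region.contig and region.start < e and s < region.end:
                hit = lid
                break  # loci are disjoint; at most one can overlap
        out[region.region_id] = hit
    return out


def write_fasta(genome: GenomeModel, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(genome: GenomeModel, path: str, source: str = "regionsift_sim") -> None:
    """Write the feature annotation as gene-kind GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for fid, contig, start, end, strand in genome.features:
            attrs = f'gene_id "{fid}"; gene_type "sim_small_rna";'
            fh.write(
                f"{contig}\t{source}\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )


def simulate_experiment(design: SimDesign, outdir: str) -> dict[str, object]:
    """Run the full generator: genome, annotation, truth, SAMs, design echo.

    Returns a manifest dict with the genome/truth objects and all file paths.
    """
    genome = build_genome(design)
    truth = assign_truth(design, genome)
    os.makedirs(outdir, exist_ok=True)

    fasta = os.path.join(outdir, "genome.fa")
    gtf = os.path.join(outdir, "annotation.gtf")
    truth_tsv = os.path.join(outdir, "truth.tsv")
    design_yaml = os.path.join(outdir, "design.yaml")

    write_fasta(genome, fasta)
    write_gtf(genome, gtf)
    truth.to_csv(truth_tsv, sep="\t")
    with open(design_yaml, "w") as fh:
        yaml.safe_dump(asdict(design), fh, sort_keys=True)
    sam_paths = simulate_reads(genome, truth, design, outdir)

    return {
        "design": design,
        "genome": genome,
        "truth": truth,
        "fasta": fasta,
        "gtf": gtf,
        "truth_tsv": truth_tsv,
        "design_yaml": design_yaml,
        "sam": sam_paths,
    }
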