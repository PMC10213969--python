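# Methods

This note documents the models, defaults and numerical choices behind
`regionsift`, and what the simulator does and does not emulate.

## The find-then-annotate model

The package treats "expression" as a property of genomic intervals, not of
annotated genes. Per-base depth is accumulated per sample from SAM/BAM
alignments (span = POS plus CIGAR reference consumption; soft clips consume
nothing) and pooled across samples. Segmentation operates on the pooled
track only: one consistent region set per experiment, rather than
per-sample region sets that would then need reconciling. A region is a
maximal run of pooled depth ≥ `cutoff`, after bridging sub-cutoff gaps of ≤
`max_gap` bases and discarding runs shorter than `min_length`.

Defaults: `cutoff = 1` (any covered base is potentially expressed, matching
the permissive mincov-1 style of small RNA region callers), `max_gap = 0`,
`min_length = 18` nt. The length floor is set just below the mature miRNA
length (~22 nt) so the most abundant EV species always pass; no published
value exists for this knob, and it is exposed as a parameter.

Annotation is applied only afterwards. Each region is assigned to the
overlapping gene with the largest overlap, provided the overlap reaches the
counting policy's `min_overlap` (default 5 bases); ties break to the
lexicographically smallest gene ID — a deterministic artifact decision, as
largest-overlap assignment needs *some* total order and no convention is
standard. Assignment is region-level: the region's entire count vector goes
to its winning gene. Regions with no qualifying overlap are `UNANNOTATED`
and flow to the discovery branch instead of being discarded.

The counting policy mirrors established small RNA practice: PCR/optical
duplicates dropped, secondary alignments (multi-mappers) counted, records
(not distinct query names) counted, strand ignored. A read overlapping k
intervals by ≥ `min_overlap` counts toward all k.

## Differential expression

The DE module is a self-contained exact-test pipeline for two groups:

1. **Low-count filter** — keep rows with ≥ `min_count` in ≥ `min_samples`
   samples (defaults 1 and 2).
2. **TMM** — the reference sample is the one whose upper quartile of
   library-scaled counts is closest to the mean upper quartile. M (log2
   ratio) and A (mean log2 abundance) values are computed over genes
   positive in both sample and reference; the extreme 30 % of M and 5 % of
   A are trimmed and the factor is `2**mean(M)` (unweighted). Factors are
   rescaled to zero log-sum, so they carry compositional differences only.
3. **Common dispersion** — counts are scaled to the geometric mean of
   effective library sizes; per row and group the moment estimate
   `(s² − m)/m²` of φ is formed (variance = μ + φμ²), averaged over the two
   groups, floored at 0, and the median over rows is taken. The estimator
   is deliberately simple and validated by simulation recovery: it returns
   ≈ 0 on Poisson data and recovers φ = 0.4 to within the tested band at
   n = 6 + 6, and the resulting test is calibrated (see below). It is
   median-biased slightly low at high φ; the exact test's discreteness is
   mildly conservative, and the two effects roughly offset at the
   dispersions the simulator produces.
4. **Exact NB test** — each sample is linearly rescaled to the common
   effective library size and summed within its group. (The classic
   construction adjusts quantiles for unequal group sizes; linear scaling
   is an approximation, adequate here because group sizes are equal in the
   target design.) Conditional on the row total t, the group-1 sum follows
   the distribution ∝ `NB(k; n₁μ̂, n₁/φ) · NB(t−k; n₂μ̂, n₂/φ)` with
   `μ̂ = t/(n₁+n₂)`; the two-sided p-value sums the probabilities of all
   outcomes no more likely than the observed one. Outcomes with mass ≤
   observed × (1 + 1e−8) are included so floating-point noise can never
   exclude the observed outcome from its own tail. At φ = 0 the kernel is
   binomial and the test is the exact two-sided binomial test. The full
   conditional distribution 0..t is enumerated; at desk scale (t up to
   ~10⁵) this is exact and fast, and no saddlepoint fallback is provided.
5. **log2FC and FDR** — fold changes are `log2((m₂+c)/(m₁+c))` on
   pseudo-count group means with prior `c = 0.5`; the prior stabilizes the
   estimate only and never enters the test. Benjamini–Hochberg adjustment
   is delegated to statsmodels.

Group direction is fixed by sorted label order (group 2 vs group 1), so
relabeling groups negates log2FC and leaves p-values unchanged.

## Consensus triage

Regions from multiple callers are matched by reciprocal overlap ≥ 0.5
(default): exact-coordinate matching would be brittle across callers whose
boundaries differ by a few bases. Matching is transitive; each connected
component supported by ≥ `min_tools` distinct callers contributes one
consensus interval, the intersection of its members' spans (components
whose spans have an empty common intersection are dropped). Candidates
must then be unannotated, non-exogenous, ≥ 21 nt (strictly more than 20),
mean normalized abundance ≥ 10 (a default standing in for "highly
abundant"; no published threshold exists), and FDR < α = 0.1 in every
supporting caller — α is deliberately permissive because triage feeds
wet-lab validation, which is the real false-positive filter. Candidates are
ranked by worst-caller FDR. Exogenous screening is consumed as a flag table
(region → boolean); producing it (e.g. by BLAST against microbial genomes)
is outside the package's scope.

When a supporting caller has no DE row for a consensus region, the strict
behaviour is a consistency error; the pipeline instead passes
`missing_de="drop"`, since upstream low-count filtering legitimately
removes rows and such a region simply fails the significance criterion.

## The simulator

`SimDesign` defaults encode the canonical benchmark design: two groups of
6 samples, 22-nt reads, 20 % of features planted 2-fold up and 20 % 2-fold
down in treatment, NB counts with variance μ + φμ². The planted counts are
`floor(frac·n)`; fractional leftovers are never planted, which keeps the
realized fractions deterministic. Values the design leaves open were fixed
once as field-realistic choices: baseline mean 100 counts per feature,
φ = 0.1 (a typical bulk RNA-seq biological dispersion), 100 features, 10
orphan loci, feature lengths 60–300 nt, orphan lengths 60–120 nt, and half
of orphans flagged exogenous (surveys of unannotated EV small RNA find
roughly half of such regions also map to exogenous genomes). All orphan
loci are planted as upregulated at the design fold change, since the
discovery use case is loci overexpressed in the disease group.

The genome is a single random contig laid out left-to-right with features
and orphans in seeded random order, separated by intergenic spacers of at
least one read length — so every read falls entirely within exactly one
locus and a called region can never straddle two. Reads are exact genome
substrings (no sequencing-error or quality model: the analysis consumes
alignments, so base errors would exercise nothing), placed uniformly within
their locus on a random strand, and emitted as coordinate-sorted SAM.
Identical designs produce byte-identical outputs.

What the simulator does **not** emulate: transcript-level fragment
distributions, adapter/quality artifacts, multi-mapping reads (every read
has a unique origin), overlapping genes, chimeric or spliced alignments,
and library-size imbalance beyond what count noise induces. Passing tests
therefore demonstrate the correctness of segmentation, counting,
assignment, testing and triage logic — not robustness to alignment
ambiguity or annotation pathologies in real data.

## Test and verification scale

The verification suite runs everything at desk scale, chosen so the full
suite completes in a few minutes: segmentation is checked against a naive
per-base oracle on 500 random tracks; DE calibration uses 2000-row
matrices at n = 6 + 6 (type-I error in [0.03, 0.07] at p < 0.05; planted
2-fold recovery with mean |log2FC| within [0.8, 1.2], sensitivity ≥ 0.8,
specificity ≥ 0.9 at FDR < 0.05); the find-then-annotate equivalence uses
a deep-coverage simulation (baseline 500) where called regions tile every
locus, making region-sum and direct gene counts identical cell-for-cell
and their per-gene log2FC correlate at r ≥ 0.95.

The end-to-end discovery check (every planted non-exogenous orphan
recovered, no annotated gene admitted) runs at φ = 0.02 and baseline 500.
At the generator's default φ = 0.1, a 2-fold locus occasionally *realizes*
a near-null fold in a 6 + 6 draw — no test could then call it, and "all
orphans recovered" would fail for reasons unrelated to the pipeline. Power
under the default noise is measured separately (the sensitivity figures
above); the low-dispersion discovery run isolates what it is meant to
verify: the consensus matching, annotation exclusion and exogenous
exclusion wiring.

## Known limitations

- One dispersion for all rows (no tagwise/trended shrinkage, no GLMs or
  covariates); adequate for the simulator's homogeneous φ, optimistic for
  heterogeneous real data.
- The unequal-group-size quantile adjustment is approximated linearly;
  with markedly unbalanced groups the exact test loses some accuracy.
- Region calling is unstranded and threshold-based; HMM-style callers can
  split adjacent loci that a threshold merges.
- The consensus interval is the intersection of matched spans, which can be
  conservative when callers disagree about boundaries.
- BAM is accepted wherever SAM is, but CRAM and paired-end mate resolution
  are not supported (small RNA libraries are single-end).
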