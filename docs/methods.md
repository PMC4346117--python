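# Methods

This note documents the models, defaults and numerical conventions behind
`heteroclone`, and what the simulation-based tests do and do not establish.

## Binary mutation matrix

Calls are reduced to presence/absence per (sample, locus); a locus is
identified by (chrom, pos, ref, alt), so two substitutions at one position
are distinct loci, and indels (len(ref) ≠ len(alt)) are accepted as
ordinary loci — downstream arithmetic is identical. Coordinates are 1-based
inclusive everywhere (mutation tables, SEG, harmonized regions); chromosome
labels are opaque strings and never normalized. Effect filtering removes
{synonymous, intronic, intergenic, near-gene}; unknown effect strings are
retained and logged rather than dropped, since filtering should never
silently shrink a call set. Presence filtering keeps loci with at least one
call among the tumor samples; normal samples may be carried as all-zero
rows for tree rooting (off by default).

## Distance and trees

The sample distance is 1 − Pearson correlation of row profiles, computed
over all retained columns. Columns present in every sample (trunk loci) are
deliberately *kept*: they shift row means and hence the correlations, and
the discovery matrix that defines the method retains them. A constant row
(e.g. an all-zero normal against a fully presence-filtered matrix) has no
defined correlation and raises an error naming the sample, rather than
propagating NaN. Output distances are clipped to [0, 2] against rounding.

Neighbor-Joining follows Saitou–Nei exactly: join the pair minimizing
Q(i,j) = (n−2)d(i,j) − Σ<sub>k</sub>d(i,k) − Σ<sub>k</sub>d(j,k), standard
branch-length formulas, distances to the new node by the reduction formula.
Negative branch lengths are kept (faithful to the algorithm); the tree is
unrooted and serialized with a trifurcating root. UPGMA uses size-weighted
average linkage with node height d/2, which makes the output ultrametric by
construction and reproduces an ultrametric input's cophenetic matrix
exactly. In both algorithms, ties in the merge criterion are broken by the
lexicographically smallest (min-leaf, min-leaf) label pair, with a 1e-12
comparison tolerance, so results are deterministic across platforms and
label orderings. Tree cutting opens the k−1 highest internal nodes of the
rooted UPGMA tree (the standard maxclust dendrogram cut); equal-height ties
go to the node with the smallest leaf label.

The test suite checks NJ against the additivity property (on 200 random
additive matrices the path metric must equal the input to 1e-9 — for an
additive metric this identifies topology and lengths uniquely) and against
scikit-bio's NJ on noisy matrices (Robinson–Foulds 0 via dendropy); UPGMA
is checked against scipy's average-linkage cophenetic matrix. These
reference implementations appear only in tests, never in the pipeline.

## Mutation classification

Cluster presence uses per-cluster support thresholds; the default
max(2, ⌈|c|/2⌉) reproduces the 3-of-P1 / 2-of-P2 / 2-of-M rule at cluster
sizes 6/2/3 and is overridable per cluster in the YAML config. Labels:
Common = present in all clusters; Shared = in ≥ 2 but not all (the cluster
set is recorded, so with three clusters this is exactly "any two");
Cluster-specific = exactly one; Sample-specific = below every cluster
threshold, even if raw calls touch scattered samples of several clusters.
Label rank is monotone in the number of present clusters (tested).

Damaging-prediction votes are consumed, not computed: a vote is
n_damaging/n_available over the prediction algorithms applicable to the
change; stop-gains have no applicable algorithm and report N/A.

Allele-fraction fold changes normalize each sample's deep-sequencing AFs by
that sample's mean AF over validated somatic loci (a per-sample purity
correction) before comparing cluster means. The alternative normalization
(per-locus mean over samples) is a defensible reading of "normalized to the
mean allele frequency"; per-sample was chosen because it corrects exactly
the nuisance (purity/ploidy differences between samples) that motivates
normalizing at all. Fold changes use arithmetic means; a zero comparator
yields an infinity sentinel rather than an exception.

## Copy-number weighting and consensus

Segments are made comparable across samples by partitioning each chromosome
at the union of all samples' breakpoints and propagating each sample's
log2 value onto the sub-intervals it covers; uncovered sub-intervals score
0 with a logged count. Alteration calls are boundary-inclusive
(δ = +1 at log₂ ≥ 0.2, −1 at ≤ −0.2) — symmetric and conservative, since
segments at exactly the cutoff were segmented as altered upstream. The
weight is δ·max(log₁₀ L, 1); the floor keeps every altered region's weight
magnitude ≥ 1 regardless of length. Only regions altered in at least one
sample become tree columns; neutral-everywhere columns carry no signal and
would only dilute the correlation.

Cluster consensus requires unanimity (all members amplified, or all
deleted); any mixture makes the cluster discordant, and discordant clusters
are excluded from the agreement count rather than treated as neutral — the
closest reading of "neglected". Region labels: Common when every cluster
shares one non-neutral status; Shared when a proper subset of ≥ 2 does
(with > 3 clusters an equal-size amplified/deleted tie goes to amplified);
Specific when exactly one cluster is non-neutral. Span summaries count each
harmonized region once and do not merge adjacent same-label regions —
with per-sample breakpoint unions there is no canonical merged segment, so
the convention is stated rather than hidden.

## Validation statistics

The unit of evaluation is the (locus, sample) pair: a locus called in one
sample is a negative test in every other assayed sample. This is the only
reading under which a ~93% precision and a ~1% false-positive rate can
coexist — most assayed pairs are true negatives. Assessability requires
≥ 500 deep reads in both tumor and normal; validated-somatic requires deep
tumor AF strictly > 5% (a pair at exactly 5% is assessable but negative).
The normal-tissue data enters only through the depth filter; no normal-AF
threshold is applied. FPR uses validated-negative pairs as its denominator.
Undefined rates (empty denominators) are reported as N/A, never as 0.

## Simulator

The generator emulates a multi-region serous ovarian carcinoma with
transcoelomic spread:

- **Design.** Three clusters on a ladder tree ((P1, M), P2) — two primary
  clusters that diverged early, and a metastatic cluster branching late
  from P1's ancestor — with 6/3/2 samples. Mutation budgets: 19 common,
  82 shared(P1, M), 39/11/54 cluster-specific (P1/M/P2), 10 private per
  sample. These sit near the observed group counts of the motivating case
  but are a simulation design, not a claim about the generative truth.
- **VAF model.** Diploid heterozygous and clonal within carriers:
  VAF = purity × cell fraction / 2, with purity 0.7 (pathology floor of
  the motivating case) and cell fraction 1 — so 0.35 at every present
  locus. Subclonal fractions, CN-altered loci and contamination are not
  modeled.
- **Noise.** Each true presence drops out independently with probability
  fn_rate = 0.06. False positives arise at fp_rate = 0.01 per truth-absent
  (sample, candidate-locus) pair, where the candidate universe is the true
  loci plus a decoy pool of artifact-prone sites. Flipping truth-absent
  pairs of real loci (not only decoys) keeps the false-positive process
  and the FPR denominator on the same universe, which is what makes the
  measured FPR an unbiased estimate of fp_rate; planted categories remain
  exactly defined because truth is stored separately from observations.
- **Decoy pool size (740).** The three jointly reported discovery-quality
  rates (precision 93%, FNR 6%, FPR 1%) imply a negative:positive pair
  ratio of ≈ 7.1 in the validation assay (0.94·P/(0.94·P + 0.01·N) = 0.93
  ⇒ N ≈ 7.08·P). With the default budgets the positives number 1,432
  pairs and the true loci contribute 2,033 negatives, so the pool adds
  (7.08·1432 − 2033)/11 ≈ 737 loci, rounded to 740. This is derived from
  the printed rates once, not fitted to test outcomes.
- **Validation assay.** The deep panel covers the full candidate universe
  at Poisson(9,647×) tumor and normal depth, binomial alt reads at the
  true VAF with a 0.1% sequencing-error floor. Absent loci therefore sit
  far below the 5% AF threshold, so assay error is negligible relative to
  discovery error — the regime the depth was chosen for.
- **CNAs.** Each branch of the cluster tree (trunk, internal clades, one
  per cluster) carries 4 segments of 2–20 Mb, amplification or deletion
  with equal probability, placed without overlap genome-wide on hg19
  chromosome lengths rounded to the Mb; carriers get log₂ +0.58 (one copy
  gained at purity 1) or −1.0 (one copy lost), other samples 0, with
  neutral gap segments completing each chromosome. Segment-level noise is
  not modeled; the SCNA recovery tests are therefore exact-recovery tests
  of the weighting/consensus/labeling logic, not of robustness to
  segmentation error.
- **Reproducibility.** All draws flow from one integer seed through
  per-stage child generators (`default_rng([seed, stage])`); identical
  parameters give byte-identical outputs.

**What passing tests show.** Partition recovery (100/100 seeds at default
conditions) and ~95% label accuracy demonstrate that the pipeline's
algorithms recover a planted truth under the stated noise model. Real
tumors add alignment artifacts, subclonality, copy-number-driven VAF
distortion and purity variation that the generator does not emulate, so
these numbers bound the method's behavior under its own assumptions, not
its field performance.

## Problem sizes

The recovery studies use 100 simulated patients of 11 samples × ~1,050
candidate loci each, and validation concordance uses ~11,600 assessable
pairs — large enough for the 99% binomial intervals on the 6%/1% rates to
be a few tenths of a percentage point wide, and small enough that the whole
suite runs in well under a minute per study on one CPU.

## Known limitations

- NJ is O(n⁴) as implemented (exact, deterministic tie-breaking was
  prioritized over speed); fine for tens of samples, not for hundreds.
- `cut_clusters` requires the rooted ultrametric UPGMA tree; NJ trees are
  for reporting, matching the pipeline's division of labor.
- The VCF reader is deliberately minimal (GT/AD/DP, first ANN/CSQ effect);
  it is not a general-purpose VCF toolkit.
- Multi-allelic records are split into per-allele calls; phasing, SVs and
  BND records are out of scope.
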