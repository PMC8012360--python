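# Methods

## Motif model and scanning

A motif is a position weight matrix (PWM) of per-position base
probabilities `p_i(b)`, scored against a window `x` by the natural-log
likelihood ratio versus a uniform background,
`S(x) = Σ_i ln(p_i(x_i)/0.25)`. Both strands are scanned at every
offset; a minus-strand hit is the score of the reverse-complemented
window, reported at its forward offset. A hit is any offset with
`S ≥ T`, the motif's detection threshold, read from the motif file.
Overlapping hits are all retained; for site-level presence/absence they
are deduplicated by (interval, strand). Windows containing non-ACGT
characters are skipped rather than partially scored. Degenerate
consensus motifs over `{A,C,G,T,N}` are matched exactly (N wildcards),
again on both strands.

Numerical conventions: natural log with uniform 0.25 background (motif
file thresholds are interpreted on the same scale); a pseudocount of
1e-3 per cell, followed by renormalization, whenever a parsed matrix
contains zeros (prevents −∞ scores); matrix rows off unity by ≤ 1e-3
are renormalized with a warning, larger deviations are parse errors
naming the offending line.

## Four-way classification, correction, rescue

Each peak's own breadth (start–end, not the summit±1 kb window used for
aggregate profiles — the two windows are distinct and both implemented)
is scanned with three PWMs: a well-defined full GRE, a degenerate
(relaxed) full GRE, and a half-GRE. Full hits are the union of the two
full models. Presence/absence of full and half hits gives the four-way
class {full_only, half_only, both, none}.

**Overlap correction.** The half-GRE model re-detects single arms of
genuine full GREs. A half hit is *explained* when the interval of its
ACA/TGT core trinucleotide (pattern positions 3–5 of the 8-bp half
model; strand-mapped to forward coordinates) intersects by at least
1 bp either terminal hexamer `[s, s+6)` or `[e−6, e)` of any full hit.
A `both` site becomes `full_only` (flag `corrected`) only when *every*
half hit is explained — a conservative site-wise rule that keeps `both`
whenever an independent half-site remains. Two stricter variants are
available behind flags: full containment of the core in the arm, and
required strand concordance between the half hit and the full hit.
The correction is idempotent and never increases the number of
half-containing sites.

**Degenerate rescue.** `half_only` sites are rescanned with a
configurable list of relaxed full-site consensus patterns. Two presets
ship: `results_acannntnt` (`ACAnnnTnT`) and `methods_agann_set`
(`AGAnnnTnn`, `AGAnnnnGn`, `AGAnnnnnT`, `AGAnnnTnT`, `AGAnnnTGn`,
`AGAnnnnGT`); the two spellings circulate for this analysis and both
are provided, with the `ACAnnnTnT` form as default since it is the one
quoted with the worked example counts. A site is `rescued` when any
pattern matches within its breadth. Cluster-level adjusted half-site
percentage: `100·(h − r)/n` (h half-only, r rescued, n sites), reported
both exact and integer-rounded (half away from zero, the printed
style).

## Peak operations

Coordinates are 0-based half-open (BED) throughout; summits are
absolute. Depth normalization scales counts to 10 million mapped reads
(`count · 1e7 / total`). Aggregate profiles bin summit-relative event
offsets in ±1 kb windows at 10 or 20 bp and report events per site per
bp; total mass is conserved exactly.

The peak filter chain keeps a candidate iff raw tags > 75, fold change
over the depth-matched control > 4, fold change over the local
background > 4, and Benjamini–Hochberg-adjusted Poisson upper-tail
p-value < 0.001 with λ the depth-matched control count. BH is computed
over the candidate set (the upstream tool's internal FDR procedure is
unspecified; BH is the standard choice and is logged). Fold-change
denominators are floored at one tag. The differential test between
receptors uses `FC = a_norm/(b_norm + 1)` and the Poisson tail
`P(X ≥ a | λ = b·total_a/total_b)`, flagging FC > 4 and p < 1e-4.

Cluster assignment on a union peak set: C4 if called in all three
receptors; C3 if called in GRdim but not GRwt; among peaks called in
GRwt, C1 when the GRwt-over-GRdim differential flag is set, else C2.
Peaks called nowhere (or in GRmon alone, a case the cluster definitions
do not cover) are excluded with a warning. Gene association takes the
nearest TSS by |summit − TSS| with deterministic tie-breaks (smaller
coordinate, then lexicographic id). Genomic-region annotation evaluates
the summit with precedence promoter (−1000/+100 around the TSS,
strand-aware) > misc (exon/UTR/ncRNA) > intron > intergenic. Distances
are edge-to-edge with 0 for overlap.

## Modified RUVg

Given a genes × samples count matrix: genes are kept when more than 15
reads appear in at least two samples (strict inequality). Size factors
are median-of-ratios (per-gene geometric means over samples, genes with
any zero excluded from the reference). The unwanted-factor estimate is
the SVD of the per-gene-centered `ln(normalized + 1)` matrix restricted
to empirical control genes; `W` collects the sample-space singular
vectors at the requested 1-based ranks, default (1, 4) for k = 2.
Signs are fixed so each column's largest-magnitude entry is positive
(reproducible across SVD backends); columns are unscaled singular
vectors by default with a singular-value-scaled variant behind a flag.
Requesting a rank beyond the matrix rank is an explicit error. The
exported design matrix is (intercept, condition indicator, W columns),
with a rank-deficiency warning (condition number included) when W is
collinear with the condition. `adjust_log_counts` residualizes the
centered log expression on W for visualization. The choice of ranks
(1, 4) is exposed as data, not hard-coded: the skipped middle components
presumably carry wanted treatment variation, but the estimator makes no
such inference itself.

## Synthetic data: what it emulates and what it does not

The generator plants verified motif configurations: background windows
are rejection-sampled to contain no hit of any provided motif (the two
full models, the half model, and the rescue consensus list), class
inserts are added, and the assembled window is re-scanned so that its
noise-free classification equals the intended class by construction.
Full-GRE inserts are sampled from the PWM and rejected until they reach
the detection threshold. Half-site inserts are the half-model consensus
(with random bases at N positions): sampling short half-sites from the
PWM conditional only on reaching the threshold concentrates instances
near the threshold, where the planted truth label itself would be
ambiguous under mutation. An optional `motif_mutation_rate` applies
per-base substitutions to planted motif bases only.

The shipped motif set is **synthetic** — constructed from the canonical
GRE architecture, not the published matrices: a 15-bp full GRE
`AGAACAnnnTGTTCT` with 12 informative positions at probability 0.9
(threshold 8.0), a relaxed degenerate version at probability 0.65
(threshold 4.6, tolerating ~4 mismatches — the backup that catches
mutated full sites), and an 8-bp half-site `AGAACAnn` with 6
informative positions (threshold 4.3, tolerating one mismatch). These
tolerances were chosen from the mismatch arithmetic so that a 5%
per-base mutation rate leaves ≥ 95% of planted sites correctly
classified, which the recovery tests confirm.

Tag counts follow negative-binomial draws (`Var = μ + φμ²`, default
φ = 0.1, a typical bulk-sequencing scale) from receptor templates at
10M depth: C1 (GRwt 400, GRdim 15, GRmon 5), C2 (300/300/5), C3
(5/300/5), C4 (300/300/250). Templates were set so that called/not
called and differential decisions are several standard deviations from
their thresholds. Count matrices follow
`μ_gj = s_j q_g exp(x_j β_g + (Wα)_jg)` with two orthonormal planted
unwanted factors, orthogonal to both intercept and condition, with
*distinct* per-factor loading scales (sd 0.9 and 0.5): equal scales
would make the signal singular values near-degenerate and the
individual factors unidentifiable up to rotation. A configurable
fraction of genes (default 10%) carries treatment effects
β ~ N(0, 1); β = 0 genes are flagged as empirical controls. Effect
sizes are module parameters, not inferences about any particular
dataset.

Known limitations — what passing tests do and do not show:

* The half-site model is short; random windows at realistic GC content
  match it at a much higher rate than a real, longer half-site matrix
  matches accessible chromatin. Background class percentages from the
  generator are therefore not comparable to published background rates;
  no test or target depends on them.
* Planted peaks are uniformly sized, evenly spaced (≥ peak width apart,
  avoiding nearest-feature ties) and strand-unbiased; real peak
  geometry, copy number and mappability structure are not modeled.
* Tag counts are exchangeable NB draws per template; no fragment-length,
  duplicate or positional model. Read-level simulation is out of scope.
* Genome-scale published numbers (cluster memberships, 79%-of-6067
  partitions, misclassified-site counts) depend on the external ChIP
  data and genome and are not reproduced; the desk-scale checks cover
  the printed worked-example arithmetic and oracle/recovery properties.

## Problem sizes and determinism

Recovery suites use 800 planted sites (200 per class) for
classification, 1000 candidates for filter/differential oracles, and
2000 genes × 12 samples at dispersion 0.1 for the RUV track — sizes at
which every statistical margin computed above is several SD wide while
the whole suite stays fast. All randomness flows through seeded
`numpy.random.Generator` instances; identical spec + seed reproduces
FASTA, tables and reports byte-identically, and every written table
carries the configuration hash.
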