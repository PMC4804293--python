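# Methods

`cnvpopgen` implements a copy-number-variation (CNV) population-genetics
pipeline for SNP-array intensity data: log R ratio (LRR) matrices are
segmented into shared multi-sample segments, genotyped into three copy
states, recoded as biallelic deletion markers, and analysed for population
structure and lineage differentiation (V_ST). A synthetic-cohort generator
with recorded truth makes every stage testable end to end.

## Signal model

The LRR of a probe is a normalized log2 intensity ratio that is ~0 at two
copies, negative under deletion and positive under duplication. The
pipeline's working assumption, shared with the synthetic generator, is a
piecewise-constant per-sample mean plus Gaussian probe noise and a smooth
GC-content wave:

    LRR_ij = mu(state_ij) + a_i (gc_j - mean gc) + eps_ij,  eps ~ N(0, sigma^2)

Default state means are mu(2)=0, mu(1)=-0.5, mu(0)=-1.2, mu(3)=+0.4
(configurable). The value for three copies deserves a note: the calling
rule thresholds segment means at ±0.3, and a state mean placed exactly at
the threshold would be missed about half the time under any symmetric
noise, because P(mean ≥ t) → 1/2 when E[mean] = t. The duplication mean
is therefore set above the threshold (+0.4, roughly the single-copy-gain
shift observed on Illumina-type arrays), so that each non-neutral state
clears its threshold with margin. Real two-peak deletion clusters sit near
0 and −1; the defaults bracket them.

## GC-wave correction

Array intensities carry a slowly varying spurious component correlated
with local GC content. The correction regresses each sample's LRR vector
on the panel's probe GC fraction and subtracts the fit, retaining the
sample mean. Three modes:

* `linear` — ordinary least squares. Residuals are exactly orthogonal to
  the GC track and the operation is idempotent.
* `trimmed` (pipeline default) — the same regression fitted only on probes
  within 4 scaled median absolute deviations of the sample median, with
  the fit subtracted from all probes. Rationale: genuine copy-number spans
  are intensity outliers, and when they cover a non-negligible fraction of
  the panel they leverage a plain OLS fit — on the desk-scale synthetic
  genome (CNVs cover ~20% of 800 probes) OLS attenuates segment means by
  up to ~0.1 at GC extremes, eroding the ±0.3 calling margins. On
  realistic panels (CNV fraction well under 2%) the two modes agree.
* `loess` — lowess local-linear fit of LRR on GC, for curved waves.

Missing cells are imputed with the per-probe median when under 5% of a
probe's samples are missing; otherwise the probe is dropped. Probes not on
a configured autosome list (default labels "1".."29", the cattle
autosomes) are dropped and counted.

## Segmentation

Chromosomes are partitioned into segments whose breakpoints are shared by
all samples, so recurrent events at the same position reinforce each
other. The procedure is recursive binary splitting: for a block, the
candidate breakpoint maximizes the pooled reduction in within-segment sum
of squared deviations,

    stat = SSE(block) - SSE(left) - SSE(right),

summed over samples, with both sides at least `min_probes` (default 3)
long and ties broken toward the smallest index. Significance is assessed
by a max-statistic permutation test — probe order is shuffled identically
across samples, preserving each probe's cross-sample covariance — with
p = (1 + #{permuted max ≥ observed}) / (1 + n_perm); a split is accepted
at p ≤ 0.01 with n_perm = 1000 by default (tests and the reproduction
script use 200–300 permutations to stay desk-scale; the p-value floor
1/(n_perm+1) remains below the threshold).

A single binary cut has a known blind spot: a compact event in the middle
of a long block contributes weak contrast to any one split (its signal is
diluted over one long side), so the permutation test can stall even when
the event is obvious — we measured p ≈ 0.03 for a 14-probe duplication
inside a 309-probe block. Blocks whose best single split is not
significant are therefore re-tested for their best interior double cut
(island): stat = SSE(block) − SSE(island) − SSE(complement), maximized
over all interior windows with all three parts ≥ `min_probes` — the
circular-binary-segmentation move — under the same permutation scheme.
Accepted cuts recurse into the sub-blocks; internal significance checks
stop early once enough permuted maxima have reached the observed value to
make rejection inevitable, which leaves the accept/reject decision
identical to the exact test.

Consequences asserted in the test suite: segment means equal arithmetic
means exactly; segments tile each chromosome; segmentation is invariant
to per-sample constant shifts; on piecewise-constant signals of ≤ 12
probes the greedy result matches a brute-force minimal-SSE partition at
equal segment count; pure-noise chromosomes stay unsplit in ≥ 95% of
replicates.

## CNV calling, merging, filtering, recoding

Per-sample segment means are called loss (mean ≤ −0.3), gain (≥ +0.3) or
neutral; the boundary is inclusive. Segments with at least one non-neutral
sample are candidates; candidates overlapping by ≥ 1 bp or adjacent in
probe coordinates are unioned (with shared breakpoints segments tile the
chromosome, so adjacency is the only way two candidates can abut — bp
overlap alone would never merge them). After a union, each sample's
representative mean comes from the constituent segment where its |mean| is
largest, and its state is re-called from that mean; the region type is
loss/gain when all non-neutral states agree, else mixed.

Regions are retained when their carrier frequency strictly exceeds 1% and
renamed CNV1..CNVn by descending frequency (ties by chromosome and start).
Loss-type regions become biallelic markers: "12" for a loss event, "22"
for neutral. The single loss state follows the empirical observation that
array deletion clusters show two peaks (neutral and homozygous deletion)
with rare intermediates; the generator nevertheless simulates
Hardy-Weinberg heterozygotes, whose −0.5 means are called loss, so the
one-state decision's effect is measurable. Region coordinates are 1-based
inclusive internally; BED output converts to 0-based half-open.

## Relatedness (pi-hat)

For a pair of samples, the probability that their codes match at a marker
with deletion-allele frequency q is, conditioning on the number of alleles
shared identical by descent (IBD) under the dominant carrier model
(code "12" ⟺ ≥ 1 deletion allele, carrier frequency α = 1 − (1−q)²):

    IBD=0: m0 = α² + (1−α)²
    IBD=1: m1 = 1 − 2(1−q)² + 2(1−q)³
    IBD=2: m2 = 1

Since m1 lies between m0 and 1 with a nearly constant ratio across
realistic q, the three state probabilities are not separately identifiable
from binary matches — joint moment fits are so noisy that clamping to the
probability simplex biased unrelated pairs to ~0.3. The estimator
therefore targets the identifiable quantity directly: the IBD-sharing
coefficient θ = P1/2 + P2 (pi-hat), fitted by least squares of observed
matches on m0 + θ(1 − m0) and clamped to [0, 1]. It is unbiased at the
null (measured mean 0.03 across unrelated pairs) and exactly 1 for
duplicates; intermediate relatives are attenuated (parent-offspring ≈ 0.4
against a true 0.5), a documented limitation that does not affect the
> 0.4 duplicate-removal use. `ibd_probs` exposes the boundary-consistent
(P0, P1, P2) decomposition. Filtering is greedy: while any pair exceeds
the cutoff, the member of the worst pair with the larger mean pi-hat to
all others is removed (ties: the later sample), deterministically.

## Distance, MDS, trees, admixture

* **IBS distance** D = 1 − (IBS2 + 0.5·IBS1)/N over the "12"/"22" codes;
  with two codes every pair shares at least the "2" allele at each marker,
  so D ≤ 0.5.
* **Classical (Torgerson) MDS**: double-center −D²/2, take the top
  eigenpairs with positive eigenvalues, scale eigenvectors by √eigenvalue;
  each coordinate's sign is fixed so its largest-magnitude loading is
  positive. Euclidean inputs of rank ≤ dims are reproduced exactly.
* **Neighbor joining** (Saitou–Nei) with the standard Q-criterion,
  smallest-(i,j) tie-break, and the usual branch-length formulas; negative
  estimates are clamped to 0 and recorded. Additive matrices are
  reconstructed to numerical precision; output is Newick.
* **Hierarchical clustering** of per-sample region-mean profiles uses
  scipy's average-linkage agglomeration on Euclidean distances (linkage
  configurable), serializable to Newick.
* **Admixture**: each individual draws c alleles per marker (c = 1 by
  default — one observed deletion-presence code) from a mixture of K
  cluster deletion frequencies F weighted by ancestry proportions Q.
  The log-likelihood Σ [x log(QF) + (c−x) log(1−QF)] is maximized by EM
  (non-decreasing by construction, asserted on every run), best of
  several seeded restarts. This replaces Bayesian MCMC inference of the
  same model: deterministic per seed, desk-scale, and testable; the
  correlated-allele-frequency prior of the MCMC formulation is dropped.
  Cluster labels are arbitrary; evaluation aligns them by the
  permutation minimizing mean absolute error against truth.

## V_ST

For one region and two groups, V_ST = (V_T − V_S)/V_T with V_T the
population variance (denominator n) of all individuals' segment mean LRRs
pooled and V_S the size-weighted mean of the two within-group population
variances. These conventions make V_ST exactly the between-group variance
share (law of total variance), hence within [0, 1]; an `unbiased` switch
uses (n−1) variances with an unweighted group mean and is reported
unclamped. V_T = 0 rows are degenerate: V_ST = 0, flagged, never counted
as differentiated. Flags use strict inequalities at 0.4 and 0.6. V_S is
averaged over the two compared groups (not over breeds); a breed-level
alternative would require breed labels inside each comparison and is out
of scope here. V_ST is computed on continuous segment means, not on
discretized states.

A note on the companion length/frequency contrast: the class summaries
(N, mean, SEM) feed a Welch two-sample t-test with the
Welch–Satterthwaite degrees of freedom. Recomputing a published frequency
contrast from rounded summary statistics of this kind need not reproduce
its printed p-value exactly; this module always reports the Welch result
computed from the data it is given.

## Gene overlap

Region-gene intersection uses 0-based half-open coordinates (GFF3 input is
1-based inclusive and is converted by start−1); every pair overlapping by
at least 1 bp is reported with its overlap length. Implementation uses an
interval tree per chromosome.

## Synthetic cohorts

The generator emulates a multi-breed cattle-like cohort at desk scale:
three ancestral groups × two breeds × eight individuals plus four
admixed hybrids, two chromosomes of 400 probes at 2 kb spacing, and 12
non-overlapping CNV loci of 10–25 probes, of which three are deletions
with fixed differentiated frequencies (0.9 in one group, 0.05 elsewhere)
and the rest draw ancestral frequencies uniformly from [0.2, 0.8] and
diverge via Balding–Nichols sampling (Beta with mean equal to the parent
frequency) at F = 0.2 between groups and F = 0.05 between breeds —
magnitudes chosen to mirror the strong taurine/indicine split and mild
within-group breed divergence of real cattle. Genotypes follow
Hardy–Weinberg sampling at the breed frequency (hybrids at their
ancestry-weighted mixture of group frequencies, ancestry drawn from a
flat Dirichlet); duplication carriers get three copies. Probe noise is
N(0, 0.12) — comfortably inside the regime where a ≥ 10-probe segment
mean resolves a ±0.3 threshold — and a GC wave of amplitude 0.2 rides on
a smooth sinusoidal GC track. About 30% of non-differentiated loci are
duplications, mirroring the deletion-dominated composition of array CNV
call sets. All draws derive from a single seed; identical configurations
are bit-identical.

A marker-level shortcut (`simulate_deletion_markers`) draws "12"/"22"
genotypes directly from the same frequency hierarchy, for testing
marker-based methods at marker counts (hundreds) larger than the probe
panel can host.

What the generator does **not** emulate: B-allele frequencies (the
pipeline is LRR-only), linkage disequilibrium between loci, multi-allelic
duplications, per-sample wave-amplitude variation, batch effects, or
probe-specific variance. Passing tests therefore demonstrate correctness
of the algorithms under the stated signal model, not performance on real
array data.

## Problem sizes and numerical choices

Test and reproduction runs use the standard cohort above (52 samples ×
800 probes), 200–300 permutations per significance test, 200 replicates
for false-positive-rate estimates, and 200-marker cohorts for admixture —
sizes at which the full suite completes in a few minutes on one CPU while
leaving the statistical margins (99% state accuracy, ±2-probe boundaries,
≥ 9/10 V_ST power, ≤ 5% false-split rate) intact. Degenerate inputs are
handled explicitly: constant GC tracks raise errors, V_T = 0 regions are
flagged rather than divided by zero, monomorphic-only marker sets refuse
a pi-hat, EM mixture probabilities are clipped at 1e−12 before logs, and
all tie-breaks (split index, NJ join pair, relative removal) are fixed
for determinism.

## Known limitations

* Greedy top-down splitting is not globally optimal for k ≥ 3 segments on
  adversarial inputs; it matches the exhaustive optimum on
  piecewise-constant signals, which is the intended regime.
* pi-hat attenuates intermediate relatedness (see above).
* The admixture model treats one code per marker as one allele draw;
  with few markers (tens) ancestry estimates are coarse, as the examples
  show (MAE 0.14 at 10 markers vs 0.03 at 200).
* V_ST on segment means inherits any residual wave or normalization
  artifacts; on heavily contaminated data the degenerate/flag logic does
  not substitute for quality control.
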