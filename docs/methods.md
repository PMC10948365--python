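# Methods

This note documents the models, parameter choices and numerical behaviour
of `remodel3d`, and what the synthetic-data tests do and do not establish
about real data.

## Contact matrices and balancing

Matrices are dense, symmetric, per-chromosome and intra-chromosomal only
(inter-chromosomal contacts are excluded up front, as translocation-prone
tumour genomes make them unreliable). ICE balancing is plain iterative
correction: bins with zero marginal plus the lowest 2% quantile of nonzero
marginals are masked (the fraction is configurable; published pipelines do
not print theirs), then rows/columns are scaled until the coefficient of
variation of unmasked row sums falls below 1e-5 (max 200 iterations; the
convergence flag and iteration count are kept on the result). The bias
vector is normalized to mean 1 over unmasked bins, so `balanced =
C / (bias_i · bias_j)` holds exactly. Knight–Ruiz balancing is deliberately
not provided: the analysis path of the study design this reproduces used
ICE throughout.

The expected profile is the per-diagonal mean of the balanced matrix over
unmasked pairs; O/E entries at masked bins or empty distances are NaN.
Per-diagonal O/E means are 1 to within 1e-9 by construction.

## Compartments

PC1 is the leading eigenvector of the Pearson correlation matrix of the
O/E matrix restricted to unmasked bins (eigendecomposition via LAPACK
`eigh` on the symmetric matrix). Numerical choices:

- Residual NaN entries inside the unmasked submatrix (distances with no
  unmasked pair) are set to the neutral O/E value 1 before correlation.
- If the leading eigenvalue is ≤ 1 (a correlation matrix with no shared
  structure, e.g. constant O/E), the track is all-zero and the chromosome
  is flagged ambiguous rather than returning an arbitrary basis vector.
- The "100 kb window at 50 kb bins" smoothing is implemented as a
  *centered* running mean over 3 bins. A trailing 2-bin mean — the literal
  reading — shifts the track by half a bin and systematically misassigns
  block-edge bins; the centered odd window is phase-neutral. Smoothing is
  toggleable (`smooth_bins=0`).
- Orientation multiplies PC1 by ±1 so its correlation with gene density is
  ≥ 0; |correlation| < 0.1 flags the chromosome ambiguous. Only the sign
  and rank of PC1 are ever compared across samples — eigenvector scale is
  arbitrary.

Condition consensus takes the sign of the mean PC1 across replicates and
requires a configurable fraction of replicates (default: all) to share
that sign, else the bin is NA; bins NA in either condition are NA overall.
The published tool's correlation-difference switch score is not
reproduced — this sign-consensus rule is the package's declared substitute
and is validated against planted truth instead.

Saddle: bins ranked by PC1 into equal-occupancy groups; matrix entries are
mean log2 O/E between groups; corner means (AA, BB, AB) are plain O/E
means between the top/bottom 20% of ranks (self-pairs excluded), and
strength is log2((AA+BB)/(AB+BA)). The A:B interaction ratio sums O/E from
each 100 kb window to all A- and all B-labelled bins (excluding the window
itself) and reports the log2 ratio, with zero-denominator windows flagged
missing.

## Insulation and TAD boundaries

Insulation at bin *i* is the mean balanced contact over the `w × w` square
upstream×downstream of *i*, `w = round(window_bp / bin_size)` (102,353 bp
→ 5 bins at 20 kb). A bin is NA when the window overlaps a chromosome end
or more than 50% of its cells touch masked bins.

Boundaries are strict local minima (flat minima report their leftmost bin)
below a cutoff with positive prominence (depth below the lower flanking
maximum, walking outward until the track drops back below the minimum's
level). Two non-obvious choices:

- **Valley merging.** A boundary depresses the track over a valley about
  one window wide, which can contain several noise-level local minima;
  minima closer than the window width are merged, keeping the deepest.
- **Valley centering.** The reported bin is the centre of the run of bins
  within half the prominence of the minimum, not the argmin: balancing
  inflates the depleted boundary bin's bias and tilts the plateau floor,
  so the raw argmin drifts 1–3 bins while the half-prominence centre stays
  put.

The cutoff is in units of mean balanced contact, so it must be chosen on
the data's count scale (the examples use half the track median, i.e. "dips
to less than half the typical insulation"). Replicate boundaries merge by
single-linkage when within one bin of each other (≤ 2 bins after one-bin
dilation), requiring support in all replicates by default; cross-condition
boundaries with no counterpart within the same distance are
condition-specific.

## Capture interactions

Scores are consumed, never computed: the capture scoring model itself is
out of scope, and the synthetic generator produces score tables directly.
Records at score ≤ 5 or bait-to-bait (other-end name ≠ ".") are dropped.
Other-end anchors of one bait within a 10 kb gap merge by single linkage
into region-level calls keyed on the union of both conditions; the
per-replicate region score is the maximum member score, with absent
records counted as score 0 (absence of a called interaction is treated as
evidence of absence in capture data; averaging only over present
replicates is available as an alternative). Significance: score > 5 in ≥ k
of n replicates (2-of-3 default, 2-of-2 for duplicate designs). Classes:
gained / lost when |Δ mean asinh score| > 1 in the corresponding
direction, maintained otherwise among regions significant somewhere.
Distances are anchor-midpoint to anchor-midpoint. The time-course
partition marks a treated-stage gain as maintained when the recovery stage
holds a consensus-significant region for the same bait overlapping its
other end.

## Methylation

β = M/(U+M+100) (the +100 offset keeps β < 1 and guards 0/0), masked at
detection p > 0.01; M-values clip β to [1e-6, 1−1e-6] before the logit.
The DMR rule is the region-merging definition only — no kernel smoothing
or per-probe inference: candidate probes need |Δβ| > 0.30 on group-mean
βs; same-sign candidates chain while consecutive gaps are ≤ 1,000 nt;
chains survive with ≥ 2 probes and region-mean |Δβ| > 0.30. Both the
per-probe and region-mean gates are configurable because published
phrasing does not fix where the ">30%" applies; applying both is the
stricter reading. Region summaries average unmasked probe βs per interval
(no probes → missing, never zero) and flag re-methylation at > 0.30 gain
from treated to recovery.

## Interval statistics

Interval algebra (merge, intersect, overlap fractions) is implemented on
sorted numpy arrays and cross-checked in the tests against per-base
membership oracles. Consensus peaks keep a first-replicate peak only if a
*single* peak in every other required replicate covers > 60% of its
length (fraction relative to the query peak, matching the intersect
convention; reciprocal mode available). Permutation enrichment re-places
each query interval uniformly at random on its own chromosome within the
workspace, preserving length, without overlap enforcement between placed
intervals and without GC or gap matching (declared simplification);
empirical p = (1 + #{permuted ≥ observed}) / (n_perm + 1). BH adjustment
delegates to statsmodels; the gene-set test is scipy's Fisher exact with a
0.5 continuity-corrected sample odds ratio when a cell is zero.

## Digestion and bait design

IUPAC motifs are scanned with overlapping-match regular expressions on the
forward strand; the two default motifs (^GATC, G^ANTC) are
reverse-complement palindromes, so a forward scan finds every site.
Non-palindromic custom motifs are additionally scanned as their reverse
complement with the cut offset mapped to forward coordinates. Genome
letters outside A/C/G/T never match any motif position — including motif
N — so assembly gaps produce no spurious cuts. Coordinates are 0-based
half-open everywhere; a TSS exactly at a cut site belongs to the fragment
starting there. Bait targets follow the ≤ 700 bp whole-fragment / two
350 bp edge rule; a configuration where 2 × edge length exceeds the
whole-fragment threshold is rejected because the two edge targets would
overlap. Probe tiling inside targets (a vendor step) is out of scope.

## Synthetic scenarios

The generator emulates the *structure* of a decitabine-style study, not
its sequencing noise. Expected Hi-C intensity is
`c · (1+d)^(−α) · (1±γ) · Π(attenuation)` — power-law decay (α = 1),
within/between-compartment affinity (γ = 0.5), and per-boundary contact
attenuation (0.2, i.e. 5×) capped at two crossings — scaled so the
expected pair total matches the depth (5×10⁵ per replicate) and sampled
as Poisson counts. Condition 2 flips a planted subset of blocks (default
8 B→A + 2 A→B on a 20 Mb chromosome of 500 kb blocks) and removes 10 of
20 boundaries. Capture tables draw per-bait true interactions ~
Poisson(8) with scores 5 + Exp(4) jittered Normal(0, 0.5) per replicate,
sub-threshold noise ~ U(0, 5), planted treated-stage gains ~ Poisson(3),
and a 73.4% recovery loss rate — the headline fraction of the study design
this emulates, configured as a scenario constant. Methylation probes carry
a Beta(8, 2) background, a planted −0.40 β at enhancers with Normal(0,
0.03) noise, and recovery re-gain of half the loss (full re-gain for a 40%
enhancer subset so the > 0.30 re-methylation flag has true positives);
probe placement is EPIC-like, denser (400 bp ladder) inside enhancers so
the ≤ 1 kb chaining rule can operate there. M/U intensities are
back-computed from β with LogNormal totals, so β inversion is exact.

Three presets express that different planted features need different
backgrounds:

- `compartment_scenario`: 40 Mb, 80 blocks, 30 planted B→A flips, *no*
  boundaries — boundary attenuation adds genuine non-compartment structure
  that competes with the eigenvector at desk-scale depth.
- `boundary_scenario`: planted boundaries on γ = 0 background —
  compartment-block junctions are themselves real insulation dips and
  would be counted as false boundaries although they are not noise.
- `null_scenario`: identical parameters in both conditions; every switch
  call is a false positive.

Everything is deterministic under the scenario seed (per-stage fixed
sub-streams), and each generator serializes its truth to JSON; tests read
truth only from those files.

**What passing these tests shows — and does not.** Recovery of planted
flips, boundaries, gains and DMRs demonstrates that the decision rules
(thresholds, consensus, merging) implement their definitions correctly and
are well-calibrated against Poisson/Gaussian noise at desk-scale depth. It
does not establish performance on real data, which adds mappability and
copy-number artefacts, overdispersion, correlated replicate noise,
restriction-fragment geometry and capture bias; none of these are
simulated (an overdispersion option exists for contacts).

## Pipeline

`run_pipeline` executes sections in dependency order with section-level
isolation (an exception in one section is recorded in the report's
`errors` block without aborting the rest), serializes its full
configuration (defaults are the study-printed thresholds: score 5, 2-of-3,
asinh 1, 10 kb gap, window 102,353, cutoff 50, DMR 1,000 nt / 2 probes /
0.30, 1,000 permutations) and re-derives every reported percentage from
the counts in the same report at write time. Per-stage sub-seeds are
derived from the run seed and stage name, so sections are individually
reproducible. Problem sizes throughout (20–40 Mb single-chromosome
scenarios, ≤ 1,000 bins per matrix, 500 baits, ~20k probes) are chosen so
the complete pipeline, test suite and acceptance script each run in well
under a minute to a few minutes on one CPU.

## Known limitations

- Dense matrices cap practical resolution near 10 kb for a full human
  chromosome (~25k bins ≈ 5 GB); the intended working range is 20–50 kb.
- The insulation cutoff is count-scale dependent; there is no automatic
  per-sample normalization of insulation units.
- Permutation placement matches chromosome and length only (no GC,
  mappability or isochore matching).
- The eigenvector method reports a single PC1 per chromosome; no
  sub-compartments, no trans-chromosomal analysis.
- Capture scoring, peak calling, read alignment and array normalization
  are consumed as inputs, never recomputed.
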