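# Methods

This note documents the models, parameters and design choices behind crckit,
and what the synthetic validation does and does not establish.

## Super-enhancer calling

Enhancer peaks (H3K27ac) are stitched transitively when the gap between them
is at most `se_stitch_bp` (default 12,500 bp). Peaks lying fully inside a
TSS ± `tss_exclusion_bp` window (default 2,500 bp) are removed before
stitching so that promoter-proximal acetylation does not bridge distinct
distal elements; containment is evaluated as `start ≥ tss − x` and
`end ≤ tss + x` in half-open coordinates. These two values are the canonical
ROSE defaults and are exposed in the config.

Each stitched region is scored by its background-subtracted signal area,
`Σ_bases max(track − control, 0)`: flooring at zero keeps totals nonnegative
and matches common ROSE practice; bases not covered by the track count 0.
Ranks descend by total signal with (chrom, start) breaking ties.

The hockey-stick cutoff rescales ascending rank and signal to the unit
square and takes the point maximizing `x − y` — the point where a slope-1
line is tangent to the convex rank curve. Regions with signal strictly above
the signal at that point are super-enhancers; strict inequality makes ties at
the cutoff non-super, which keeps the call deterministic. A completely flat
curve yields no super-enhancers. The cutoff is invariant under positive
affine rescaling of the signals (both axes are normalized), which the test
suite asserts as a property.

Gene assignment gives each super-enhancer *all* genes with a TSS within
`se_assign_window_bp` (default 50 kb), not only the nearest: a single domain
may serve several TFs, and circuit construction needs every TF whose locus a
super-enhancer plausibly regulates. A `nearest_only` flag provides the
stricter alternative.

## Motif scanning

Scores are log2 likelihood ratios of pseudocounted motif probabilities
(pseudocount 10⁻³, renormalized) against a 0-order background, uniform by
default since the source data do not justify anything richer; a
genome-derived background can be passed in each PWM. Per-position scores are
discretized to a 10⁻³-bit grid and summed per window, so a window score is an
exact sum of integers; the null distribution of that integer score is
computed exactly by convolving the four-point per-position distributions
(dynamic programming). The p-value of a score is the exact tail
`P(S ≥ s)`, and a window is a hit iff its p-value is at most `fimo_pvalue`
(default 10⁻⁴, the FIMO default). Because hit calling and `pwm_pvalue` share
one discretized score definition, the DP tail matches exhaustive enumeration
over all 4^w words bit-for-bit up to float summation error, which the
acceptance suite verifies for w ≤ 6. Ambiguity codes (N) contribute 0 bits at
every position. Minus-strand hits are scored with the reverse-complement
matrix on the forward sequence and reported at the forward coordinates.

GGAA microsatellites — the fusion driver's preferred element — are detected
as maximal non-extendable runs of consecutive GGAA tetramers (TTCC on the
minus strand, reported as GGAA on −) with at least `ggaa_min_units` units
(default 4). The driver-motif requirement for circuit membership is satisfied
by such a run, or by a driver PWM hit when a driver motif is supplied; the
GGAA rule is the default because the driver's elements are microsatellite
repeats rather than a sharp PWM.

Motif spacing statistics pair each hit with its nearest hit of a *different*
motif and report the mean/min/max of edge-to-edge gaps
(`max(0, later.start − earlier.end)`). Edge-to-edge was chosen over
center-to-center; with a fixed motif width the two differ by a constant.

## Circuit construction

Super-enhancer regions of each SE-assigned TF are extended by
`se_extension_bp` (500 bp, a printed parameter of the procedure) on both
sides, clamped to the chromosome and merged. A directed edge A→B is recorded
when A's motif has at least one hit inside any of B's extended regions;
every edge carries its hit list as evidence. Auto-regulated TFs are those
with a self edge. The driver constraint — at least one qualifying driver
element *and* at least 1 bp of driver ChIP peak overlap within the TF's
region set — is evaluated at the level of the region set (the two conditions
may be met by different regions) and applied *before* clique enumeration,
since the requirement holds for all candidate members; a post-hoc filtering
mode exists for sensitivity analysis.

Fully interconnected auto-regulatory loops are the maximal cliques of the
undirected support graph that links A and B when both A→B and B→A exist,
restricted to auto ∧ driver-passing nodes. Enumeration uses Bron–Kerbosch
with pivoting (networkx `find_cliques`); isolated eligible nodes appear as
size-1 circuits. All maximal cliques are reported, ordered by size, then
total evidence, then members, so output order is total and deterministic.
The acceptance suite checks the enumeration against exhaustive subset search
on 200 random graphs of up to 12 nodes.

## Occupancy analysis

Each H3K27ac peak is the backbone of one regulatory element (the two
histone-mark definitions share H3K27ac⁺, so the acetylation peak is the
natural common unit; a TSS-window promoter mode exists as a flag). Promoters
additionally require an H3K4me3 overlap, no H3K4me1 overlap, and a TSS
within `promoter_window_bp` (default 2,000 bp — a conventional promoter
radius, exposed in config); enhancers require H3K4me1 and no H3K4me3.
Elements matching neither pattern (or both marks) are dropped and counted in
the run log. Overlap is ≥ 1 bp in half-open coordinates; abutting intervals
do not overlap. Bound fractions are reported as percentages rounded to one
decimal. Signal metaprofiles average per-base track values in equal bins
over center ± `profile_halfwidth_bp`; group profiles are unweighted means
over elements and are invariant to element order. Group expression
comparisons use a two-sided rank-based test (exact for small tie-free
samples, normal approximation otherwise); two identical groups give p = 1.

## Expression filters and differential sets

Lineage specificity averages TPM per lineage, ranks lineages descending and
passes a candidate iff its target lineage ranks within the top
`specificity_topk` (default 5). Ties all receive the worst shared rank —
the conservative choice, making ties harder to pass; a per-sample ranking
mode is available since the original panel ranking could be either.
Correlations are plain Pearson r over a sample subset; zero-variance genes
yield missing values rather than spurious ±1.

Downregulated sets take the negative side of the printed absolute
fold-change rule: `padj < 0.05` and `log2FC < −0.5` (standard), or
`log2FC < −1` (strict) with the universe restricted to genes with mean
TPM > 0.5 when an expression matrix is supplied.

## Overlap statistics

The empirical distribution test redraws each gene set uniformly without
replacement from the expressed-gene universe at its observed size and counts
permutations whose k-way intersection reaches the observed one;
`p = (n_ge + 1)/(n_perm + 1)`, which can never be zero, so resolving
p < 10⁻⁶ needs `n_perm ≥ 10⁶` (the default). The intersection size under
this null is sampled by an exactly equivalent chain of hypergeometric draws
(|S₁∩S₂| ~ HG(N, n₁, n₂), then each further set intersects the running
intersection hypergeometrically), which vectorizes to 10⁶ permutations in
well under a second; set sizes are canonicalized before sampling so the
p-value does not depend on argument order. On small universes the estimate
converges to the exact hypergeometric tail, which the tests assert within
three standard errors. "Shared" genes are those present in ≥ 1 other set
(the Venn reading); an all-sets variant is a flag.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, with
exact — not probabilistic — ground truth:

* **Geometry.** Two 500-kb chromosomes carry 20 super-enhancer loci (each
  five 3-kb H3K27ac constituents at 4-kb pitch, stitching into one ~19-kb
  region) in 75-kb units, plus typical 1-kb enhancers and 200 genes at
  ≥ 4 kb TSS spacing. Nine loci belong to "special" TFs — the three-member
  planted circuit, three decoys without their own motif, three decoys
  without driver evidence; the remainder are high-signal decoy loci assigned
  to non-TF genes. Unit length is chosen so no special TF's TSS falls within
  the 50-kb assignment window of another special locus, and the 21
  non-circuit ("filler") TF genes sit in chromosome tails more than 50 kb
  from any super-enhancer, so the SE-assigned TF set is exactly the nine
  special TFs.
* **Exactness by scrubbing.** Planted motifs use near-consensus PWMs
  (0.97/0.01 rows). At the 10⁻⁴ threshold a width-8 motif of this sharpness
  hits iff the window equals the consensus or its reverse complement
  (p(≤1 mismatch) = 25/65536 ≈ 3.8×10⁻⁴ > 10⁻⁴), so after every off-plan
  occurrence of any consensus word — and any GGAA/TTCC run of ≥ 4 units —
  is mutated out of the background, scanning recovers exactly the planted
  instances. This is why `motif_width ≥ 7` is enforced. Consensus words are
  drawn with pairwise Hamming distance ≥ 3 (including reverse complements)
  and excluding GGAA-repeat phases.
* **Planted structure.** Each circuit locus carries one instance of every
  circuit member's motif (successive instances 16–31 bp apart, the spacing
  regime reported for the real enhancer element), a 6-unit GGAA run, a
  driver ChIP peak over the run, and TF ChIP peaks on the motifs. No-auto
  decoy loci carry the circuit motifs (but not their own) plus driver
  evidence; no-driver decoys carry only their own motif. Signal is
  piecewise-constant at the peak level plus Gaussian noise truncated at 0
  (sd 0.1) — the simplest model that exercises ranking and profiles.
  Additional combinatorial TF binding is planted at promoters and enhancer
  constituents with cooperative (dual/trio) patterns more common than solo,
  mirroring the genome-wide occupancy structure of the real data; extra
  driver peaks go only to typical enhancers, which can never enter a TF's
  region set, so decoy guarantees are untouched.
* **Expression and knockdowns.** Circuit TFs are top-ranked in lineage 0
  with a shared latent factor giving pairwise r ≥ 0.8; other genes are
  i.i.d. Three knockdown tables share a downregulated core of
  `shared_down_fraction × de_set_size` genes (the three TFs themselves plus
  non-TF targets); every non-member misses both thresholds by at least a
  factor of two, so set construction has no borderline cases.
* **Null bundles** keep the geometry and signals but scatter the same
  multiset of motif instances and GGAA/driver elements uniformly over the
  genome and remove the expression/knockdown structure.

What passing these tests shows: the pipeline's inference chain is correct on
data satisfying its assumptions, with zero tolerance (the planted circuit is
recovered exactly, decoys never appear). What it does not show: robustness
to read-level noise, peak-calling artifacts, motif degeneracy, overlapping
regulatory domains, or mapping biases — none of which the generator
simulates.

## Problem sizes and determinism

Default validation runs use 2 × 500 kb genomes, 200 genes, 30 TFs, 20
super-enhancer loci, 5 lineages × 4 samples and 10⁶ overlap permutations;
the planted-recovery and null controls each span 20 seeded bundles. A full
generate-plus-analyze cycle takes about one second on one CPU. All
randomness flows from a single integer seed through `numpy.random.
default_rng`; identical seeds give byte-identical file bundles, outputs and
manifests, and the manifest (config snapshot, input/output SHA-256 checksums,
per-stage counts, seed) fully determines a rerun.

## Known limitations

* One PWM per TF; with multiple motifs per TF, any hit qualifies (union
  rule), but the library format carries one matrix per motif id.
* Quantitative circuit scoring is limited to evidence counts; membership,
  not strength, is the output.
* The occupancy module's promoter universe depends on the chosen backbone
  (H3K27ac peaks); published element counts from other universes are not
  expected to match numerically at synthetic scale.
* bedGraph input uses a strict non-overlapping dialect; overlapping segments
  must be resolved upstream.
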