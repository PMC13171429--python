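# Methods

This note documents the models and procedures implemented in `vertitrace`,
the parameters that matter, the design choices made where the design was
genuinely open, what the synthetic-data generators do and do not emulate,
and the known limitations.

## Z-curve composition segmentation (`zseg`)

A nucleotide sequence is summarized by three cumulative disparity series —
purine−pyrimidine (x), amino−keto (y) and weak−strong (z) — each stepping
±1 per base (`N` bases repeat the previous value and are excluded from all
counts).

Segmentation is recursive binary splitting. For a segment with n counted
bases split into sides of n_L and n_R bases with frequency vectors p^L,
p^R and pooled vector p, the split statistic is the weighted gain in the
genome order index S(p) = Σ_b p_b²:

    Δ = n_L·S(p^L) + n_R·S(p^R) − n·S(p) = (n_L n_R / n)·‖p^L − p^R‖²

Δ is non-negative, zero iff the sides share a composition, and — because of
the n-weighting — scale-comparable across segment sizes: a fixed
composition contrast yields Δ proportional to segment length. At every
segment the maximizing admissible split (both children ≥ `min_len` bp,
ties to the smallest position) is accepted iff Δ ≥ `t0`, then both children
are segmented recursively.

**Parameters.** `t0 = 100` (dimensionless) and `min_len = 1000` bp are the
package defaults. Under the Δ normalization above, the null distribution of
the maximal Δ on homogeneous 50 kb sequences stays around 10–15, so
`t0 = 100` is conservative: in 100 seeded homogeneous 50 kb genomes the
pipeline produced zero breakpoints (this measured value is pinned as a
regression test). The threshold is calibrated against the synthetic
prophage-style control below rather than against any sliding-window
heuristic.

**Locus scan.** `scan_locus` reports the distance from a gene locus to the
nearest breakpoint (0 if one falls inside the locus, +∞ if there are none)
and a flag for "segmentation within `window_bp`" (default 10 kb) — the
quantity the LGT verdict consumes.

## GC composition (`composition`)

Gene GC vs genome GC per strain; GC = (G+C)/(A+C+G+T) with `N` excluded.
Genome GC pools counts over all contigs (equivalently, a length-weighted
mean of per-contig GC) — never an unweighted mean of contig fractions.
Summaries use the sample (n−1) standard deviation. Fractions internally,
percentages only at the report layer. A per-strain z-score of the gene's GC
against the other strains' gene GCs quantifies "no deviation".

## Pairwise dN/dS (`codon_dnds`)

Codon alignments are built by threading each coding sequence onto its
aligned protein row (gap columns become `---`; a terminal stop codon is
stripped; any translation mismatch is an error naming the position).

The estimator is classical Nei–Gojobori (1986) counting under the standard
genetic code (configurable NCBI table id):

* **Sites.** Each sense codon contributes, per position, the fraction of
  its single-base changes that are synonymous, counting only changes to
  sense codons (changes to stops reduce that position's denominator);
  s + n = 3 per codon. Pair totals S and N average the two sequences.
* **Differences.** Columns where both codons are ungapped sense codons are
  compared; codons differing at k positions average the syn/nonsyn step
  counts over all k! mutational orderings with equal weight. Orderings that
  pass through a stop codon are excluded and the remainder reweighted; a
  column whose every ordering crosses a stop is skipped entirely (it then
  contributes neither sites nor differences, keeping Sd ≤ S).
* **Correction.** p_S = Sd/S and p_N = Nd/N are corrected with the
  Jukes–Cantor formula d = −(3/4)·ln(1 − (4/3)p).

Each pair carries a status. `undefined_pS0` marks a genuinely undefined
ratio — p_S = 0 with nonsynonymous change present — and is checked before
the `filtered_dN0_or_dS0` status that removes pairs with d_N = 0 or
d_S = 0 (identical rows, with both counts zero, fall to the filter status).
`saturated` marks (4/3)p ≥ 1, where the correction diverges. Only `ok`
pairs enter the retained ω set. Equal pathway weighting (no
transition/transversion weighting) and averaging sites over both sequences
are the canonical NG86 conventions and are stated in every report.

## Bootstrap comparison (`boot_stats`)

The focal ω set is compared with the core-gene background by the standard
shift bootstrap for equality of means: both groups are recentred on the
pooled mean (imposing the null while preserving each group's shape and
size), resampled with replacement B = 1000 times, and the two-sided
p-value is the add-one fraction p = (1 + #{|T*| ≥ |T_obs|})/(B + 1), floor
1/(B+1), never zero. The test is calibrated on null data at realistic group
sizes (hundreds of pairwise comparisons per group): over 1000 null
simulations with gamma-shaped, ω-scale groups of 100, the type-I error at
α = 0.05 stays inside the 99% binomial band. Swapping the groups flips the
sign of T_obs and leaves the p-value unchanged up to Monte Carlo
resampling noise (the invariance is distributional, not per RNG stream).
Box summaries use linear-interpolation quartiles and Tukey 1.5×IQR
whiskers.

## Trait evolution (`trait_evo`)

**Model.** Binary presence/absence evolves under a 2-state Markov (Mk)
model: ER (one rate, the default — matching the common default of
graphical ASR tools) or ARD (gain rate q01, loss rate q10). Transition
probabilities are closed-form; the root prior is equal by default
(stationary available for ARD).

**Inference.** The likelihood is computed by Felsenstein pruning; rates are
optimized in log space by bounded scalar (ER) or L-BFGS-B (ARD, three
starts) maximization over [1e−8, 1e4]. Marginal node probabilities use the
standard up/down message construction, equivalent to re-rooting at each
node. All-zero branch lengths are rejected rather than silently perturbed.

**Events.** Nodes are labeled by max marginal; ties inherit the parent's
label (a root tie resolves to absent), biasing toward fewer inferred
gains. Gains are 0→1 edges, losses 1→0 edges. The origin node is the node
closest to the root that is ancestral to every present tip and whose
marginal presence exceeds the threshold (default 0.5; the comparison is
strict with a 1e−9 guard so that a maximally uncertain node — marginal
exactly 1/2 at the root of a symmetric configuration — never claims the
origin). If no node qualifies, the MRCA of present tips is returned with a
warning. The marginal at the origin is always reported so stricter cutoffs
can be applied downstream.

**Dating.** Node depth is the mean path length to descendant tips
(substitutions/site). A substitution rate r (subs/site/Ma) is fitted by
least squares through the origin over the calibration nodes,
r = Σ h_c a_c / Σ a_c², and ages are h/r; confidence intervals refit r at
the calibration CI bounds. This is an intentionally simple relative-rate
method: on clock-like trees calibration nodes are dated exactly and ages
are parent-monotone; on strongly non-clock trees mean-path depths need not
be monotone and the method should be treated as indicative only.

**Transfer flags.** The species tree is restricted to the gene tree's tips;
a tip is flagged when its sister set (the tips of its sibling subtree)
differs between the trees, with the gene-tree sisters proposed as the donor
lineage. Sister-set incongruence necessarily also flags the donor and the
recipient's former neighbors, so a refinement marks *recipient candidates*:
flagged tips whose removal from both trees erases all remaining
incongruence — the signature of a single tip-level transfer. This is
deliberately not a full duplication-transfer-loss reconciliation; it
targets the single-allele-transfer case and will not decompose overlapping
multi-transfer histories.

## Subtypes and synteny (`subtype_synteny`)

Percent identity is computed over mutually ungapped columns (columns gapped
in either row count for neither numerator nor denominator); pairs with no
shared ungapped column are reported as undefined. Single-linkage clustering
at an identity threshold (default 85%, chosen between typical
within-subtype identities of ≥ 90% and between-subtype identities of
≤ 70%) yields subtypes numbered largest-first and `subtype.variant` labels.
Single linkage matches the "variant cloud" semantics of a subtype; note
that real subtype definitions are often additionally guided by tree
structure, so automatic clustering is an approximation and the threshold is
always recorded. Alignment trimming (N-terminal columns and an explicit
1-based column range) is parameterized because trim coordinates are only
meaningful for a specific alignment width.

Neighborhood profiles list (family label, strand, offset) for genes within
a window (default 10 kb) of the focal locus; family labels are
caller-provided. The synteny score between two profiles is
`J/2 + ADJ/2`: the Jaccard index of family sets plus the fraction of one
profile's adjacent ordered family pairs (restricted to shared families)
preserved as adjacent ordered pairs in the other. Identical profiles score
1, disjoint ones 0; with shared content but no adjacency to check, ADJ is
vacuously 1.

## Synthetic data (`synthetic_data`)

Every generator is a pure function of its arguments including the seed and
returns machine-readable truth.

* **Island genomes** draw i.i.d. bases from a background composition
  (default 72% GC, emulating a high-GC actinomycete chromosome) with
  sharp-boundary islands at known coordinates. The test/default island
  emulates an integrated prophage of markedly lower GC (40%; L1 contrast
  0.64) and 10 kb length in a 50 kb genome — the regime the segmentation
  threshold is calibrated to detect. Real islands can have composition
  gradients and repeats at their edges, which this generator does not
  emulate; passing tests show boundary recovery under sharp contrast, not
  performance on ameliorated ancient islands.
* **Codon pairs** evolve from a uniform-sense-codon ancestor for t/2 per
  lineage by an event-by-event process with rates ∝ κ^(transition) ×
  ω^(nonsynonymous), stops and multi-base jumps disallowed; time is scaled
  to expected substitutions per codon at the uniform-ancestor mean rate.
  The simulator is deliberately richer than the NG86 estimator (κ), so
  recovery tests probe robustness rather than a shared-model tautology.
  Defaults: 500 codons, t = 0.5, matching moderately diverged congeneric
  strains.
* **Yule trees** are pure-birth and ultrametric; root depth is a sum of
  Exp(kλ) waits for k = 2..n, which the tests check against the closed
  form.
* **Trait histories** evolve edge-by-edge with exponential waiting times,
  recording every flip. The single-origin test scenario uses q01 = 0.02
  and q10 = 0.15 on 64-tip trees (expected ~1 gain per tree) and keeps,
  by rejection, histories with exactly one gain and at most three losses.
* **Transfers** prune the recipient tip and regraft it at the midpoint of
  the donor's pendant edge. Test scenarios draw donor/recipient pairs at
  topological distance ≥ 4 edges: adjacent transfers leave signatures that
  are genuinely ambiguous at tip level (removing either of two tips can
  restore congruence), which is a limitation of incongruence-based
  detection itself, not of the generator.
* **Variant proteins** mutate subtype ancestors from a base protein and
  variants from their ancestor. Identity targets are *pairwise*: a
  mutation fraction x gives two independently mutated copies expected
  identity (1−x)² + x²/19, inverted analytically; realized identities land
  within ~3 points of targets at the default length 300.

## Pipeline and reporting (`pipeline`, `cli`)

`run_pipeline` executes the configured stages independently, records
failures per stage without aborting the rest, and emits a JSON report with
full parameter provenance and a verdict block with one boolean per
criterion: GC deviation small (default |Δ GC| ≤ 0.02), no segmentation
within the window of the locus, dN/dS consistent with the core background
(bootstrap p ≥ α), single origin, few (≤ 3) losses, no incongruent tips,
synteny conserved (min pairwise score ≥ 0.5). The criteria are reported
separately because the underlying argument is one of converging independent
evidence. All randomness derives from the master seed via fixed per-stage
offsets recorded in the report; a rerun with the same config is
byte-identical.

## Problem sizes in the test suite

The exhaustive-oracle comparisons run on 100 sequences of 1.5–6 kb
(segmentation), 1000 codon alignments of ≤ 50 codons (NG86) and 30 trees of
≤ 10 tips (Mk likelihood); recovery studies use 100 replicates of 50 kb
genomes, 200 codon pairs per ω value, 1000 null bootstrap datasets, 100
64-tip trait datasets, 50 32-tip transfer scenarios and 50 variant-set
seeds. These sizes make the full suite complete in well under a minute
while keeping Monte Carlo error small relative to every asserted margin.

## Known limitations

* The segmentation statistic assumes i.i.d. composition within segments;
  gradients, repeats and coding-strand asymmetries can shift breakpoints.
* NG86 is a counting method: it underestimates ω under strong
  transition/transversion bias at high divergence and has no site-to-site
  rate variation.
* ER ancestral-state reconstruction with an equal root prior can place the
  origin too deep when gain and loss rates are very asymmetric; the ARD
  model is available but needs more signal than small trees provide.
* Relative-rate dating is not a relaxed clock; use it for order-of-
  magnitude statements only.
* Tip-level incongruence flags cannot resolve transfers between adjacent
  lineages or overlapping multi-transfer histories.
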