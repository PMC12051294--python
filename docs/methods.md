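# Methods

`scopeggs` re-implements, as a tested library, the bespoke statistics used
to build and verify chromosome-scale scaffolds for the fungus gnat
*Bradysia coprophila*: SCOPE (long-range Hi-C interaction calling), EGGS
(inter-chromosomal gene-shuffling entropy), polytene-map distance
expectations, and the supporting coverage/interval procedures, together
with a synthetic-data generator that reproduces the statistical structure
those analyses assume.

## SCOPE — Scatter Clusters Of Paired Ends

### Model and procedure

Intra-chromosomal Hi-C contact pairs are treated as points (x, y) =
(mate-1 position, mate-2 position), canonicalized to the upper triangle
(x ≤ y).  After filtering (pair MAPQ ≥ `min_mapq`, inter-mate distance ≥
`min_intermate_distance`), a 2D Gaussian kernel density estimate is
evaluated on an m × m grid spanning [0, chromosome length], peak bins are
taken strictly above the `peak_quantile` empirical quantile of all m²
values, their genomic bin-center coordinates are clustered
agglomeratively (Euclidean distance, complete linkage by default) and the
tree is cut into exactly `k_clusters` clusters.  Clusters are summarized
(median/min/max per axis, summit bin = member with maximal density, ties
to the smaller row-major index) and kept only when
|median_y − median_x| ≥ `min_separation` — genuine long-range loci pairs.
Optionally, calls are removed when both anchors (in either order, padded
by one bin width by default) overlap a call from a genomic-DNA control
run, or when either anchor overlaps a known SV-breakpoint interval.

### Parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `min_mapq` | 10 | — | pair MAPQ = min of the two mates' MAPQs; the conservative reading of a per-pair quality threshold |
| `min_intermate_distance` | 1 Mb | bp | broad fold-back-region run; 5 Mb for the narrow-anchor variant |
| `grid_size` m | 1024 | — | gives ≈68.9 kb bins on the 70,507,862 bp X scaffold; 2048 gives ≈34.4 kb |
| `bandwidth_x/y` | 250 kb | bp | Gaussian SD of the smoothing kernel; 50 kb in the narrow variant, 100 kb in the permissive SV-screening variant |
| `peak_quantile` | 0.998 | — | top 0.2 % of grid values; 0.9999 (narrow), 0.995 (permissive), 0.999 (gDNA control) |
| `k_clusters` | 12 | — | tree-cut count; 4 (narrow), 50 (SV screening and control) |
| `min_separation` | 5 Mb | bp | separates long-range loci pairs from short-range structural noise |
| `kernel_truncation` | 4 | SDs | beyond 4 SDs a Gaussian contributes < 3.4e−4 of its peak |

### Numerical choices

* **KDE accumulation.**  Each point adds a separable Gaussian evaluated at
  its *exact* offsets from nearby bin centers, truncated at
  `kernel_truncation` SDs — O(N·r²) with r the truncation radius in bins.
  With truncation disabled this equals the direct N·m² Gaussian sum to
  machine precision, which is how the implementation is tested against
  `naive_kde_2d`; approximating points by grid-snapping (classical linear
  binning) was rejected because its interpolation error (~(bin/SD)²/8,
  about 2e−3 at the default bandwidth-to-bin ratio) is far larger than the
  agreement we require between the fast path and the oracle.  The grid is
  normalized so Σ z · bin_width² = 1.
* **Quantile threshold.**  Linear-interpolation empirical quantile over
  all m² values including zeros; bins must be *strictly* above it, so a
  constant grid yields no peaks.
* **Determinism.**  Peak bins are kept in row-major order before
  clustering; summit ties break to the smaller row-major index; the median
  of an even-sized coordinate set is the midpoint of the central pair.
  Shuffling the input pair order does not change the calls.
* **Coordinates.**  0-based half-open internally.  BEDPE mates are read as
  interval midpoints; the 5-column pair text format is 1-based points,
  converted on read.  Anchor intervals of a call are the cluster min/max
  bin centers widened to bin edges.

## EGGS — Entropy of Gene Group Shuffling

For two species A and B sharing n single-copy orthologs (SCOs), count the
SCOs on every pair of chromosomes (i from A, j from B), add a pseudo-count
of 0.1 to every cell, and normalize to a joint probability table p(i, j).
With H(·) the Shannon entropy in bits (0·log₂0 = 0):

* H_obs = H(p); H_min = (H(p_A) + H(p_B))/2 where p_A, p_B are the
  marginals; H_max = H(p_A ⊗ p_B), the entropy of the independence table,
  which equals H(p_A) + H(p_B) = 2·H_min analytically;
* MMNE = (H_obs − H_min)/(H_max − H_min) ∈ [0, 1], equivalently
  1 − 2·MI(A;B)/(H(p_A) + H(p_B)).

MMNE is 0 for a species compared with itself (before pseudo-counting) and
1 under complete independence of the two chromosome assignments.  Both
identities are enforced to 1e−9 in tests, with the mutual information
cross-checked against scikit-learn's contingency-table MI.

Choices worth recording: the pseudo-count is applied to *every* cell
including self-comparisons, so a self MMNE is slightly positive (O(0.1/n),
< 0.01 at 4 chromosomes × 1000 SCOs — tested as such, not as 0); chromosome
arms can be merged before counting (e.g. 2L + 2R → 2) via an explicit label
map; counterpart-chromosome percentages use the raw counts without
pseudo-counts, report the top target plus any target ≥ 20 % (every
secondary counterpart in the study's table is ≥ 23.9 %), and break ties by
declared label order; a single-chromosome species makes MMNE 0/0 and
raises an error rather than returning a value; pairwise MMNE matrices are
clustered with average linkage by default (the linkage is a recorded
parameter — the study's heatmap tool default is not documented) after
forcing the near-zero diagonal to exactly zero.

## Polytene-map distance expectations

The historical banding map of the X chromosome has 14 zones × 3 sub-zones.
Assuming similar nucleotide lengths per zone, a scaffold of length L
implies sub-zone length L/42 and zone length L/14; the expected distance
between two landmarks is (map distance in sub-zones) × (sub-zone length).
For the 70,507,862 bp X scaffold this gives 1.678759 Mb and 5.036276 Mb.
The X length itself is recovered from the published four-scaffold assembly
summary statistics two independent ways (total − longest − shortest − N50,
and 2·median − N50) rather than hard-coded blind.  Reported distances are
rounded half-away-from-zero at 1 decimal place (3 for sub-Mb values),
matching the published precision.

## Coverage and interval tracks

* `summed_alignment_depth`: at every position, the sum of the *full*
  lengths of all alignments overlapping it — deliberately not standard
  depth; one long repeat alignment outweighs many short ones, which is
  what makes the track peak at centromeric repeat arrays.  Computed by an
  interval sweep over breakpoints (never per-position loops) and reported
  per bin as the mean over the bin's true width (partial last bin
  included).  Tested for exact equality with a per-position brute force.
* `binned_fraction_covered`: standard union coverage per window (100 kb
  default); duplicated intervals count once.
* `locate_centromere`: argmax bin center after median smoothing over 3
  bins (smoothing is a parameter; whether the original per-position track
  was smoothed before visual calling is not documented), ties to the
  leftmost bin, error on an all-zero track.
* `target_linked_profile`: pairs with ≥ 1 mate in a target region; the
  other mate is counted in bins anchored at the target's boundaries
  (the target is its own bin) and reported as log₁₀(count + 1), so 0 means
  no interactions.  Pairs with both mates in the target count once, in the
  target's own bin, so total counts equal the number of selected pairs.

## Synthetic data generator

The generator produces the three kinds of inputs the analyses need, with
explicit seeds throughout (a root seed derives per-stream sub-seeds).

**SCO tables.**  Each SCO keeps its counterpart chromosome with
probability 1 − θ, else is reassigned uniformly over all chromosomes
(`uniform_any`, so an effective off-diagonal rate of θ·(K−1)/K) or over
the other chromosomes (`uniform_other`).  θ is the knob that makes mean
MMNE sweep monotonically from ~0 to ~1.

**Hi-C pairs.**  A mixture over background and planted features.
Background: left mate uniform, inter-mate distance from a truncated
shifted power law p(d) ∝ (d + d0)^(−α) with α = 1, d0 = 10 kb, drawn
jointly by rejection so the pair fits on the chromosome — this keeps the
near-diagonal decay ridge uniform along the chromosome instead of piling
long-range mass into a corner.  Features: both mates at an anchor pair
plus independent Gaussian jitter, clipped (not resampled) at the
chromosome bounds — clipping slightly inflates edge density, acceptable at
the anchor positions used.  Loop-like interactions default to 150 kb
jitter; SV-like dots to 10 kb, reproducing the broad-dot vs tiny-dot
contrast seen between real fold-back regions and structural differences.
The matched control drops the loop specs and folds their probability mass
into the background, so pair counts are preserved — the control's dot
intensities are a testability choice, since no quantitative description of
real control dots is available.

**The bundled demo configuration** (`fbr_demo_hic_config`) is the study
condition used by the recovery tests and the acceptance script: a
70,507,862 bp X-like chromosome, 200,000 pairs, the three pairwise
fold-back-region interactions plus the inversion-breakpoint dot (2 % of
pairs each), and eight compact short-separation features (0.4 % each,
50 kb jitter, separations 1.2–2.5 Mb) standing in for the small structural
variants and shorter-range dots that populate real contact grids.  Those
short-separation features matter structurally: the k = 12 tree cut
resolves twelve *localized* groups, of which the ≥ 5 Mb separation filter
then removes eight — exactly the division of labour the real analysis
relied on.  A background-only decay ridge cannot play that role (complete
linkage over a contiguous 70 Mb ridge forces merges whose diameters
eventually exceed the distance between adjacent dots, making the cut
unstable), which is why the demo plants discrete features instead.
Optional far-separated SV dots (1 % each) survive the separation filter
and are removed only by subtraction against the matched control, using the
permissive parameter set (≥ 2 Mb, 100 kb bandwidth, q = 0.995, k = 50) and
the control's own set (≥ 1 Mb, 250 kb, q = 0.999, k = 50).

**What the generator does not emulate**: restriction-fragment structure,
mappability and coverage biases, inter-chromosomal contacts, duplicate
reads, and position-dependent MAPQ.  Passing recovery tests therefore
demonstrate correctness of the pipeline's geometry, thresholds and
book-keeping under a faithful signal/noise layout — not robustness to
every artifact of real libraries.

## Problem sizes

The test suite and acceptance script run the full pipeline at the study's
actual scale for the X chromosome (70.5 Mb, 1024²–2048² grids) but with
200,000 simulated pairs — enough for every planted feature to carry
thousands of pairs and for the quantile/clustering stages to behave as
they do at full depth, while each end-to-end run completes in seconds.
Entropy sweeps use 4 chromosomes × 1000 SCOs with 20 replicates per θ.

## Known limitations

* The KDE grid extent is fixed to [0, chromosome length]; densities are
  not reflected at the boundary, so bins within one truncation radius of
  the edges are mildly deflated (matching the naive oracle, which has the
  same property).
* Exactly-k tree cuts inherit the usual instabilities of agglomerative
  clustering when the peak-bin landscape is degenerate (e.g. a single
  contiguous ridge); the separation filter, not the cut, is the robust
  stage.
* MMNE compares chromosome *assignments* only; it is blind to
  intra-chromosomal rearrangement.
* `summed_alignment_depth` reports per-bin means of the per-position
  statistic; the original per-position visualization is recovered with
  `bin_size=1`.
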