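# Methods

This note documents the models and procedures implemented in karstcomm,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make runs
reproducible.

## Lineage delimitation

Input trees are rooted, ultrametric phylograms with branch lengths in
substitutions per site. Consensus trees from Bayesian samplers are only
numerically ultrametric, so ultrametricity is accepted within a relative
tolerance (`rel_tol`, default 1e-6 of tree height) and node depths are
taken as the midpoint of the min/max tip distance below the node.

Delimitation cuts the tree at height *t* above the tips: lineages are the
maximal clades whose crown depth is ≤ *t*; a node at depth exactly *t*
stays within one lineage, and a tip whose first coalescence is deeper
than *t* becomes a singleton lineage. The default *t* = 0.04
substitutions/site is the conventional divergence proxy for these snails;
it is a tunable of `RunConfig`. An alternative reading of a node-depth
criterion — stem depth rather than crown depth — would move the cut by
one branch; the crown (height-cut) reading is implemented because it
yields a unique partition identical to single-linkage clustering of
cophenetic distances at cut 2*t*, which is also how the test-suite oracle
checks it.

Cophenetic distances are rounded to 4 decimal places by default using
round-half-even (IEEE default), for bit-reproducibility across platforms;
`round_digits=None` disables rounding. Zero-length terminal branches
(collapsed identical haplotypes) are legal, so distinct tips may be at
distance 0. The analysis uses one representative tip per lineage — the
first member by sorted label unless an explicit map is configured.

## Outline morphometrics

* **Semilandmarks.** Outlines are closed polygons; orientation is
  normalized to counter-clockwise by signed area so traced direction does
  not affect homology, then *k* points (default 200) are placed at equal
  arc-length intervals starting exactly at the start vertex. The start
  vertex (widest point of the aperture on the right side) is a biological
  judgment made at digitization and is therefore supplied as an index,
  never auto-detected. Input outlines must be complete and closed; no
  gap interpolation is performed.
* **Procrustes.** Generalized Procrustes analysis: center, optionally
  scale to unit centroid size (`keep_size=False`), then iterate optimal
  proper rotations against the running consensus until the consensus
  moves < 1e-8 RMS (cap 100 iterations, warning on non-convergence).
  Reflections are never allowed: left/right shell asymmetry is real
  biology. With `keep_size=True` (the default) centroid sizes pass
  through unchanged, because shell size is itself an ecologically
  relevant trait; this requires all coordinates in a dataset to share one
  length unit. The fitted configurations are finally rotated into a
  canonical frame (scatter major axis on x, 180° ambiguity resolved by
  the third moment), which makes the result invariant to specimen input
  order.
* **Averaging and PCA.** Aligned specimens are averaged per lineage, or
  per lineage × area population when a lineage spans several areas, so
  area-specific morphologies enter separately. PCA is on the covariance
  matrix of the flattened (2k) coordinates — relative warps with uniform
  weighting; no semilandmark sliding and no bending-energy weighting are
  applied, matching the equidistant-resampling design. Score signs
  follow a largest-|loading|-positive convention. The broken-stick rule
  retains the leading run of components whose variance share exceeds
  b_k = (1/p) Σ_{i=k..p} 1/i (always ≥ 1 component); a configuration
  override is available. Trait distances are Euclidean over the retained
  scores (absolute differences when only PC1 survives, the typical
  size-dominated case).

## Null-model analysis

The independent swap algorithm randomizes the binary area × entity matrix
by repeated 2×2 checkerboard flips, conserving all row and column sums
(community richness and taxon occurrence frequencies). Chain mechanics,
which the algorithm's name does not fix, are: each replicate is an
independent chain started from the observed matrix, with
`attempts = 10 × rows × columns × max(row sum)` attempted swaps
(replicate independence was preferred over thinning a single long chain).
The transition kernel is symmetric, so the chain samples the fixed-margin
set uniformly; the test suite verifies this against an exhaustive
enumeration on a small matrix.

SES = (observed − null mean) / null sd, with sd over replicates
(ddof = 1). p-values: a two-sided permutation p with the
add-the-observation convention, 2·min(#{null ≤ obs}+1, #{null ≥ obs}+1) /
(n_reps+1), capped at 1 (never exactly 0); and a secondary
normal-approximation p = 2·Φ(−|SES|), reported because t/normal-style
p-values are common in published tables even when the null is a
permutation distribution. Defaults: 9,999 replicates (configurable down
to 99 for tests). Areas with one entity are dropped with a warning. A
null distribution that is constant up to floating-point summation noise
(sd ≤ 1e-12 of the metric scale) is flagged degenerate and reported as
SES = 0, p = 1.

In the trait analysis the entities are populations, and a randomized
matrix placing two populations of the same lineage in one community is
biologically impossible; such matrices are rejected wholesale and
regenerated (keeping exactly n_reps complete, margin-preserving null
datasets), with rejection counts logged and a retry cap (1,000 × n_reps)
that fails loudly when the constraint is unsatisfiable. Per-community
exclusion was the alternative reading; wholesale rejection was chosen
because it leaves every null replicate a complete dataset with the
observed margins.

The swap chain and the null-metric evaluation are numba-compiled; random
row/column draws come from an explicit 64-bit LCG (MMIX constants) seeded
per replicate from the user seed, so identical seeds give bit-identical
reports on any platform regardless of global RNG state.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not snail anatomy:

* **Trees**: pure-birth (Yule) trees, optionally rescaled to a target
  height; the study-scale bundle uses 15 tips at height 0.3
  substitutions/site — deep enough that a 0.04 cut yields a mid-range
  lineage count.
* **Traits**: Brownian motion from root value 0, tip covariance =
  σ² × shared path length. With σ² = 1 on height-1 trees, one trait unit
  is about one among-taxon standard deviation.
* **Communities**: neutral (uniform sampling without replacement);
  filtering (per-area optimum drawn uniformly over the trait range,
  members sampled among taxa within `filter_window` = 1.0 trait units,
  full width); competition (sequential admission with minimum pairwise
  spacing `competition_delta` = 0.3 trait units, area re-drawn up to a
  retry cap of 10,000 when the target size is unreachable). The
  competition spacing was set at 0.3 because Brownian traits are
  phylogenetically clumped: a larger spacing can admit no 5-member
  community at all on some trees, whereas 0.3 is feasible across
  simulated trees while still producing a strongly positive mean SES.
  Competition operates on trait distance, with the tree linking trait and
  phylogenetic signals — exactly the assumption under which relatedness
  proxies ecology.
* **Outlines**: radial harmonic series around a base circle with a
  Gaussian aperture bump (the start landmark), aspect stretching, and
  radial noise. In the bundle, lineage trait values map to shell size
  classes via base radius ∝ exp(0.35·z), with a small (σ = 4%) area
  effect on size and lineage-specific low-amplitude shape harmonics —
  enough structure for a size-dominated PC1 without imitating real shell
  geometry.

The bundle (7 areas, 2–3 lineages each, every lineage present somewhere,
5 outline replicates per population, one morphology-only "extra" lineage
known from a single shell) writes newick/TPS/CSV files plus a ready
`config.yaml`, and is byte-identical under a fixed seed.

What the generator does *not* emulate: sampling biases of museum
collections, intra-lineage molecular variation (tree tips are lineage
representatives), correlated harmonics of real shell outlines,
measurement error in landmark placement, or spatial structure among
areas. Passing tests therefore demonstrate correctness of the
algorithms and power under idealized assembly rules, not field realism.

## Power

Parameter recovery is measured at a deliberately powered scale — pool 30,
20 areas, 5 taxa per community, 999 replicates, 200 datasets per mode —
where the trait-metric SES averages about +0.85 under competition, −1.5
under filtering, and 0 under neutrality, with directional sign agreement
essentially always. At the study's own scale (7 areas, 2–3 taxa per
community) the directional means persist but the spread per dataset is
wide: single-area significance is rare, and inference should rest on the
across-area pattern. The acceptance script prints both scales.

## Known limitations

* Delimitation assumes an ultrametric tree; phylograms with rate
  variation must be time-calibrated upstream.
* The trait distance defaults to PC1 only; when the broken-stick rule
  retains more components the Euclidean distance over all retained
  components is used, but no per-component weighting is offered.
* The same-lineage constraint can make the null set very small for
  matrices with many shared lineages; the retry cap then aborts with the
  offending margins rather than sampling a biased null.
* TPS support covers LM/ID/IMAGE/SCALE records with 2-D coordinates
  only.
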