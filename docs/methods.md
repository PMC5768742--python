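# Methods

## Scope and data model

The package analyses fragment-resolution Hi-C of a compact genome. All
coordinates are 0-based half-open; the coordinate system for
fragment-resolution work is a `FragmentMap`, an ordered gap-free partition of
each chromosome into restriction fragments (for DpnII, fragments are the
pieces between GATC motif starts; the enzyme cleaves 5′ of the site, so any
consistent cut convention shifts all fragments identically and we cut at the
motif start). Contact matrices store the upper triangle of the symmetric
count matrix over fragments or fixed bins, plus an optional per-row
balancing weight and a mask of zero-coverage rows.

## Balancing (ICE)

Iterative correction finds per-row biases `b` with
`balanced[i,j] = raw[i,j]/(b_i b_j)` and equal balanced row sums over
unmasked rows. The update multiplies `b` by the square root of the
normalised balanced row sums (damped fixed-point iteration); convergence is
declared when the maximal relative row-sum deviation falls below `tol`
(default 1e-5, maximum 200 iterations — common practice values), and
non-convergence is flagged, never silent. Masking is exactly the
zero-total-count rows; no additional low-coverage percentile filter is
applied by default. The bias vector is normalised to mean 1 over unmasked
rows, which fixes the arbitrary global scale.

## Domain annotation

The caller maximises, by dynamic programming, the sum over chosen
non-overlapping intervals of `max(q′, 0)`, where
`q′(k,l) = S(k,l)/(l−k)^γ − μ(l−k)`, `S` is the balanced within-interval
contact sum and `μ(d)` the exact mean quality over all intervals of span
`d`. Unassigned bins between domains are allowed; intervals with `q′ ≤ 0`
are never emitted (a perfectly uniform full-span matrix therefore yields no
domains — the only interval at the full span has `q′ = 0` by construction).
Ties prefer fewer domains, then leftmost starts, making the output
deterministic; multiplying the matrix by a constant rescales every `q′`
uniformly and leaves the segmentation unchanged.

Implementation: per chromosome the matrix is converted to a banded array
`B[i,d] = M[i,i+d]`, from which `S` follows by two cumulative recurrences in
O(n·w) time and memory for band width `w` (`max_domain_bins`, default 900
fragments ≈ 180 kb in the pipeline — comfortably above the largest domain in
the default synthetic design; `None` lifts the cap). The DP itself is O(n·w)
with an exact traceback. On every random dense matrix with n ≤ 12 the DP
objective equals exhaustive enumeration over all segmentations exactly
(tested; the enumeration accumulates gains left-to-right, matching the DP's
addition order, so equality is bitwise).

Defaults: γ = 0.9 at fragment resolution with `min_domain_bins = 2`;
super-TADs use the same program on the ICE-balanced 20 kb binned matrix. A
read-desert fallback re-annotates a chromosome at γ = 0.6 when any domain
edge lies within one bin of a run of ≥ 3 consecutive masked bins, because
coverage deserts can masquerade as borders. A multi-γ consensus mode (sweep
0 … 2.0 in 0.1 steps, keep domains whose edges recur in at least half the
solutions) is available but not the default.

Boundary centers are midpoints between adjacent domains (floor division). A
junction is "same-fragment" when the upstream domain's last fragment and the
downstream domain's first fragment are adjacent indices (no intervening
fragment). Nesting assigns a TAD to the super-TAD — or to the region between
super-TADs, including chromosome-terminal regions — that covers ≥ 75 % of
its length.

## Boundary-element statistics

Signal tracks are piecewise-constant step functions with prefix integrals,
so window means are exact; regions absent from a bedGraph count as zero.
Profiles average the track in 80 bp windows across ±4 kb of each center (100
windows); the background repeats this for uniformly re-drawn centers
(per-chromosome counts preserved, 100 shuffles by default, seeded), and the
enrichment is the elementwise ratio with zero-background windows flagged
rather than infinite. Pair sites are anchor peaks whose interval lies within
`max_gap` (default 200 bp, a fragment-scale co-occurrence criterion) of a
partner peak; the site position is the anchor summit. Co-localization uses a
2 kb tolerance, counting each border and each site once; the three-protein
Venn partition applies the same rule per protein independently. The border
enrichment test is a two-sided Fisher exact test of observed hit counts
against the shuffled expectation.

## Border prediction

Features are per-fragment marker values (mean of the track over the
fragment), Z-transformed per column (population SD; zero-variance columns
dropped with a warning). Labels mark fragments containing a boundary center.
Negatives are subsampled to the positive count by default (border fragments
are a small minority and AUC comparisons between marker panels are the
target; unbalanced mode is available), the data are split into random equal
halves (seeded, stratified), and an L2-regularised logistic regression
(weak penalty, C = 100, lbfgs to tolerance 1e-8 — unpenalised likelihoods
diverge on separable data) is fit on one half and scored on the other. AUC
is computed as the normalised Mann–Whitney rank statistic (ties count ½),
with curve points from the standard ROC construction; the rank AUC is
invariant under strictly increasing score transforms.

## Chromatin-state typing

Each TAD is summarised by the mean of each genome-wide Z-scored mark track
over its interval (length-weighted genome moments; a constant track Z-scores
to zero with a warning). Rows are clustered by Lloyd's algorithm with
k-means++ seeding, k = 8, best of 10 restarts, seeded; the within-cluster
sum of squares is checked to be non-increasing across iterations and a
violation raises. Clusters map to major types by the mark group (active /
inactive / polycomb) with the highest mean centroid Z if it exceeds τ = 0.5
Z units, else "undetermined"; ties are undetermined. The default 15-mark
panel (5 active, 5 inactive, 3 polycomb, 2 neutral) is a conventional
grouping that users override; unlisted marks join the clustering but not the
typing. The type-vs-localization association (active/inactive ×
super-TAD/inter-super-TAD) is a two-sided Fisher exact test, skipped with a
warning when a class is empty.

## Interaction metrics

The distance expectation is computed per chromosome (arm-specific decay) as
the mean balanced contact over unmasked fragment pairs per 200 bp bin of
midpoint separation; empty bins are NaN and pairs falling in them are
skipped and counted. TAD–TAD enrichment averages observed/expected over all
fragment pairs spanning the two (disjoint, same-chromosome) domains;
`expectation_matrix` builds the matrix whose entries equal the expectation,
on which every pair enrichment is exactly 1 — the normalisation identity
used in tests. Condensation is the mean balanced contact over intra-TAD
pairs, excluding fragments with no ligation products, compared only within
the 5–20 kb size-matched set. Adjacent-pair enrichments are grouped by type
pair with seeded bootstrap intervals; the super-TAD contrast compares pairs
inside one super-TAD with pairs whose members belong to different regions.

Planted-boost checks (condensation ratio, pair-enrichment boost) are
evaluated on raw counts: the synthetic matrices carry no fragment bias, so
raw counts are unbiased, whereas balancing provably absorbs part of a
uniform planted block boost into the per-row weights (a 2× planted boost
measures ≈ 1.55× after ICE). The pipeline's reported tables use balanced
counts, with the raw mode available for parity checks.

## Synthetic data

The generator is a pure function of its design and seed (per-purpose
streams derived from the seed, so the fragment map, matrix, peaks and marks
are independently reproducible).

* **Fragments** — i.i.d. geometric lengths with median 194 bp (the DpnII
  digest regime), truncated to tile each chromosome exactly.
* **Domain plan** — the genome is fully tiled by alternating super-TAD
  blocks (2–4 TADs of 8–28 kb) and inter-super-TAD strings (1–4 TADs of
  5–14 kb), snapped to fragment boundaries; chromatin types are drawn with
  region-dependent probabilities (inactive-rich super-TADs, active-rich
  inter regions). An explicit plan can be supplied for targeted tests.
* **Contacts** — independent Poisson counts with intensity
  `λ(i,j) ∝ (s₀ + sep)^(−α) × boosts`, where boosts multiply for same-TAD
  pairs (4×), adjacent-TAD pairs by type pair (I–I and P–P 1.4×, A–A 0.7×),
  and different-TAD pairs inside one super-TAD (1.3×); optional planted
  per-fragment biases exercise ICE, and optional desert intervals force
  zero coverage. The expected total is the depth, 2.7 × 10⁶ contacts per Mb
  by default (the published map's sequencing density), placed within a
  150 kb separation band (beyond the largest planted super-TAD no planted
  structure exists). The decay plateau s₀ = 15 kb encodes the dense-block
  regime of sub-kb maps: within a TAD, contact probability barely decays.
  This is not cosmetic — with a pure power law α = 1 at all scales, interval
  contact sums grow only ~linearly in span while the γ = 0.9 objective
  rewards merging only when they grow ~span^(1+γ), so every caller would
  fragment the domains; in the plateau regime the caller reproduces the
  planted annotation essentially exactly when noise is removed (703 called
  vs 696 planted domains, contiguity 1.0 on the noise-free intensity).
* **Peaks/tracks** — at each planted boundary, with probability 0.77 a
  BEAF-32 peak plus a partner (CP190 or Chromator, equal odds) is planted at
  the center with 100 bp Gaussian jitter; solo border occupancy and uniform
  background peaks (40 per Mb per protein) are added. Occupancy tracks are a
  positive baseline (1.0) plus 80 bp-binned Gaussian noise (SD 0.2) plus
  box-shaped peak bumps (amplitude ≈ 5) — the modENCODE-style normalized
  tracks the enrichment ratios are meant for; a zero-baseline impulse track
  would make the central-window ratio statistically uninterpretable at
  realistic peak densities.
* **Marks** — per mark, unit Gaussian noise in 200 bp bins plus an effect of
  3 Z units inside TADs whose type matches the mark's group.

**What the generator does not emulate:** mappability and GC biases beyond a
flat multiplicative fragment bias, trans contacts, replicate-level
variability beyond Poisson resampling, loop/corner-peak structure (absent in
the fly), and real peak-width/signal distributions. Passing tests therefore
validate the algorithms and their calibration on data whose generative
assumptions are known to hold; they do not certify performance on real
libraries with unmodelled artifacts.

## Numerical and design choices

* Banded quality arrays switch to float32 above 2×10⁶ cells; the DP
  objective on small test matrices is float64 and bit-reproducible.
* Fragment-to-bin assignment is by fragment midpoint (unambiguous for
  straddling fragments); binning conserves total counts exactly.
* Map resolution follows the standard convention: the smallest candidate
  bin size at which ≥ 80 % of covered bins have ≥ 1000 contacts, falling
  back (flagged) to the largest candidate.
* Replicate correlation is the Pearson correlation of raw binned counts
  (default 20 kb) over the union of non-zero upper-triangle entries.
* Permutation and bootstrap procedures, shuffled backgrounds, k-means
  restarts and train/test splits all take explicit seeds; a pipeline re-run
  with the same config and seed reproduces the report bit-for-bit on one
  platform.
* The AUC calibration check under permuted labels uses balanced classes at
  n = 2000 (null AUC SD ≈ 0.013) so that the ±0.05 acceptance band is a
  ≈4σ test; at a 5 % positive rate the same band would be ~1σ and
  uninformative.
* The condensation-parity null uses type-independent surroundings (no
  type-dependent neighbour boosts, types independent of region): with
  type-dependent neighbour boosts, balancing couples a TAD's condensation to
  its neighbours' types, which is a real inequality rather than a test
  artifact.

## Problem sizes

The default synthetic design is one 10 Mb chromosome (~36 k fragments,
~700 TADs, 2.7 × 10⁷ contacts); the full simulate–balance–call cycle runs in
about a minute on one CPU. Unit tests use 0.3–2 Mb genomes; calibration
ensembles use 100 seeded repeats of geometry-only simulations (no contact
matrix needed). These sizes were chosen so the whole validation cycle stays
interactive while every statistic retains enough events to be tested at its
stated tolerance.

## Known limitations

* The caller over-segments noisy dense regions (extra abutting sub-domain
  boundaries) at finite depth; planted boundaries remain a subset of the
  called edges, so recovery is unaffected while the called domain count
  exceeds the planted one.
* Balanced condensation is coupled to a TAD's wider environment through the
  row-sum constraint; cross-type comparisons should use the size-matched set
  and, for planted-truth validation, raw mode.
* `run_pipeline` orchestrates the synthetic study end-to-end; external data
  flow through the library functions and the stage-level CLI commands
  (`matrix`, `call`, `enrich`, `predict`, `interactions`) instead.
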