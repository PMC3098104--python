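# Methods

`lincontig` assembles BAC clones into ordered contigs from restriction
fingerprints. A clone's fingerprint is a multiset of bands; band `b` has a
dye/enzyme type `k_b ∈ {1..K}` and an integer scored size, and two bands
match when their types agree and their sizes differ by at most the
tolerance `t`. Everything downstream is built on the statistics of the
shared-band count `k` between two clones with `n1` and `n2` bands.

## Overlap significance

Three p-value metrics estimate `Pr(c1, c2)`, the probability that two
*random* clones share at least the observed overlap statistic:

* **`sulston`** — the classical binomial approximation: with per-band
  match probability `p1 = 1 − (1 − (2t+1)/G)^n2` over a universe of `G`
  distinct band values, the upper binomial tail `P(K ≥ k)` is evaluated in
  log space. Accurate while `k` is small relative to `n1`; it degrades
  for strongly overlapping clones (relative error at `k = 3`, `n1 = 5` is
  tens of percent), which is the motivation for the calibrated metrics.
* **`siid`** — Monte-Carlo calibration under the same iid model. `reps`
  random clone pairs are simulated (uniform draws over the
  tolerance-collapsed universe `G_eff = G/(2t+1)`, duplicates collapse),
  the empirical complementary CDF of the shared count is recorded, and the
  deep tail is approximated by `exp{−(a0 + a1·k + a2·k²)}`. Below the
  threshold `k0` (the point past which the fitted tail stays under 1e-3)
  the empirical table is used directly.
* **`sind`** — the abundance-weighted variant. Band-class abundances
  `f_b` are estimated from the whole database: classes pool the sorted
  size axis per type (a new class starts when the gap exceeds `t`),
  `π_b = N_b/N` is the fraction of clones carrying the class, and
  `f_b = min(1, n_mean⁻¹ · π_b/(1−π_b))` (the small-`f` maximum-likelihood
  approximation; `π_b = 1` caps the odds at `N`). The overlap statistic
  becomes `k_w = −Σ ln f_b` over matched bands, so sharing rare bands is
  stronger evidence than sharing ubiquitous ones, and the Monte-Carlo
  calibration draws band classes with probability proportional to `f_b`.
  Under uniform abundances `k_w ∝ k` and the ranking collapses to `siid`.

Shared genetic markers multiply any of the p-values by `exp(−a_mark)` per
marker, `a_mark = 100 ln 10` by default, i.e. one shared marker alone makes
a pair more significant than `10⁻¹⁰⁰`.

### Numerical choices in the tail fit

The quadratic is fitted by least squares on support points subsampled at
~80 log-spaced tail levels between `10/reps` and `0.5`. Restricting the
fit to the deep tail alone (tails in `[10/reps, 1e-3]`) leaves only one to
three support points at practical `reps` and produced erratic, sometimes
concave fits whose extrapolations differed by orders of magnitude between
adjacent band-count cells; the wide, quantile-balanced window makes the
fits stable and mutually consistent. `−ln P(K ≥ k)` is convex in `k`, so
a concave fit is rejected in favour of the linear one. Beyond the largest
simulated statistic the fitted curve is continued *linearly* (slope taken
at the support end): true deep tails grow like `k log k`, so an unbounded
quadratic would overstate the significance of near-duplicate clones —
and, because the ordering criterion sums these weights, would actively
distort clone ordering. `k0` keeps the paper-style empirical/fitted
switch at tail `1e-3`.

Calibrations are cached on a grid: band counts round to the nearest
multiple of 10 and all pairs in a cell share one tail model. The
abundance model additionally serves every cell from two master draw
matrices (column prefixes are iid draws), with a two-pointer kernel for
the per-pair weighted intersection; this keeps an all-pairs run on ~1000
clones within tens of seconds at the default `reps = 50,000`.

## The net of significant overlaps

Pairs with `Pr < Pr_0` (default `1e-12`) form an undirected net with edge
weights `W_ij = −log10 Pr`. Because a chromosome region at coverage ≳3 is
tiled by several clones, every *true* overlap should be corroborated by a
short parallel path. The TENPP filter works in one pass of two phases:
edges without a simple parallel path of 2–5 edges are excluded, then (on
the edge-filtered net) every vertex with some neighbour pair that cannot
be re-connected by a 2–5-edge path avoiding it is excluded. Exclusions
are pooled, not destroyed — merging re-admits them later. The pass is
deliberately not iterated to a fixpoint; the adaptive clustering loop
re-applies it per round, which suffices unless false overlaps are very
frequent.

Linearity of a cluster is diagnosed against a *diametric path* (the
longest among all-pairs shortest paths, ties broken by smallest endpoint
ids): the rank of a vertex is its edge distance to the path, and ranks ≥2
mark non-short offshoots incompatible with the linear chromosome. A
non-linear cluster is split by removing the branching path vertices
(those attaching a rank-≥2 offshoot) and re-testing components until all
are linear.

## Adaptive clustering

Single-linkage clustering at cutoff `Pr_0` equals connected components of
the thresholded net. The loop: cluster the unfrozen clones at the
current cutoff; run TENPP inside clusters above the large threshold
(default 500); recompute components; freeze clusters of reasonable size
(6–500 clones) so later rounds cannot dissolve them; tighten the cutoff
by ×1e-3 and repeat while large clusters remain (default at most 10
rounds, remaining large clusters are flagged unresolved). Clones in
sub-minimal clusters or excluded by TENPP stay available for elongation.

## Ordering

Within a linear cluster the order `Ω` maximises
`W(Ω) = Σ W_{Ω(i),Ω(i+1)} − b(Ω)·W0`, where `b(Ω)` counts adjacent pairs
that are not significant at `Pr_0` and `W0` (default `−log10 Pr_0`) is
the per-gap penalty. This is an open-path TSP with distances
`d(c_i,c_j) = Wmax − W_ij + W0·1{Pr > Pr_0}`; unevaluated pairs enter
with `W = 0`. The solver is a multi-start nearest-neighbour construction
refined by 2-opt and Or-opt moves over the closed tour through a zero-cost
dummy city; it provably matches the exhaustive optimum on every random
instance up to n = 9 in the test suite, and acceptance is always by
criterion value, not by matching a particular solver.

Before ordering, buried ("parallel") clones are detached and re-attached
to their best host afterwards: clones whose fingerprints are near-copies
of a longer clone carry no independent order information, and at 12–13×
coverage they dominate the cluster. The detachment threshold on the
matched fraction is 0.84 by default, derived from the noise model: a
fully contained clone matches `τ·(1−p_missing) ≈ 0.94·0.95 ≈ 0.89` of its
bands in expectation, and two binomial standard deviations at ~100 bands
give ≈0.05 of slack. The containment-query default (`find_buried`)
remains the stricter `q = 0.90`.

Order robustness is estimated by jackknife resampling of the *band
universe*: each replicate removes a random 5% of the band classes
(every occurrence of them), recomputes overlaps restricted to the kept
bands against the same calibrated tail models, reorders, and tallies each
clone's left/right neighbours after canonical orientation;
`instability(c) = 1 − mean_side max_nbr frequency`. Dropping classes
rather than per-clone bands avoids the artificial significance inflation
a bootstrap over bands would cause. Clones above an instability
threshold can be removed to form a stable skeleton order.

## Merging, MTP, verification

Contig ends are elongated at a relaxed cutoff by re-admitting excluded
clones and singletons: two contigs merge when their ends connect directly
or through at most two intermediate clones, provided the merged net stays
linear and no marker-zone conflict arises; an end with several mutually
exclusive linear continuations blocks all of them and is only reported
(wet-lab evidence, e.g. BAC-end sequencing, has to disambiguate).

The minimal tiling path is the shortest chain (in clone count) of
significant overlaps between the contig's terminal clones — a Dijkstra
search with the lexicographic cost (hops, −summed weight), so among
equally short chains the most significant one wins.

Externally supplied contigs are verified by recomputing their overlaps
and classifying problems into: non-connected nets, buried-clone
conflicts (connectivity lost after detaching buried clones),
reorder-fixable gap patterns, marker conflicts (one marker on
non-overlapping clones), and non-linear topology.

## The library simulator

The simulator emulates high-information-content fingerprinting of a BAC
library from a genome sequence:

| parameter | default | meaning |
|---|---|---|
| boundary enzyme | HindIII (AAGCTT) | clone ends sit on its sites |
| K protruding enzymes | BamHI, EcoRI, XbaI, XhoI | band types 1–4 |
| blunt enzyme | HaeIII (GGCC) | cuts, but bounds no band |
| mean / sd clone length | 120 / 30 kbp | via `a = 120λ`, `σ = 30λ`, `λ = (N+1)/L` |
| `p_chimer` | 0.05 | clone is a union of ≥2 independent clones |
| band window | 50–500 bp | outside: filtered |
| clone band window | 50–250 | outside: clone dropped |
| `ε`, `p_ε` | 0.2, 0.90 | two-component uniform size error |
| scale | ×30, rounded | FPC units; tolerance `t = 2ε·30 = 12` |
| type offsets | (k−1)·5000 | added to the scaled size in sizes files |
| `p_missing` | 0.05 | independent band dropout |

Clones pick a uniform start site index, a ±1 direction, and a site count
`h = ⌊Normal(a, σ²)⌋`; out-of-range ends clip to the chromosome ends and
zero-length draws are redrawn. Within a clone, fragments are delimited
by the protruding-end sites, the blunt sites and the clone ends; each
fragment yields one band per *distinct* protruding enzyme bounding it
(two different protruding enzymes ⇒ the fragment appears twice; blunt or
end on both sides ⇒ no band). The probability that two observations of
one band fall within the tolerance is the closed form
`τ = p_ε²(1−(1−t/2ε)²) + p_3ε²(1−(1−t/6ε)²) + 2·p_ε·p_3ε·(t/3ε)`,
= 0.94 at the defaults.

Two properties of the realized clone-length distribution are worth
stating explicitly. The floor in `h` and end clipping shave ~2–3% off
the 120 kbp nominal mean. And the *bp-length* spread is larger than the
nominal 30 kbp: lengths are sums of `h` site spacings whose gaps have
CV ≈ 1 on an i.i.d. genome, adding `E[h]·spacing²` to the variance — the
realized sd is ≈36 kbp. The model is implemented exactly as specified;
the reported statistics are the honest consequences.

What the generator does *not* emulate: repeat structure (the i.i.d.
random genome has no repeated elements, so band "linkage disequilibrium"
and repeat-driven false overlaps are absent), sub-library length mixtures
(real libraries can be bimodal in insert size), partial digestion, and
gel-calling artefacts beyond the uniform size error. Passing the
end-to-end tests therefore demonstrates correctness of the machinery on
clean-to-moderately-noisy data, not performance on repeat-rich genomes —
the regime where the abundance weighting and parallel-path filtering are
expected to help most but where no synthetic ground truth is available
here.

## Problem sizes and defaults used in the shipped runs

The end-to-end benchmark uses a 10 Mbp synthetic genome at 44% GC, 1000
simulated clones (~12× coverage, ~940 retained), the full noise model and
5% chimeras; calibration uses 50,000 Monte-Carlo pairs per band-count
cell; ordering uses 4 restarts; jackknife is off by default in pipeline
runs (it is exercised separately at replicate counts of 12–30) because
its cost is `replicates ×` the cluster's overlap+ordering cost. All
stages take an explicit seed; a fixed seed reproduces outputs
bit-identically.

## Known limitations

* Band maps (consensus band coordinates) are out of scope; MTP selection
  is purely topological, and clone-end bp coordinates are not estimated.
* The sizes-file type encoding (`size + (k−1)·5000` with scaled sizes up
  to 15,000) is not uniquely decodable; files are best re-read untyped
  (`use_offsets=False`), which preserves tolerance matching except at
  rare bucket boundaries.
* Ambiguous elongations are reported, never auto-resolved.
* The `M*`/`M**` small-cluster-corrected partition-overlap statistics are
  represented only by the `min_cluster` suppression knob.
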