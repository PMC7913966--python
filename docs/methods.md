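# Methods

## Model and objective

A shapelet s is a short real-valued sequence; its distance to a series t
is the minimum over all |t|−|s|+1 aligned windows w of the
length-normalized squared Euclidean distance Σᵢ(sᵢ−wᵢ)²/|s|. All windows
are considered, including the terminal one, so an exact suffix occurrence
scores 0; the distance is 0 exactly when the shapelet occurs pointwise in
the series. Normalizing by shapelet length is deliberate: individuals mix
shapelets of different lengths inside one fitness value, and unnormalized
sums would systematically favour short shapelets. Neither shapelets nor
windows are z-normalized by default; `TimeSeriesDataset.standardized()`
offers per-series standardization for data whose scale varies.

A shapelet set S = {s₁..s_K} maps a labeled collection (T, y) to the N×K
distance matrix D. Discovery minimizes the loss of a classifier on (D, y);
the discovery and the final classifier are decoupled.

## Fitness

The fitness of a set is the pair (error, complexity), compared
lexicographically:

* **error** — in-sample mean log loss of a multinomial logistic regression
  with fixed ridge penalty (C = 1, lbfgs), fitted on (D, y). The solver is
  deterministic, so identical sets always score identically, and results
  are cached by shapelet content so only modified offspring are
  re-evaluated.
* **complexity** — Σ|s|, breaking error ties toward simpler sets.

Exactly duplicated columns of D are dropped before the fit. A ridge
penalty is not duplicate-column invariant — a doubled column halves its
effective penalty and *lowers* the in-sample loss (≈1e−2 in measurements),
which would make redundancy fitter; deduplication restores the intended
semantics (duplicating a shapelet leaves the error unchanged and strictly
worsens fitness through complexity).

One fitness evaluation costs O(K·N·M²) pointwise comparisons; an
instrumented counter in `core` asserts this bound in the tests.

## Evolutionary loop

Generational scheme with population P (default 100), generation cap G
(default 100), early-stopping patience (default 10), per-operator
crossover probability 0.4 and mutation probability 0.1.

* **Initialization** — per individual, K ~ Uniform{2..W}; the strategy is
  K-means centroids of max(10K, 50) equal-length random subsequences, or K
  verbatim random subsequences of independent lengths, with equal
  probability among the enabled operators. Lengths are uniform in
  [4, max_len]; max_len defaults to the shortest series length M. The
  default W = ⌈√M⌉ keeps initial sets small so growth must pay for itself.
* **Selection** — tournaments of 3 sampled without replacement; the winner
  is drawn with probability proportional to its reverse rank inside the
  tournament (rank weights rather than loss values avoid loss-scale
  sensitivity).
* **Crossover** — consecutive pairs of the selected parents; each enabled
  operator fires independently with probability 0.4: one/two-point
  crossover on the member lists, one/two-point splices of individual
  shapelets at a cut common to both (within the shorter length), and a
  barycenter merge (pointwise mean; with unequal lengths, the shorter
  shapelet is averaged against a uniformly placed window of the longer and
  the child keeps the shorter length). Degenerate cuts that would empty a
  child fall back to clones.
* **Mutation** — each enabled operator fires independently with
  probability 0.1 per offspring: trim 1..⌊|s|/2⌋ points off one end of one
  shapelet (no-op below the minimum length 4), remove one shapelet (no-op
  on singletons), or append a fresh random subsequence. The add mutation
  is the growth engine of the search; with sets capped below the number of
  decision boundaries a problem needs, disabling it leaves the search on a
  visibly worse plateau (reproduced in the acceptance tests on four-class
  motif data).
* **Elitism and stopping** — the incumbent best individual replaces the
  worst offspring each generation and is exempt from crossover and
  mutation, making the best-fitness trace non-increasing. The loop stops
  at the generation cap or after `patience` generations without strict
  lexicographic improvement. The logged population mean includes the
  exploration fringe (freshly injected random shapelets), so plateau
  comparisons use the converged best fitness.

Fitness uses in-sample loss rather than a held-out split: it is cheap,
deterministic, and the max-length cap plus complexity pressure are the
overfitting controls; the final classifier is the place where validation
happens.

## Downstream classification

`fit_tuned_lr` grid-searches regularization type (ridge vs lasso) and
strength C ∈ {0.001, …, 1000} — 14 configurations — by stratified 3-fold
cross-validated log loss, refitting the winner on all data; ties prefer
stronger regularization. Classes smaller than the fold count reduce the
fold count with a warning. `tune_max_len` selects max_len from
{⌈M/4⌉, ⌈M/2⌉, ⌈3M/4⌉, M} by the 3-fold CV log loss of the ridge model on
the transform of a reduced-budget evolution (default P = 25, G = 30); the
reduced budget keeps the protocol desk-scale and only sharpens the same
comparison a full-budget run would make.

## Baselines

`information_gain` scores a candidate's distance vector by the best
entropy reduction (base 2) over all midpoint thresholds between distinct
sorted distances, ties broken toward the wider gap. `top_k_independent`
ranks every distinct subsequence of the collection by its individual gain
and keeps the top k — deliberately with no interaction between picks and
no similarity pruning, since redundancy among near-tied candidates is
precisely the failure mode under study. Candidate scoring is vectorized
per length (one Gram-matrix multiplication against all series windows),
which keeps full-range enumeration at N = 35, M = 100 in the tens of
seconds. Rank ties keep enumeration order, so shorter and earlier
candidates win.

## Synthetic data

The generators are constructions, not simulations of any particular
instrument; each is engineered so the phenomenon it demonstrates is
provable at desk scale.

* **Imbalanced three-class** (25/5/5 per class in train and test, length
  100). Class 0: one smooth waveform + N(0, 0.05) noise — a tight cluster.
  Classes 1 and 2: a shared second waveform + N(0, 0.3) noise, differing
  only in a ±half-sine motif over a fifth of the series. The motif
  amplitude (4.0) is large relative to both waveforms so that
  majority-class subsequences never align inside the motif region; their
  distances to the two minority classes are then identically distributed,
  which is what makes the independent top-k transform blind to the 1-vs-2
  boundary. With a smaller amplitude the motif region occasionally becomes
  the best alignment and leaks genuine 1-vs-2 signal into the baseline.
* **Nested amplitudes** (4 series, length 50, bump width 20, noise 0 by
  default, ≤0.01 supported). Zero baseline plus one flat-top bump of
  amplitude a: class A ∈ {0, 4}, class B ∈ {1, 3}. For boxcar bumps every
  in-data window sits at distance ∝ min((a−b)², b²) from the series of
  amplitude b, which interleaves or ties the classes — no threshold splits
  4/4 (verified exhaustively in the tests, not assumed). The flat top
  matters: a smooth arch lets short windows ride another amplitude's
  rising edge and leaks a separator. The amplitude-2 bump — the pointwise
  mean of the two class-B bumps, reachable by the barycenter crossover —
  yields distances 4E vs E (E = normalized bump energy = 1): a perfect
  split with margin ≈ 3.
* **Motif data** (generic fixture): baseline noise with one distinct
  implanted motif per class (c+1 sine half-periods, alternating sign,
  amplitude 1.5) at a uniformly random position. Separable by one shapelet
  per class at zero noise; the four-class variant is the fixture where
  two-member sets are genuinely undersized.

What these generators do **not** emulate: trends, autocorrelated or
heteroscedastic noise, warped or multi-scale motif instances, variable
sampling rates. Passing tests therefore certify the algorithmic claims —
set-level evaluation, out-of-data reachability, elitism, operator roles —
not performance on field recordings.

## Stability

`dtw_distance` is the classic O(nm) dynamic program with absolute-
difference local cost, full alignment and no warping window; path-length
normalization is available but off by default, since the compared
shapelets have similar scales and lengths. `stability_matrix` is the
pairwise DTW matrix between the sets discovered by two runs; the
acceptance check asserts that every shapelet of one run has a partner in
the other below the median inter-pair distance.

## Measurement protocol and problem sizes

The imbalanced-data comparison reports the mean test accuracy over five
independently generated train/test pairs, mirroring the repeated-resample
protocols standard for these benchmarks: a single test split has only 10
minority samples, so one draw of its accuracy is binomially noisy while
the phenomenon itself (majority separated, minorities confused) is
deterministic. The two-shapelet constraint is realized by initializing
with W = 2 and enabling only size-preserving operators (per-shapelet
crossover, merge, mask); the single-shapelet search seeds the same loop
with singleton sets. Evolution budgets in the shipped experiments
(P = 50, G = 60 for the comparisons; P = 25 elsewhere) are the sizes at
which every demonstrated effect is already stable under reseeding.

## Numerical notes and limitations

* Distances clip tiny negative Gram-identity residues to 0; oracle
  equivalence is asserted to 1e−9.
* Batch information gain evaluates only thresholds between distinct
  distances; constant vectors score 0.
* Argmax ties in exhaustive search resolve to the shorter, then earlier
  candidate; the enumeration deduplicates exact value matches.
* Reproducibility is exact for fixed (data, config, seed); the engine
  draws all randomness from one `numpy` Generator.
* Known limitations: no multivariate series, no DTW-based matching during
  discovery, no self-similarity pruning in the baseline (by design), and
  the per-candidate batch scorer holds one length-class of windows in
  memory at a time (fine to M in the thousands, not beyond).
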