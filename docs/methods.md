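# Methods

## Problem and model

The package targets pool-based batch active learning for binary
synthesizability labeling of ionizable lipids. Labels come from expert
step-count estimates through a strict threshold rule: a molecule is
synthesizable iff the estimated number of reaction steps is fewer than *k*
(`LabelingPolicy`, default *k* = 15; the threshold is a per-laboratory
feasibility choice, and values up to ~25 are defensible).

The classifier is an ensemble of gradient-boosted decision-tree models over
count ECFP fingerprints (radius 3, 2048 slots, chirality-aware, counts
folded modulo the slot count so hash collisions add). Boosting itself — the
stagewise additive update F_m = F_{m−1} + η·f_m under binary log loss — is
delegated to LightGBM; the package owns the ensemble construction (members
differ by seed, row subsampling 0.8 and column subsampling 0.8 per tree),
the posterior-draw composition, and everything downstream. Engine defaults
are sized for the tens-to-hundreds-of-samples regime of labeling campaigns:
100 iterations, learning rate 0.1, depth 6, `min_child_samples` 2 and
`max_bin` 15 (fingerprint counts are small integers). Columns that are
constant on the training set cannot host a split, so the fitted handle drops
them and stores the column mask; this is model-invariant and substantially
faster on combinatorial pools where most fingerprint slots are empty.

## Posterior draws

Model uncertainty is approximated by 100 probability draws per molecule
(10 members × snapshots at 10 evenly spaced boosting stages, the final
snapshot being the full expansion). Draws are deterministic given the
fitted handle. The composition scheme is pluggable: the acquisition layer
depends only on the draws-matrix contract (rows = candidates, columns =
draws, entries in [0, 1]), so any other virtual-ensemble scheme can be
substituted. Early-stage snapshots are systematically less extreme than the
converged model, which widens the spread of draws for hard candidates —
exactly the behaviour the entropy estimates exploit.

## Acquisition

For two candidates the joint law of the predicted labels is estimated as a
mixture of per-draw product Bernoullis: conditionally on a draw the two
predictions are independent, and the mixture over draws carries the shared
model uncertainty. Pairwise joint entropies (base 2; the base only rescales
scores and never changes the argmax) fill a symmetric matrix whose diagonal
holds the marginal entropies of the per-candidate mean Bernoulli. Batch
joint entropy is approximated by assuming all dual total correlations vanish
for N ≥ 3, giving (1/(N−1))·Σ_{i<j} H(X_i, X_j); the batch optimizer
equivalently maximizes the pair sum Σ_{i<j} H(X_i, X_j). The approximation
is exact at N = 2 and for mutually independent candidates, and overestimates
under higher-order redundancy (three perfectly correlated fair coins score
1.5 bits against a true 1 bit) — an acceptable bias for ranking batches.

Numerical conventions: 0·log 0 = 0; joint probabilities below 1e-12 are
treated as exact zeros; probabilities entering log loss are clipped to
[1e-15, 1−1e-15].

Optimizers: `exhaustive` enumerates all C(n, N) batches (refused above 10^5
combinations — the error advises greedy); `greedy` seeds with the maximal
pairwise entry, grows by best acquisition gain, and finishes with one
single-swap improvement pass; `random` samples uniformly without
replacement. All ties break toward the lowest candidate index, making every
optimizer deterministic given its seed.

## Pools

Candidate pools are assembled by a head–linker–tail grammar with single-bond
junctions (RDKit attachment markers, zipped with `molzip`). This is a
deliberate simplification of reaction-based fragment recombination: it
preserves the pool's role in the pipeline without encoding any proprietary
reaction set. Filtering applies, in a fixed order that makes removal counts
reproducible: validity → uniqueness (canonical SMILES, toolkit-internal
keys only) → molecular weight within [500, 1500] Da inclusive (average
atomic masses) → largest SSSR ring ≤ 8 atoms → banned-moiety SMARTS list
(the shipped default list is illustrative; laboratories maintain their own).
Diversity reduction is K-means (Euclidean on count vectors, 4 seeded
restarts keeping the best inertia) with the nearest-to-centroid member as
each cluster's representative.

## Campaign driver

A round fits the ensemble on the labeled set, draws the posterior over the
pool, builds the entropy matrix and selects a batch (default size 30).
Annotators may skip molecules: skipped selections are parked (not
re-selected, not counted as labels). Redundant annotations resolve by
unanimity, else majority for ≥ 3 annotators (flagged), while two-way ties go
to a conflict list for human resolution — a tie was resolved by reading the
annotators' free-text reasoning in the campaign this mirrors, which is not
automatable. If a record carries both a step estimate and an explicit label
that disagree under the policy, the explicit label wins (annotator intent)
and the record is flagged. Agreement statistics count molecules with ≥ 2
non-skipped annotations; percent agreement is 100·(redundant −
disagreeing)/redundant.

## Retrospective experiments

Label efficiency is measured by simulated campaigns on a fully labeled
dataset: per replica, an initial set (default 25) is drawn from the training
partition (default 215 = 25 + 190), and selection/reveal/refit iterates
with batch size 10 until test accuracy (ensemble mean, 0.5 threshold, fixed
stratified 42-sample test set) first reaches the target (default 0.83),
recording the labeled-set size; replicas that exhaust the pool are censored
at init + pool size and excluded from means/medians but counted. Arms
("al" = joint-entropy greedy, "random") share initial sets per replica by
default (paired design, variance reduction; an unpaired mode exists).
Convergence histograms use batch-width bins with right-to-left tail
widening until the final two bins each hold ≥ 5 replicas, and distributions
are compared by a Pearson chi-squared contingency test without continuity
correction (uniform rule for any number of bins).

The shipped experiment sizes (50 replicas in the test suite and acceptance
script, against 200 in a full study) keep a complete run at a few minutes on
one CPU while leaving the median comparison stable; the replica protocol is
unchanged.

## Synthetic data

`synthdata` emulates a withheld expert-labeled campaign. Molecules are
head–linker–tail assemblies from a built-in library (8 ionizable amine
heads, 6 diester/amide/aromatic linkers, 8 C16–C22 aliphatic tails; 384
products, ~99% inside the 500–1500 Da window). The step-count oracle is
additive: base steps + a coupling cost per fragment + moiety penalties
(aromatic ring +2 once, each alkene +1, sulfur +2 once), evaluated on the
canonical SMILES so it is spelling-invariant. Coupling costs are bimodal —
each fragment is independently routine (1–2 steps) or synthetically
demanding (5–7 steps) with probability 0.5 — which keeps most step counts
away from the labeling boundary, the way routine couplings and exotic
chemistry separate in practice, and guarantees the retrospective target
accuracy is reachable on held-out data. A single integer offset on the base
step count is tuned so the realized positive fraction lands within ±0.05 of
the 0.60 target (matching the roughly 60/40 balance of a real campaign's
total dataset); if the cost table cannot reach the target the generator
raises rather than silently drifting. Redundant annotations default to the
observed campaign pattern (≈23 double- to 7 triple-annotated per 30
redundant molecules) with one annotator flipped per disagreeing molecule
(disagreement rate default 1/30). `make_learnable` optionally flips each
label with probability (1−s)/2 to dial the structure–label signal from
fully deterministic (s = 1) to none (s = 0).

What the generator does *not* emulate: real reaction-step estimation,
annotator-specific biases, scaffold-correlated label noise, and the
chemical diversity of LLM- or literature-derived pools. Passing tests on
synthetic campaigns therefore demonstrate the pipeline's mechanics and the
selection strategy's label efficiency under a structure-determined labeling
rule — not predictive accuracy on any real lipid series.

## Known limitations

- Canonical SMILES are RDKit-specific; uniqueness sets are not portable
  across toolkits or versions.
- The greedy optimizer is a heuristic: it matches the exhaustive argmax on
  ≥ 90% of small random instances and never exceeds it, but carries no
  approximation guarantee.
- The pair-sum acquisition ignores higher-order redundancy by construction;
  batches of near-duplicate uncertain candidates are penalized only through
  pairwise correlation.
- Censoring in retrospective runs is recorded, not modeled; heavily
  censored configurations make the mean/median comparison fragile.
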