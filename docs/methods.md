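# Methods

## Scope and model

`screenopt` optimizes docking-model parameterizations against a labeled
retrospective dataset. A *parameterization* is one complete assignment of
searchable parameters — numeric tunables such as the electrostatic and
ligand-desolvation thin-sphere radii (Å), categorical pose-sampling
controls, and a matching-sphere set — and a *docking model* is a
parameterization combined with a docking engine. The engine is a
pluggable backend: given (parameterization, dataset, seed) it returns one
total score per molecule plus an electrostatic / van-der-Waals /
ligand-desolvation breakdown that sums to the total (within 1e-9, checked
on every result). Scores are energies: lower is better.

## Enrichment metric

The criterion is normalized LogAUC on the semilog ROC. The ROC is the
piecewise-linear curve through the cumulative (FPR, TPR) counts at each
distinct score; tied scores contribute a single diagonal segment. This
diagonal convention reproduces the expectation over random tie-breaking
exactly for the curve's vertices and for the uniform-weight AUC; for the
log-weighted area it is the standard deterministic convention rather than
the exact expectation (the two differ by a term of the order of the tie
block's width, and coincide in the untied case). The semilog area is

LogAUC = ∫_λ^1 TPR d log₁₀ FPR / log₁₀(1/λ),  λ = 0.001 (configurable),

computed in closed form per linear segment. FPR values below λ are
clamped to λ with TPR interpolated at λ. Normalization subtracts the
diagonal's expectation R = (1−λ)/(ln10·log₁₀(1/λ)) and divides by (1−R),
so perfect → 1 exactly, random → 0 in expectation, worst → −R/(1−R). The
un-rescaled variant (LogAUC − R) is registered as the criterion
`adjusted_logauc`; criteria are addressed by name so different pipeline
steps can use different ones.

Numerics: the perfect case (TPR ≡ 1 on [λ, 1]) is returned as exactly 1.0
rather than through the segment sum, so the boundary semantics are exact
and the metric never exceeds 1 by rounding. A rank-based fast path (used
by the null simulator) computes the same quantity from the positives'
positions in O(n_pos) and is tested to agree with the generic path to
1e-12; the generic path is tested against dense numerical integration on
every ranking of ≤ 8 molecules to 1e-9.

## Null distribution and significance

The null is the conditional distribution of normalized LogAUC when
`n_pos` positives are placed uniformly at random among
`round(ratio·n_pos)` negatives; the default ratio is 50 negatives per
positive, the canonical retrospective benchmark shape. The default desk
scale is 1e5 replicates (cached to text files keyed by n_pos/ratio/
reps/seed); an exact enumeration mode covers small datasets and anchors
the Monte-Carlo version in tests. Significance of a best-of-N search uses
the Bonferroni-corrected level p/N (default p = 0.01) and the empirical
(1 − p/N) quantile with "higher" interpolation, which is conservative: the
rejection rule never exceeds its nominal family-wise error. If p/N falls
below 1/reps the threshold is refused with an instruction to rerun with
more replicates rather than silently extrapolating the tail; the
pipeline records the threshold as unavailable in that case. Bonferroni
assumes independent tests and is strictly conservative for the positively
correlated models that neighboring parameter values produce.

## Matching-sphere perturbation

Each candidate sphere file spawns variants by displacing every sphere
independently with a draw from the uniform distribution over a 3-ball of
radius 0.4 Å (default): direction from a normalized Gaussian, norm
R·U^(1/3), which is exact — (norm/R)³ is Uniform(0,1), verified by KS
tests against a rejection-sampling oracle — and needs no rejection loop.
Displacement norms are hard-bounded by the radius on every draw. The
per-step variant counts default to (10, 25, 50): 10 per candidate in the
first step rising to 50 in the final step, when the beam has narrowed and
fine pose-sampling placement matters most. A rigid mode (one shared
displacement per variant) exists but is not the default, since per-sphere
draws add more sampling diversity. Whether a real optimizer perturbs all
spheres or a subset is an open choice; all spheres are perturbed here.

## Candidate DAG

Input files (receptor, ligand) are root nodes; derived files are
intermediate nodes; final dockfiles are leaves. Each multivalued
parameter becomes a fan-out step, and enumerating parameterizations is
the Cartesian product over fan-out pools (pools are treated as
independent; conditional dependence between pools is not modeled).
Structure, node hashes and parameterization ids are pure functions of
config + root contents; a parameterization id is a SHA-256 prefix over
canonically ordered bindings plus the sphere set's provenance string, so
results rows are joinable across steps and reruns. Execution proceeds by
topological generations, deduplicates identical (node, bindings) work
items, skips nodes whose on-disk content hash is unchanged, and isolates
failures to the branches that depend on them. The registered transforms
are deliberately toy file-stampers: receptor-preparation chemistry is out
of scope, the graph contract is not.

## Search

Grid search evaluates every combination once. Beam search: step 0
evaluates the initial grid crossed with the base sphere set plus the
first perturbation round; each later step k evaluates (i) the refined
grid — every numeric range re-centered on the best retained value with
width divided by `zoom_factor` (default 2), clipped to the original
bounds, same pool cardinality — at the best candidate's sphere set, and
(ii) `counts_per_step[k]` perturbed sphere variants of each retained
candidate at that candidate's bindings. Retained candidates carry their
scores forward without re-evaluation; candidates are deduplicated by id,
so the history length equals the evaluation budget exactly. Retention is
ceil(top_fraction · evaluations-this-step) capped by `max_beam_width`
(default 5) — the cap keeps the default pipeline at a few hundred
evaluations despite the sphere fan-out. Ranking ties break by
parameterization id for deterministic reports. Early stopping fires when
the running best improves by less than `min_delta` for `patience`
consecutive steps; a step with no strict improvement always counts as a
stall, so a flat history stops even at min_delta = 0. Failures are
recorded with a "failed" sentinel and excluded from ranking; a step in
which every candidate fails aborts with a diagnostic.

Searches can also be declared as a *step sequence*: an ordered list of
phases, each with its own step count, retention settings and criterion
name (e.g. a cheap criterion first, the full enrichment score later),
optionally nesting child sequences with an iteration count. Nesting is
validated to depth 3. Each phase starts from ranges refined around the
previous phase's best candidate and that candidate's sphere set;
candidates revisited by a later phase keep only their first record, so
parameterization ids stay unique in results.csv.

## Synthetic oracle

The oracle makes class separation depend on the tested parameters:

score(m) = −signal · 1[m positive] · affinity(m) · g(θ) · h(S) + noise_sd · ε

with g(θ) = exp(−‖θ − θ*‖²/2σ²) a Gaussian kernel around a hidden
optimum θ* over the numeric parameters, and h(S) the fraction of matching
spheres within 1.5 Å of a configured hotspot. Energy terms are a fixed
Dirichlet(1,1,1) convex split of the score (drawn once from the oracle
seed), with an optional per-unit-charge offset added to the electrostatic
term to emulate charge bias in the report's violins. The categorical
pose-sampling controls (match_goal, bump limits, chemical matching) scale
noise_sd, modeling their real effect — sampling reliability — without
physical docking. In the default pipeline θ* is drawn from the master
seed uniformly within the parameter bounds and hotspots default to the
base sphere centers.

## Synthetic datasets

The generator emulates the shape of curated retrospective benchmarks:
exactly `n_pos` positives, `round(ratio·n_pos)` negatives (default ratio
50), integer net charges uniform on {−2,…,+2}, and bit fingerprints
(default 256 bits, density 0.3). Positive fingerprints are noisy copies
of `n_clusters` prototype vectors resampled until pairwise Tanimoto
distance exceeds cutoff + 0.1 margin; members flip 4% of bits, keeping
within-cluster distances well under the 0.6 clustering cutoff, so the
planted partition is the unique complete-linkage solution at 0.6 and the
cross-validation machinery has a ground truth. Positives carry a latent
affinity ~ max(0.1, N(3, 1)) — positive and graded so the oracle's
separation is never degenerate; negatives get affinity 0. What the
generator does **not** emulate: real chemical similarity structure among
decoys, property matching, correlated fingerprint bits, or any
relationship between fingerprint and affinity. Tests passing on these
datasets therefore validate the pipeline's logic and statistics, not
docking accuracy on real targets.

## Cross-validation

Positives are clustered by Tanimoto (Jaccard) distance with complete
linkage cut at 0.6 — complete linkage because its merge criterion (max
pairwise distance) is exactly the "every pair within the cutoff" cluster
definition; the max-intra-distance invariant is asserted directly in
tests. One fold per cluster: the held-out cluster is the test positive
set; negatives are partitioned across folds (single shuffle, contiguous
blocks) so each test set preserves the dataset ratio within rounding,
with everything else forming the training set. The alternative of reusing
all negatives in both splits is a documented option not taken, to keep
train/test strictly disjoint. For each fold the beam search runs on the
training set, and the best model of step 0 and the best overall are
scored on the test set; each test enrichment is flagged against the null
conditioned on that fold's test positive count, since the bar depends
strongly on how few positives a fold holds. A single cluster is refused —
there is no chemically distinct test set to hold out.

## Determinism and execution

One master seed lives in the config; every candidate's docking seed is a
SHA-256 hash of (master seed, parameterization id) reduced below 2³¹.
Results are therefore invariant to evaluation order, worker count and
rerun — results.csv is reproduced byte-identically (tested for 1 vs 8
workers). The local executor is a thread pool implementing the minimal
submit/collect contract with bounded retries; Slurm/SGE adapters are
documented stubs.

## Problem sizes in the test suite

The shipped experiments run at desk scale by design: null distributions
use 1e3–1e5 replicates instead of the 1e9-scale tabulations a production
deployment would precompute; search experiments use 4-point pools over
two thin-sphere parameters, datasets of 8–30 positives at ratios 10–50,
and 20 seeded repetitions for the recovery, beam-vs-grid and
cross-validation properties. The parameter-recovery experiment averages
each candidate's criterion over two docking replicates — variance
reduction that a real campaign would get from docking more molecules per
candidate. These sizes are stated here as the package's chosen study
conditions; the contracts they check (recovery within one final grid
cell in ≥ 90% of runs, beam ≥ grid at matched budget in ≥ 80%, no
systematic last-over-first CV gain under a signal-free oracle) are
independent of scale.

## Known limitations

- No physical scoring, pose geometry or pose-reproduction criteria; the
  dock38 backend is an untested adapter stub.
- Bonferroni is the only multiplicity correction (conservative under the
  dependence structure of nearby parameterizations).
- The empirical-threshold error message, not an analytic tail model,
  guards the undersampled-null regime.
- Fan-out pools are independent; conditional parameter spaces are not
  expressible.
- Fingerprints arrive as dataset columns; fingerprinting real structures
  (e.g. Morgan fingerprints from SMILES) is left to upstream tooling.
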