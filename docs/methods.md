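# Methods

## The selection problem

Given a two-class expression matrix with *n* samples and *m* genes, wrapper
feature selection searches for a binary inclusion mask X ∈ {0,1}^m that
maximizes

    f(X) = w₁ · accuracy(X) − w₂ · |X| / m

where accuracy(X) is the cross-validated accuracy of a classifier trained on
the selected gene columns and |X| the number of selected genes.  With
w₁ ≫ w₂ (defaults 0.99 / 0.01) accuracy dominates and the penalty acts as a
tie-break toward smaller subsets: dropping one gene out of 100 is worth
10⁻⁴ fitness, far below the smallest possible CV-accuracy change, so a gene
is only ever dropped when the classifier genuinely does not need it.

## The optimizer

A single swarm of N binary masks is evolved for T_max iterations.  Each
member behaves as both an "ant" (local, pheromone-guided moves) and a
"grasshopper" (global, heavy-tailed jumps); a comprehensive-learning phase
blends the two proposal streams according to their recent success.

**Initialization.** Each bit is 1 independently with probability p.  Any
all-zero mask is repaired by switching on one uniformly chosen bit, a
guarantee that holds after every phase (the fitness is undefined on the
empty set).

**Pheromone update.** A per-gene trail τ_j starts at 0.5, decays by a factor
(1−ρ) per iteration and is reinforced by

    Δτ_j = (1/N) Σ_i X_ij · max(f(X_i), 0) / F_max     (F_max > 0, else 0)

i.e. the population-average, best-normalized fitness of the masks that carry
gene j.  τ is clamped to [0.01, 0.99] so the toggle distribution below never
degenerates and no gene is permanently locked in or out.

**Ant local search.** Each mask flips n_toggles genes (default 1) drawn
without replacement from the categorical distribution

    p_j ∝ τ_j^α (1 − τ_j)^β

(α = β = 1 by default).  The flipped candidate replaces the incumbent only
if its fitness is strictly higher.

**Grasshopper global search.** Each mask takes a Lévy-flight step: the
continuous position X + s·σ·L is re-thresholded to binary (bit 1 iff the
component exceeds T = 0.5) and greedily accepted.  L is drawn per component
with the Mantegna scheme at stability index 1.5 — u/|v|^{1/1.5} with
u ~ N(0, σ_u²), v ~ N(0,1) — which is symmetric about zero and heavy-tailed:
most steps are small local perturbations, occasional components jump far
enough (> T) to switch distant bits and escape local optima.  Steps scale
exactly linearly in the step size s (default 0.1) and scale σ (default 1).
No continuous position persists between iterations; the walk always restarts
from the current binary mask.

**Comprehensive learning.** Per gene, the success scores
S_A_j = Σ_i (f_A(X_i)/F_max)·X_ij and S_G_j = Σ_i (f_G(X_i)/F_max)·X_ij
attribute the post-ant and post-grasshopper fitnesses of the population to
the genes it carries.  The adaptive weights W_A = ΣS_A/(ΣS_A+ΣS_G) and
W_G = 1 − W_A then blend each member's two phase proposals, encoded as
signed move indicators A_ij = (ant candidate bit − current bit) ∈ {−1,0,+1}:

    x_ij' = X_ij + W_A·A_ij + W_G·G_ij,

thresholded at T, repaired, and greedily accepted.  The signed encoding
makes W_A = 1 reproduce the ant proposal exactly; raw 0/1 proposals would
only ever push components upward and saturate the threshold.  When no
success is attributable (F_max ≤ 0, possible only with exotic objectives)
both weights fall back to 1/2.  The phase can be disabled wholesale
(`comprehensive_learning=False`) for ablation; thanks to named per-phase
random streams all other draws are unchanged by the switch.

**Elitism and determinism.** Candidates are accepted only on strict fitness
improvement and the best-so-far is tracked explicitly (ties broken by fewer
genes, then lexicographically), so the best fitness is non-decreasing.  One
master seed spawns independent streams for initialization, ant draws, Lévy
draws, the learning phase, the classifier and the data split, making runs
bit-reproducible and phase ablations stream-stable.

## Fitness evaluation

The dataset is split 60/20/20 (stratified, largest-remainder rounding per
class) into training, validation and test roles.  The wrapper fitness
cross-validates on the *training* portion only — by default a single
stratified 10-fold partition; `cv_folds` and `cv_repeats` are configurable,
the latter averaging accuracy over several independently drawn partitions
to damp the wrapper's tendency to overfit one particular partition.  The
default inner classifier is a linear-kernel SVM (C = 1); naive Bayes,
decision tree, random forest and k-NN adapters are provided, all cloned
once and refit per fold so repeated evaluations are deterministic.  Fitness
values are memoized by the exact bit pattern of the mask, which typically
saves 30–50 % of CV computations in a converging swarm.  Final metrics
(accuracy, precision, recall, F-measure, with 0 conventions for empty
denominators) are computed on the untouched test split after refitting on
training + validation samples.

## Synthetic data

The generator plants signal in an otherwise standard-Gaussian matrix:
informative genes get class means ±δ/2 (so the between-class shift is δ
noise-SD units), redundant genes are ρ_dup·parent + √(1−ρ_dup²)·fresh noise
for a randomly chosen informative parent, and everything else is pure noise.
Because parent and copy share the class mean shift, the *marginal*
parent–copy correlation exceeds ρ_dup; conditional on class it equals ρ_dup
exactly, which is what the tests check.  The model is deliberately
classifier-agnostic and makes recovery quantifiable; it does not emulate
microarray-specific artifacts (probe effects, intensity-dependent variance,
batch structure), so passing tests demonstrate algorithmic behavior, not
robustness to platform noise.

## The benchmark and what it shows

The test-bench problem is 60 samples × 100 genes with 5 informative genes
at δ = 2.0, balanced classes, fitness weights 0.99/0.01, a 5-fold inner CV
and a linear-SVM inner classifier, optimized by a swarm of 20 for 100
iterations with sparse initialization (p = 0.1).  The swarm size and
sparse start keep a full multi-run bench (tens of runs) in the minutes
range; p = 0.1 starts the search near the scale of the expected subset, as
is usual for wrapper selection when m ≫ expected |X| — from a dense start
(p = 0.5), single-bit local moves would need far more than T_max iterations
just to shed the ~45 excess genes.

A structural property of this benchmark is worth stating plainly, because
it bounds what subset recovery can achieve.  After the 60/20/20 split only
36 samples drive the fitness.  Among 95 pure-noise genes, a handful are by
chance strongly class-correlated *within those 36 samples*; small sets of
two or three true genes plus a few such lucky-noise genes reach CV accuracy
exactly 1.0 — under any inner classifier and any fold partition of those
samples, because the association is a property of the sample, not of the
classifier.  Once accuracy saturates, the size penalty strictly prefers the
smallest interpolating set, so the objective's maximizer is a 4–6-gene set
containing only part of the truth, and it is degenerate: many such sets tie
or nearly tie.  Consequences observed on the bench and reported by the
acceptance script: the Jaccard overlap between selected and true informative
sets plateaus around 0.2–0.4 (better optimization does not raise it — the
objective does not ask for the truth), run-to-run selection overlap is
likewise limited by the degeneracy, while held-out test accuracy stays high
(≈0.9–1.0) because two or three true genes already classify well.  At
realistic sample sizes this is the familiar selection-overfitting regime of
wrapper methods; repeated CV (`cv_repeats`) mitigates but does not remove
it.  Recovering the exact planted set would require either more samples or
an objective term that the method, as defined, does not have.

## Evaluation harnesses

*Stability* re-runs the optimizer with different seeds while holding
everything else fixed — including the split and folds, via a shared data
seed — and reports the full pairwise Jaccard matrix of the selected gene
sets plus its mean (one number per run pair rather than one per run, a
superset of any single-partner convention).  *Convergence* reports the
first iteration whose best fitness reaches a threshold, by default 99 % of
the best fitness attained across the compared runs.  *Ablation* runs
seed-paired optimizations with and without the comprehensive-learning phase
and summarizes paired best-fitness and test-metric differences with sign
counts; no unpaired significance machinery is attached.

## Numerical and design notes

- Toggle exponents α, β and the Lévy scale σ have no canonical published
  values; the defaults (1, 1, 1) are neutral choices and all are exposed in
  the run configuration, as are the fitness weights.
- The printed form of the Lévy density this family of methods cites is not
  a samplable expression; the Mantegna generator at index 1.5 is the de
  facto standard realization and is what `levy_step` implements.
- Zero-denominator metric conventions: precision/recall/F default to 0.
- Degenerate inputs are hard errors, never silently repaired: missing
  expression values, duplicate identifiers, non-binary labels, empty masks,
  fold counts exceeding class sizes.
- Split fraction rounding uses largest remainder per class: deterministic
  and within one sample per class per role of the exact proportions.
- All file outputs (gene list, trace CSV, summary JSON) are timestamp-free
  so identical configurations reproduce byte-identical artifacts.

## Known limitations

Binary classes only; no inner-classifier hyperparameter search; no
normalization or batch correction (inputs are taken as-is); wall-clock
performance is bounded by one classifier fit per fold per distinct mask, so
dense starts on very wide matrices are expensive; and subset recovery at
small sample sizes is limited by the objective itself, as described above.
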