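"""The hybrid swarm optimizer over binary gene masks.

A single population of binary masks is driven through four phases per
iteration:

1. *Pheromone update* — a per-gene attractiveness value tau_j decays at rate
   rho and is reinforced by the presence of gene j in currently good masks:
   tau_j <- (1-rho)*tau_j + delta_j, clamped to [tau_min, tau_max].
2. *Ant local search* — each mask flips a small number of genes drawn from
   the normalized toggle distribution
   p_j = tau_j^alpha (1-tau_j)^beta / sum_k tau_k^alpha (1-tau_k)^beta
   and keeps the flip only if fitness strictly improves.
3. *Grasshopper global search* — each mask takes a heavy-tailed Levy-flight
   step in continuous space, is re-thresholded to binary (bit 1 iff
   component > T), and again is accepted only on strict improvement.
4. *Comprehensive learning* (optional) — per-gene success scores attribute
   recent fitness to the ant and grasshopper proposals, adaptive weights
   W_A, W_G (summing to 1) blend the two signed proposals into each mask,
   and the blend is thresholded, repaired and greedily accepted.

Greedy acceptance everywhere plus explicit best-so-far tracking makes the
best fitness non-decreasing across phases and iterations.  All randomness
flows from one master seed through named per-phase streams, so disabling
one phase does not perturb the draws of the others.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import ExpressionDataset, SplitAssignment, make_cv_folds, split_dataset
from .fitness import ClassifierAdapter, FitnessEvaluator, FitnessWeights, make_classifier

_STREAMS = ("init", "ant", "levy", "cl", "classifier", "data")

# Mantegna generator constant for stability index 1.5
_LEVY_INDEX = 1.5
_MANTEGNA_SIGMA_U = (
    math.gamma(1 + _LEVY_INDEX)
    * math.sin(math.pi * _LEVY_INDEX / 2)
    / (
        math.gamma((1 + _LEVY_INDEX) / 2)
        * _LEVY_INDEX
        * 2 ** ((_LEVY_INDEX - 1) / 2)
    )
) ** (1 / _LEVY_INDEX)


def seed_streams(seed: int) -> dict:
    """Named independent RNG streams derived from one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def stream_seed(seed: int, name: str) -> int:
    """A 31-bit integer seed for downstream components (sklearn, splits)."""
    idx = _STREAMS.index(name)
    child = np.random.SeedSequence(seed).spawn(len(_STREAMS))[idx]
    return int(child.generate_state(1)[0] % (2**31))


@dataclass
class CLBSOParams:
    """All knobs of the optimizer.

    Defaults follow the published configuration: population of 50, 100
    iterations, initial inclusion probability 0.5, pheromone decay 0.1, Levy
    step size 0.1 and binarization threshold 0.5.  The toggle exponents
    alpha/beta and the Levy scale have no published values and default to 1.
    """

    population_size: int = 50  # N
    max_iterations: int = 100  # T_max
    init_prob: float = 0.5  # p, probability a bit starts at 1
    pheromone_decay: float = 0.1  # rho
    alpha: float = 1.0  # pheromone exponent in the toggle distribution
    beta: float = 1.0  # inverse-pheromone exponent
    levy_step_size: float = 0.1  # s
    levy_scale: float = 1.0  # sigma
    threshold: float = 0.5  # T, continuous -> binary cutoff
    weights: FitnessWeights = field(default_factory=FitnessWeights)
    n_toggles: int = 1  # genes flipped per ant move
    tau_min: float = 0.01
    tau_max: float = 0.99
    comprehensive_learning: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        for name in ("init_prob", "threshold", "pheromone_decay"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if self.levy_step_size <= 0 or self.levy_scale <= 0:
            raise ValueError("levy_step_size and levy_scale must be positive")
        if self.n_toggles < 1:
            raise ValueError("n_toggles must be at least 1")
        if not 0.0 < self.tau_min < self.tau_max < 1.0:
            raise ValueError("require 0 < tau_min < tau_max < 1")


@dataclass
class IterationRecord:
    iteration: int
    best_fitness: float
    best_accuracy: float
    n_selected: int
    w_ant: float
    w_grasshopper: float


@dataclass
class RunResult:
    """Outcome of one optimizer run."""

    best_mask: np.ndarray
    best_fitness: float
    selected_genes: list
    trace: list  # of IterationRecord
    params: CLBSOParams
    seed: int
    n_evaluations: int = 0
    split: SplitAssignment | None = None

    @property
    def best_fitness_trace(self) -> np.ndarray:
        return np.array([rec.best_fitness for rec in self.trace])


def repair_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Guarantee a non-empty mask by switching on one uniform random bit."""
    if mask.sum() == 0:
        mask = mask.copy()
        mask[rng.integers(len(mask))] = 1
    return mask


def initialize_population(
    n_genes: int, params: CLBSOParams, rng: np.random.Generator
) -> np.ndarray:
    """N random masks, each bit 1 with probability p; empty masks repaired."""
    pop = (rng.random((params.population_size, n_genes)) < params.init_prob).astype(
        np.uint8
    )
    for i in range(params.population_size):
        pop[i] = repair_mask(pop[i], rng)
    return pop


def update_pheromone(
    tau: np.ndarray,
    population: np.ndarray,
    fitnesses: np.ndarray,
    f_max: float,
    rho: float,
    tau_min: float = 0.01,
    tau_max: float = 0.99,
) -> np.ndarray:
    """tau_j <- clamp((1-rho)*tau_j + delta_j).

    The reinforcement delta_j averages, over the population, the (clipped,
    F_max-normalized) fitness of every mask containing gene j:
    delta_j = (1/N) sum_i X_ij * max(f_i, 0) / F_max for F_max > 0, else 0.
    """
    if f_max > 0:
        contrib = np.maximum(fitnesses, 0.0) / f_max
        delta = contrib @ population / len(population)
    else:
        delta = np.zeros_like(tau)
    return np.clip((1.0 - rho) * tau + delta, tau_min, tau_max)


def toggle_probabilities(tau: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Categorical distribution over genes: p_j ∝ tau_j^alpha (1-tau_j)^beta."""
    weights = tau**alpha * (1.0 - tau) ** beta
    total = weights.sum()
    assert total > 0, "toggle weights vanished despite pheromone clamping"
    return weights / total


def ant_local_search(
    mask: np.ndarray,
    incumbent_fitness: float,
    probs: np.ndarray,
    n_toggles: int,
    fitness_fn,
    rng: np.random.Generator,
):
    """One ant move: flip n_toggles pheromone-chosen genes, keep if better.

    Returns ``(mask', f_A, candidate)`` where candidate is the (repaired)
    proposed mask regardless of acceptance — the comprehensive-learning
    phase consumes it as the ant proposal.
    """
    n_toggles = min(n_toggles, len(mask))
    flip = rng.choice(len(mask), size=n_toggles, replace=False, p=probs)
    candidate = mask.copy()
    candidate[flip] ^= 1
    candidate = repair_mask(candidate, rng)
    f_cand = fitness_fn(candidate)
    if f_cand > incumbent_fitness:
        return candidate, f_cand, candidate
    return mask, incumbent_fitness, candidate


def levy_step(
    n_genes: int, s: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Signed heavy-tailed step per gene (Mantegna scheme, index 1.5).

    step_j = s * sigma * u_j / |v_j|^(1/1.5) with u ~ N(0, sigma_u^2) and
    v ~ N(0, 1); u's sign makes each component symmetric about zero, and the
    |v| denominator produces the occasional very long jump that lets the
    swarm escape local optima.  Scaling is exactly linear in s and sigma.
    """
    u = rng.normal(0.0, _MANTEGNA_SIGMA_U, size=n_genes)
    v = rng.standard_normal(n_genes)
    return s * sigma * u / np.abs(v) ** (1.0 / _LEVY_INDEX)


def grasshopper_move(
    mask: np.ndarray,
    incumbent_fitness: float,
    step: np.ndarray,
    threshold: float,
    fitness_fn,
    rng: np.random.Generator,
):
    """One grasshopper move: add the Levy step, re-threshold, keep if better.

    The continuous candidate is mask + step; bit j of the binary candidate
    is 1 iff that component exceeds the threshold.  Returns
    ``(mask', f_G, candidate)`` with candidate the (repaired) proposal.
    """
    continuous = mask.astype(float) + step
    candidate = (continuous > threshold).astype(np.uint8)
    candidate = repair_mask(candidate, rng)
    f_cand = fitness_fn(candidate)
    if f_cand > incumbent_fitness:
        return candidate, f_cand, candidate
    return mask, incumbent_fitness, candidate


def success_scores(
    population: np.ndarray,
    f_ant: np.ndarray,
    f_grasshopper: np.ndarray,
    f_max: float,
):
    """Per-gene success of the ant and grasshopper phases.

    S_A_j = sum_i (f_A(X_i)/F_max) * X_ij and likewise S_G_j, over the
    current population masks.  A non-positive F_max makes the ratios
    meaningless, so both scores are zero there.
    """
    n_genes = population.shape[1]
    if f_max <= 0:
        zero = np.zeros(n_genes)
        return zero, zero.copy()
    s_ant = (f_ant / f_max) @ population
    s_grass = (f_grasshopper / f_max) @ population
    return s_ant, s_grass


def adaptive_weights(s_ant: np.ndarray, s_grasshopper: np.ndarray):
    """W_A = sum(S_A)/(sum(S_A)+sum(S_G)), W_G its complement.

    When both score sums vanish (no attributable success yet) the phases are
    weighted equally.
    """
    total_a = float(np.sum(s_ant))
    total_g = float(np.sum(s_grasshopper))
    denom = total_a + total_g
    if denom <= 0:
        return 0.5, 0.5
    return total_a / denom, total_g / denom


def comprehensive_update(
    population: np.ndarray,
    fitnesses: np.ndarray,
    ant_proposals: np.ndarray,
    grasshopper_proposals: np.ndarray,
    w_ant: float,
    w_grasshopper: float,
    threshold: float,
    fitness_fn,
    rng: np.random.Generator,
):
    """Blend each mask with its phase proposals and greedily accept.

    Proposals enter as signed move indicators relative to the current mask
    (A_ij = ant-candidate bit - X_ij ∈ {-1, 0, +1}), so
    x' = X + W_A*A + W_G*G reduces exactly to the ant candidate at W_A = 1.
    The blend is thresholded back to binary, repaired if empty, and replaces
    the incumbent only on strict fitness improvement.
    """
    new_pop = population.copy()
    new_fit = fitnesses.copy()
    for i in range(len(population)):
        a = ant_proposals[i].astype(float) - population[i]
        g = grasshopper_proposals[i].astype(float) - population[i]
        continuous = population[i] + w_ant * a + w_grasshopper * g
        candidate = (continuous > threshold).astype(np.uint8)
        candidate = repair_mask(candidate, rng)
        f_cand = fitness_fn(candidate)
        if f_cand > new_fit[i]:
            new_pop[i] = candidate
            new_fit[i] = f_cand
    return new_pop, new_fit


def _is_better(f_a: float, mask_a: np.ndarray, f_b: float, mask_b: np.ndarray) -> bool:
    """Best-so-far ordering: fitness, then fewer genes, then lexicographic."""
    if f_a != f_b:
        return f_a > f_b
    ca, cb = int(mask_a.sum()), int(mask_b.sum())
    if ca != cb:
        return ca < cb
    return mask_a.tobytes() < mask_b.tobytes()


def optimize(
    fitness_fn,
    n_genes: int,
    params: CLBSOParams,
    accuracy_fn=None,
    streams: dict | None = None,
):
    """Run the four-phase loop on an arbitrary mask-fitness function.

    Returns ``(best_mask, best_fitness, trace)``.  ``accuracy_fn`` is an
    optional companion of ``fitness_fn`` used only for trace reporting (NaN
    when absent, e.g. with surrogate objectives).  Core invariants —
    probability normalization, pheromone bounds, binary non-empty masks and
    non-decreasing best fitness — are asserted every iteration.
    """
    params.validate()
    if streams is None:
        streams = seed_streams(params.seed)
    rng_init, rng_ant, rng_levy, rng_cl = (
        streams["init"],
        streams["ant"],
        streams["levy"],
        streams["cl"],
    )

    population = initialize_population(n_genes, params, rng_init)
    fitnesses = np.array([fitness_fn(m) for m in population])
    tau = np.full(n_genes, 0.5)

    best_idx = int(np.argmax(fitnesses))
    best_mask = population[best_idx].copy()
    best_fitness = float(fitnesses[best_idx])
    for i in range(len(population)):
        if _is_better(fitnesses[i], population[i], best_fitness, best_mask):
            best_mask, best_fitness = population[i].copy(), float(fitnesses[i])

    trace: list[IterationRecord] = []
    for t in range(1, params.max_iterations + 1):
        prev_best = best_fitness

        # --- pheromone update from the current population
        f_max = float(fitnesses.max())
        tau = update_pheromone(
            tau, population, fitnesses, f_max, params.pheromone_decay,
            params.tau_min, params.tau_max,
        )
        assert tau.min() >= params.tau_min and tau.max() <= params.tau_max
        probs = toggle_probabilities(tau, params.alpha, params.beta)
        assert abs(probs.sum() - 1.0) <= 1e-12

        # --- ant local search
        ant_proposals = np.empty_like(population)
        f_ant = np.empty(len(population))
        for i in range(len(population)):
            population[i], fitnesses[i], ant_proposals[i] = ant_local_search(
                population[i], fitnesses[i], probs, params.n_toggles,
                fitness_fn, rng_ant,
            )
            f_ant[i] = fitnesses[i]

        # --- grasshopper global search
        grasshopper_proposals = np.empty_like(population)
        f_grass = np.empty(len(population))
        for i in range(len(population)):
            step = levy_step(n_genes, params.levy_step_size, params.levy_scale, rng_levy)
            population[i], fitnesses[i], grasshopper_proposals[i] = grasshopper_move(
                population[i], fitnesses[i], step, params.threshold,
                fitness_fn, rng_levy,
            )
            f_grass[i] = fitnesses[i]

        # --- comprehensive learning
        w_ant = w_grass = float("nan")
        if params.comprehensive_learning:
            f_max = float(fitnesses.max())
            s_ant, s_grass = success_scores(population, f_ant, f_grass, f_max)
            w_ant, w_grass = adaptive_weights(s_ant, s_grass)
            assert abs(w_ant + w_grass - 1.0) <= 1e-12
            population, fitnesses = comprehensive_update(
                population, fitnesses, ant_proposals, grasshopper_proposals,
                w_ant, w_grass, params.threshold, fitness_fn, rng_cl,
            )

        # --- bookkeeping and invariants
        assert np.isin(population, (0, 1)).all()
        assert (population.sum(axis=1) > 0).all()
        for i in range(len(population)):
            if _is_better(fitnesses[i], population[i], best_fitness, best_mask):
                best_mask, best_fitness = population[i].copy(), float(fitnesses[i])
        assert best_fitness >= prev_best

        acc = float("nan")
        if accuracy_fn is not None:
            acc = float(accuracy_fn(best_mask))
        trace.append(
            IterationRecord(
                iteration=t,
                best_fitness=best_fitness,
                best_accuracy=acc,
                n_selected=int(best_mask.sum()),
                w_ant=w_ant,
                w_grasshopper=w_grass,
            )
        )
    return best_mask, best_fitness, trace


def run_clbso(
    ds: ExpressionDataset,
    classifier="svm",
    params: CLBSOParams | None = None,
    cv_folds: int = 10,
    cv_repeats: int = 1,
    split_fractions=(0.6, 0.2, 0.2),
    data_seed: int | None = None,
) -> RunResult:
    """Select genes on a labeled expression dataset.

    The dataset is split (stratified) into train/validation/test; the
    wrapper fitness cross-validates on the *training* portion only, so the
    optimizer never sees validation or test labels.  ``cv_repeats`` > 1
    averages the inner CV accuracy over that many independent fold
    partitions, which damps the wrapper's tendency to overfit a single
    partition.  ``data_seed`` fixes the split/fold randomness independently
    of the optimizer seed (by default it is derived from ``params.seed``);
    stability comparisons hold it constant so that only the search varies.
    ``classifier`` is a short name (svm/rf/dt/nb/knn) or a ready
    ClassifierAdapter.  Fully reproducible given ``params.seed``.
    """
    if params is None:
        params = CLBSOParams()
    params.validate()
    if cv_repeats < 1:
        raise ValueError("cv_repeats must be at least 1")
    if len(ds.classes) != 2:
        raise ValueError("run_clbso requires a binary-labeled dataset")

    streams = seed_streams(params.seed)
    if data_seed is None:
        data_seed = stream_seed(params.seed, "data")
    split = split_dataset(
        ds, fractions=split_fractions, stratified=True, seed=data_seed
    )
    train_ds = ds.subset(split.indices("train"))
    fold_seed = data_seed // 2 + 1
    folds = [
        make_cv_folds(train_ds, k=cv_folds, stratified=True, seed=fold_seed + r)
        for r in range(cv_repeats)
    ]
    if isinstance(classifier, str):
        classifier = make_classifier(classifier, seed=stream_seed(params.seed, "classifier"))
    evaluator = FitnessEvaluator(train_ds, classifier, folds, params.weights)

    best_mask, best_fitness, trace = optimize(
        evaluator, ds.n_genes, params, accuracy_fn=evaluator.accuracy, streams=streams
    )
    return RunResult(
        best_mask=best_mask,
        best_fitness=best_fitness,
        selected_genes=[str(g) for g in ds.gene_ids[best_mask.astype(bool)]],
        trace=trace,
        params=params,
        seed=params.seed,
        n_evaluations=evaluator.n_evaluations,
        split=split,
    )
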