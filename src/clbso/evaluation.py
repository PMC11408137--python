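"""Post-hoc analyses: selection stability, convergence speed, ablation,
and final held-out test metrics.

Stability is measured by the Jaccard index J(A,B) = |A∩B| / |A∪B| between
the gene sets chosen by independently seeded runs; a mean pairwise value
near 1 means the optimizer keeps finding the same subset.  Convergence is
the first iteration at which the best fitness reaches a threshold.  The
ablation harness re-runs the optimizer with the comprehensive-learning
phase disabled (same per-phase random streams otherwise) and reports paired
differences.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, SplitAssignment
from .fitness import MetricsReport, evaluate_confusion, make_classifier
from .optimizer import CLBSOParams, RunResult, run_clbso, stream_seed


def jaccard_index(set_a, set_b) -> float:
    """|A∩B| / |A∪B| for two finite sets of gene identifiers."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValueError("Jaccard index of two empty sets is undefined (0/0)")
    return len(a & b) / len(union)


@dataclass
class StabilityReport:
    """Pairwise Jaccard overlap of gene sets selected across seeded runs."""

    seeds: list
    gene_sets: list  # one set of gene ids per run
    matrix: np.ndarray  # symmetric, unit diagonal
    mean_pairwise: float

    def to_frame(self) -> pd.DataFrame:
        names = [f"run_{s}" for s in self.seeds]
        return pd.DataFrame(self.matrix, index=names, columns=names)


@dataclass
class ConvergenceReport:
    """First iteration at which each run reached the fitness threshold."""

    threshold: float
    iterations: list  # per run; None when never reached
    mean_iterations: float  # over runs that reached it (NaN if none)


@dataclass
class AblationReport:
    """Seed-paired comparison with and without comprehensive learning."""

    rows: pd.DataFrame
    mean_fitness_diff: float
    mean_accuracy_diff: float
    n_positive: int  # seeds where the full algorithm had higher fitness
    n_negative: int
    n_zero: int


def pairwise_jaccard(gene_sets) -> np.ndarray:
    n = len(gene_sets)
    matrix = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            matrix[i, j] = matrix[j, i] = jaccard_index(gene_sets[i], gene_sets[j])
    return matrix


def stability_from_sets(gene_sets, seeds=None) -> StabilityReport:
    """Stability report from already-computed per-run gene sets."""
    if len(gene_sets) < 2:
        raise ValueError("stability needs at least two runs")
    matrix = pairwise_jaccard(gene_sets)
    off = matrix[np.triu_indices(len(gene_sets), k=1)]
    return StabilityReport(
        seeds=list(seeds) if seeds is not None else list(range(len(gene_sets))),
        gene_sets=[set(s) for s in gene_sets],
        matrix=matrix,
        mean_pairwise=float(off.mean()),
    )


def stability_analysis(
    ds: ExpressionDataset,
    classifier,
    params: CLBSOParams,
    seeds,
    **run_kwargs,
) -> StabilityReport:
    """Run the optimizer once per seed and score run-to-run overlap.

    All parameters except the optimizer seed are held fixed — including the
    train/validation/test split and the CV folds (a shared data seed derived
    from the base ``params.seed``), so the runs differ only in the search
    randomness.  Any run failure aborts with the offending seed named.
    """
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("stability_analysis needs at least two seeds")
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    run_kwargs.setdefault("data_seed", stream_seed(params.seed, "data"))
    gene_sets = []
    for s in seeds:
        try:
            result = run_clbso(
                ds, classifier, dataclasses.replace(params, seed=s), **run_kwargs
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with seed context
            raise RuntimeError(f"stability run with seed {s} failed: {exc}") from exc
        gene_sets.append(set(result.selected_genes))
    return stability_from_sets(gene_sets, seeds)


def convergence_iterations(trace, fitness_threshold: float):
    """Smallest 1-based iteration whose best fitness reaches the threshold.

    ``trace`` is a per-iteration best-fitness sequence (or a RunResult).
    Returns None when the threshold is never reached.
    """
    if isinstance(trace, RunResult):
        trace = trace.best_fitness_trace
    values = np.asarray(
        [rec.best_fitness if hasattr(rec, "best_fitness") else rec for rec in trace],
        dtype=float,
    )
    if len(values) == 0:
        raise ValueError("empty fitness trace")
    hits = np.flatnonzero(values >= fitness_threshold)
    return int(hits[0]) + 1 if len(hits) else None


def convergence_report(results, fitness_threshold: float | None = None) -> ConvergenceReport:
    """Convergence summary over several runs.

    When no threshold is given, 99% of the best fitness attained across the
    compared runs is used.
    """
    traces = [
        r.best_fitness_trace if isinstance(r, RunResult) else np.asarray(r, dtype=float)
        for r in results
    ]
    if fitness_threshold is None:
        fitness_threshold = 0.99 * max(t.max() for t in traces)
    iters = [convergence_iterations(t, fitness_threshold) for t in traces]
    reached = [i for i in iters if i is not None]
    return ConvergenceReport(
        threshold=float(fitness_threshold),
        iterations=iters,
        mean_iterations=float(np.mean(reached)) if reached else float("nan"),
    )


def final_evaluation(
    ds: ExpressionDataset,
    split: SplitAssignment,
    mask_or_genes,
    classifier,
    positive_class=None,
    include_validation: bool = True,
    classifier_seed: int = 0,
) -> MetricsReport:
    """Train on train(+validation) restricted to the selected genes and
    report confusion-matrix metrics on the held-out test samples.

    ``mask_or_genes`` is either a binary mask over all genes or an iterable
    of gene identifiers.  The positive class defaults to the
    lexicographically larger label (1 in a 0/1 coding).
    """
    genes = np.asarray(mask_or_genes)
    if genes.dtype.kind in "biu" and genes.shape == (ds.n_genes,):
        sel = genes.astype(bool)
    else:
        wanted = {str(g) for g in mask_or_genes}
        known = {str(g) for g in ds.gene_ids}
        unknown = wanted - known
        if unknown:
            raise ValueError(f"unknown genes in selection: {sorted(unknown)[:5]}")
        sel = np.array([str(g) in wanted for g in ds.gene_ids])
    if sel.sum() == 0:
        raise ValueError("no genes selected")

    train_idx = split.indices("train")
    if include_validation:
        train_idx = np.concatenate([train_idx, split.indices("validation")])
    test_idx = split.indices("test")
    if len(test_idx) == 0:
        raise ValueError("split has no test samples")

    if isinstance(classifier, str):
        classifier = make_classifier(classifier, seed=classifier_seed)
    X = ds.matrix[:, sel]
    classifier.fit(X[train_idx], ds.labels[train_idx])
    pred = classifier.predict(X[test_idx])
    if positive_class is None:
        positive_class = sorted(ds.classes.tolist())[-1]
    return evaluate_confusion(ds.labels[test_idx], pred, positive_class)


def ablation_compare(
    ds: ExpressionDataset,
    classifier,
    params: CLBSOParams,
    seeds,
    **run_kwargs,
) -> AblationReport:
    """Seed-paired runs with and without the comprehensive-learning phase.

    Per seed, both variants share the master seed, and the named per-phase
    random streams guarantee the initialization, ant and Levy draws start
    identical; the paired difference therefore isolates the contribution of
    the learning phase.  Requires at least 5 seeds.
    """
    seeds = list(seeds)
    if len(seeds) < 5:
        raise ValueError("ablation_compare needs at least 5 seeds")
    rows = []
    for s in seeds:
        pair = {}
        for enabled in (True, False):
            p = dataclasses.replace(params, seed=s, comprehensive_learning=enabled)
            try:
                result = run_clbso(ds, classifier, p, **run_kwargs)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"ablation run with seed {s} failed: {exc}") from exc
            metrics = final_evaluation(
                ds, result.split, result.best_mask, classifier,
                classifier_seed=stream_seed(s, "classifier"),
            )
            pair[enabled] = (result, metrics)
        with_r, with_m = pair[True]
        wo_r, wo_m = pair[False]
        rows.append(
            {
                "seed": s,
                "fitness_with_cl": with_r.best_fitness,
                "fitness_without_cl": wo_r.best_fitness,
                "fitness_diff": with_r.best_fitness - wo_r.best_fitness,
                "test_accuracy_with_cl": with_m.accuracy,
                "test_accuracy_without_cl": wo_m.accuracy,
                "test_accuracy_diff": with_m.accuracy - wo_m.accuracy,
                "n_selected_with_cl": int(with_r.best_mask.sum()),
                "n_selected_without_cl": int(wo_r.best_mask.sum()),
            }
        )
    frame = pd.DataFrame(rows)
    diffs = frame["fitness_diff"].to_numpy()
    return AblationReport(
        rows=frame,
        mean_fitness_diff=float(diffs.mean()),
        mean_accuracy_diff=float(frame["test_accuracy_diff"].mean()),
        n_positive=int((diffs > 0).sum()),
        n_negative=int((diffs < 0).sum()),
        n_zero=int((diffs == 0).sum()),
    )
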