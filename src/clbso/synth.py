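"""Synthetic two-class expression matrices with planted informative genes.

The generative model is a Gaussian mean-shift: informative genes differ
between classes by ``effect_size`` noise standard deviations (class means at
±effect_size/2, unit variance), optional redundant genes are noisy copies of
informative ones, and every other gene is pure standard Gaussian noise.
Ground truth (which columns carry signal) is returned alongside the data so
selection quality can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .datasets import ExpressionDataset


@dataclass
class SyntheticSpec:
    """Parameters of the planted-signal generator.

    Defaults describe the benchmark used throughout the test-bench: 60
    samples, 100 genes, 5 informative genes at a class mean shift of 2
    noise-SD units, balanced classes, no redundant copies.
    """

    n_samples: int = 60
    n_genes: int = 100
    n_informative: int = 5
    effect_size: float = 2.0
    n_redundant: int = 0
    rho_dup: float = 0.8
    class_balance: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValueError("need at least 2 samples and 1 gene")
        if self.n_informative < 0 or self.n_redundant < 0:
            raise ValueError("gene counts must be non-negative")
        if self.n_informative + self.n_redundant > self.n_genes:
            raise ValueError("n_informative + n_redundant exceeds n_genes")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant genes require at least one informative parent")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0.0 <= self.rho_dup <= 1.0:
            raise ValueError("rho_dup must lie in [0, 1]")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Which gene columns carry signal, and how they were generated."""

    informative: np.ndarray  # column indices with the class mean shift
    redundant: np.ndarray  # column indices of correlated copies
    parents: dict  # redundant index -> informative parent index
    spec: SyntheticSpec

    def informative_gene_ids(self, ds: ExpressionDataset) -> set:
        return {str(g) for g in ds.gene_ids[self.informative]}

    def to_json(self) -> str:
        payload = {
            "informative": [int(i) for i in self.informative],
            "redundant": [int(i) for i in self.redundant],
            "parents": {str(k): int(v) for k, v in self.parents.items()},
            "spec": dataclasses.asdict(self.spec),
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def generate_synthetic_expression(spec: SyntheticSpec):
    """Draw one dataset from the planted-signal model.

    Returns ``(ExpressionDataset, GroundTruth)``.  Informative genes get a
    per-class mean of ±effect_size/2 on unit-variance Gaussian noise; each
    redundant gene is rho_dup * parent + sqrt(1 - rho_dup^2) * fresh noise;
    remaining genes are standard Gaussian.  Bit-identical output for a fixed
    seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_genes

    n_pos = int(round(n * spec.class_balance))
    n_pos = min(max(n_pos, 1), n - 1)  # keep both classes populated
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    labels = labels[rng.permutation(n)]

    matrix = rng.standard_normal((n, m))
    chosen = rng.choice(m, size=spec.n_informative + spec.n_redundant, replace=False)
    informative = np.sort(chosen[: spec.n_informative])
    redundant = np.sort(chosen[spec.n_informative :])

    shift = np.where(labels == 1, spec.effect_size / 2.0, -spec.effect_size / 2.0)
    matrix[:, informative] += shift[:, None]

    parents: dict = {}
    for j in redundant:
        parent = int(rng.choice(informative))
        parents[int(j)] = parent
        fresh = rng.standard_normal(n)
        matrix[:, j] = spec.rho_dup * matrix[:, parent] + np.sqrt(
            1.0 - spec.rho_dup**2
        ) * fresh

    width = max(4, len(str(m)))
    ds = ExpressionDataset(
        matrix=matrix,
        gene_ids=np.array([f"G{j:0{width}d}" for j in range(m)]),
        sample_ids=np.array([f"S{i:04d}" for i in range(n)]),
        labels=labels,
    )
    truth = GroundTruth(
        informative=informative, redundant=redundant, parents=parents, spec=spec
    )
    return ds, truth
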