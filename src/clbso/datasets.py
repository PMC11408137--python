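"""Expression-matrix I/O, train/validation/test splits and CV folds.

The in-memory convention is always *samples x genes*: rows are samples,
columns are genes.  Tables with genes in rows (one column per sample) are
transposed on load.  Labels are binary (e.g. cancer/normal); anything else
is rejected at load time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

ROLES = ("train", "validation", "test")


@dataclass
class ExpressionDataset:
    """A samples x genes expression matrix with per-sample binary labels.

    Parameters
    ----------
    matrix:
        Real-valued array of shape ``(n_samples, n_genes)``; must be free of
        missing values (loading refuses to impute).
    gene_ids, sample_ids:
        Unique identifiers for columns and rows respectively.
    labels:
        One class label per sample; at most two distinct classes.
    """

    matrix: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids)
        self.sample_ids = np.asarray(self.sample_ids)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n_samples, n_genes = self.matrix.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match matrix columns")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match matrix rows")
        if len(self.labels) != n_samples:
            raise ValueError("labels length does not match number of samples")
        if not np.isfinite(self.matrix).all():
            i, j = np.argwhere(~np.isfinite(self.matrix))[0]
            raise ValueError(
                f"missing/non-finite value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}; imputation is refused"
            )
        if len(np.unique(self.gene_ids)) != n_genes:
            dup = pd.Series(self.gene_ids)
            dup = dup[dup.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dup)[:5]}")
        if len(np.unique(self.sample_ids)) != n_samples:
            raise ValueError("duplicate sample identifiers")
        classes = np.unique(self.labels)
        if len(classes) > 2:
            raise ValueError(
                f"labels must be binary; observed {len(classes)} classes: "
                f"{[str(c) for c in classes]}"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def class_counts(self) -> dict:
        classes, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(classes.tolist(), counts.tolist()))

    def subset(self, sample_indices) -> "ExpressionDataset":
        """Row-subset of the dataset (labels and sample ids follow)."""
        idx = np.asarray(sample_indices)
        return ExpressionDataset(
            matrix=self.matrix[idx],
            gene_ids=self.gene_ids,
            sample_ids=self.sample_ids[idx],
            labels=self.labels[idx],
        )


@dataclass
class SplitAssignment:
    """Role (train/validation/test) per sample, as produced by split_dataset."""

    roles: np.ndarray  # one of ROLES per sample
    fractions: tuple
    seed: int
    stratified: bool = True

    def indices(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
        return np.flatnonzero(self.roles == role)

    def counts(self) -> dict:
        return {r: int((self.roles == r).sum()) for r in ROLES}


@dataclass
class FoldAssignment:
    """Cross-validation fold index per sample."""

    fold_ids: np.ndarray
    k: int
    seed: int
    stratified: bool = True

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_ids == fold)

    def __iter__(self):
        """Yield (train_indices, test_indices) per fold."""
        for f in range(self.k):
            test = self.indices(f)
            train = np.flatnonzero(self.fold_ids != f)
            yield train, test


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    if str(path).endswith((".tsv", ".tab")):
        return "\t"
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def read_expression_table(
    path,
    orientation: str = "samples",
    label_column: str | None = "class",
    label_file=None,
    sep: str | None = None,
) -> ExpressionDataset:
    """Read a delimited expression table into an ExpressionDataset.

    ``orientation="samples"`` (the CuMiDa-style default) expects samples in
    rows, gene columns, a first column of sample ids and a ``label_column``
    holding the class.  ``orientation="genes"`` expects genes in rows with a
    first column of gene ids; labels then come from ``label_file``, a
    two-column CSV (sample_id, label).  The returned dataset is always
    samples x genes.
    """
    path = Path(path)
    if orientation not in ("samples", "genes"):
        raise ValueError("orientation must be 'samples' or 'genes'")
    sep = _sniff_sep(path, sep)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup = pd.Series(header)
    dup = dup[dup.duplicated()].unique()
    if len(dup):  # pandas would silently mangle these to g, g.1, ...
        kind = "gene" if orientation == "samples" else "sample"
        raise ValueError(f"duplicate {kind} identifiers in header: {list(dup)[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0)

    labels = None
    if orientation == "samples":
        if label_column is not None and label_column in df.columns:
            labels = df[label_column].to_numpy()
            df = df.drop(columns=[label_column])
        elif label_file is None:
            raise ValueError(
                f"label column {label_column!r} not found and no label file given"
            )
    else:
        df = df.T  # now samples x genes

    if labels is None:
        if label_file is None:
            raise ValueError("genes-in-rows input requires a label file")
        lab = pd.read_csv(label_file, index_col=0).iloc[:, 0]
        missing = [s for s in df.index if s not in lab.index]
        if missing:
            raise ValueError(f"label file lacks samples: {missing[:5]}")
        labels = lab.loc[df.index].to_numpy()

    # locate missing cells before the numeric cast so the error can name them
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        col = df.columns[df.isna().any(axis=0)][0]
        raise ValueError(
            f"missing value at sample {row!r}, gene {col!r}; imputation is refused"
        )
    try:
        matrix = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression values in {path}: {exc}") from None

    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(
            f"expected 2 classes, observed {len(classes)}: "
            f"{[str(c) for c in classes]}"
        )
    return ExpressionDataset(
        matrix=matrix,
        gene_ids=df.columns.to_numpy(),
        sample_ids=df.index.to_numpy(),
        labels=labels,
    )


def write_expression_table(ds: ExpressionDataset, path, label_column: str = "class") -> None:
    """Write a dataset as a samples-in-rows CSV with a class column."""
    df = pd.DataFrame(ds.matrix, index=ds.sample_ids, columns=ds.gene_ids)
    df.insert(len(df.columns), label_column, ds.labels)
    df.index.name = "sample_id"
    df.to_csv(path)


def _largest_remainder(n: int, fractions) -> np.ndarray:
    """Integer role counts for n items: floors, then +1 by largest remainder."""
    target = np.asarray(fractions, dtype=float) * n
    base = np.floor(target).astype(int)
    rem = target - base
    # stable tie-break: earlier role wins on equal remainders
    order = np.argsort(-rem, kind="stable")
    for i in order[: n - base.sum()]:
        base[i] += 1
    return base


def split_dataset(
    ds: ExpressionDataset,
    fractions=(0.6, 0.2, 0.2),
    stratified: bool = True,
    seed: int = 0,
) -> SplitAssignment:
    """Assign each sample to train/validation/test.

    Fractional counts are resolved per class by the largest-remainder rule,
    so a stratified split preserves per-class proportions within one sample
    per class per role.  Deterministic given ``seed``.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != len(ROLES):
        raise ValueError(f"need {len(ROLES)} fractions, got {len(fractions)}")
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    n_roles = sum(f > 0 for f in fractions)

    rng = np.random.default_rng(seed)
    roles = np.empty(ds.n_samples, dtype=object)
    groups = (
        [np.flatnonzero(ds.labels == c) for c in ds.classes]
        if stratified
        else [np.arange(ds.n_samples)]
    )
    for grp in groups:
        if stratified and len(grp) < n_roles:
            raise ValueError(
                f"a class has {len(grp)} samples but {n_roles} roles are requested"
            )
        counts = _largest_remainder(len(grp), fractions)
        order = rng.permutation(grp)
        pos = 0
        for role, c in zip(ROLES, counts):
            roles[order[pos : pos + c]] = role
            pos += c
    return SplitAssignment(
        roles=roles.astype(str), fractions=fractions, seed=seed, stratified=stratified
    )


def make_cv_folds(
    ds_or_labels, k: int = 10, stratified: bool = True, seed: int = 0
) -> FoldAssignment:
    """Partition samples into k folds (stratified by default).

    Fold sizes differ by at most one; stratified folds keep the class ratio
    within one sample per fold.  Deterministic given ``seed``.
    """
    labels = (
        ds_or_labels.labels
        if isinstance(ds_or_labels, ExpressionDataset)
        else np.asarray(ds_or_labels)
    )
    n = len(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    if stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < k:
            raise ValueError(
                f"stratified folds need every class to have >= {k} samples"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_ids = np.empty(n, dtype=int)
    for f, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), labels)):
        fold_ids[test_idx] = f
    return FoldAssignment(fold_ids=fold_ids, k=k, seed=seed, stratified=stratified)


def write_run_report(result, path_prefix) -> dict:
    """Write a finished run as three text artifacts.

    ``<prefix>.genes.txt``  — selected gene ids, one per line;
    ``<prefix>.trace.csv``  — per-iteration trace (iteration, best_fitness,
    best_accuracy, n_selected, w_ant, w_grasshopper);
    ``<prefix>.summary.json`` — parameters, seed and final figures.

    Returns the paths written.  No timestamps are embedded, so re-running an
    identical configuration reproduces the files byte for byte.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    genes_path = prefix.with_name(prefix.name + ".genes.txt")
    genes_path.write_text("".join(f"{g}\n" for g in result.selected_genes))

    trace_path = prefix.with_name(prefix.name + ".trace.csv")
    trace = pd.DataFrame([dataclasses.asdict(rec) for rec in result.trace])
    trace.to_csv(trace_path, index=False)

    params = dataclasses.asdict(result.params)
    summary = {
        "parameters": params,
        "seed": int(result.seed),
        "best_fitness": float(result.best_fitness),
        "n_selected": int(result.best_mask.sum()),
        "selected_genes": [str(g) for g in result.selected_genes],
        "n_fitness_evaluations": int(result.n_evaluations),
    }
    summary_path = prefix.with_name(prefix.name + ".summary.json")
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {"genes": genes_path, "trace": trace_path, "summary": summary_path}
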