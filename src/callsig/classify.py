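"""Distance-based visualisation and KNN subtype classification.

Samples are compared by Euclidean distance between logCPM profiles over
a chosen gene set.  Classification follows a repeated-subsampling
protocol: in each replicate half of the eligible genes are drawn, the
draw is ranked by expression variance, and leave-one-out k-nearest-
neighbour prediction is evaluated on an increasing number of top-
variance genes.  A class-balanced variant undersamples every subtype to
the same size before classification.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

DEFAULT_GENE_COUNTS = (2, 5, 10, 20, 50, 100, 200, 500)


# ---------------------------------------------------------------------------
# distances and MDS
# ---------------------------------------------------------------------------

def distance_matrix(expr: pd.DataFrame, genes) -> pd.DataFrame:
    """Euclidean distances between samples over the listed genes' logCPM."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    missing = set(genes) - set(expr.index)
    if missing:
        raise ValueError(f"genes absent from expression matrix: "
                         f"{sorted(missing)[:5]}")
    pts = expr.loc[genes].to_numpy().T  # samples x genes
    d = cdist(pts, pts, metric="euclidean")
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=expr.columns, columns=expr.columns)


@dataclass
class MDSConfiguration:
    """Classical (Torgerson) scaling solution."""

    coordinates: pd.DataFrame  # samples x dims
    eigenvalues: np.ndarray


def classical_mds(dist: pd.DataFrame, dims: int = 2) -> MDSConfiguration:
    """Classical MDS by double-centering the squared distance matrix.

    Coordinates come from the top eigenpairs of -1/2 * J D^2 J; each
    axis's sign is fixed so its largest-magnitude loading is positive.
    """
    D = np.asarray(dist, float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    positive = int((w > 1e-10 * max(w.max(), 1.0)).sum())
    if dims > positive:
        raise ValueError(f"requested {dims} dimensions but the scaling "
                         f"solution has rank {positive}")
    coords = v[:, :dims] * np.sqrt(w[:dims])
    for j in range(dims):
        if coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    coords -= coords.mean(axis=0)
    cols = [f"dim{j + 1}" for j in range(dims)]
    return MDSConfiguration(
        pd.DataFrame(coords, index=dist.index, columns=cols), w)


def distance_correlation(dA: pd.DataFrame, dB: pd.DataFrame) -> float:
    """Pearson correlation of the strictly-lower triangles."""
    A, B = np.asarray(dA, float), np.asarray(dB, float)
    if A.shape != B.shape:
        raise ValueError("distance matrices must have the same shape")
    tri = np.tril_indices(A.shape[0], k=-1)
    return float(np.corrcoef(A[tri], B[tri])[0, 1])


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------

def knn_loo(expr: pd.DataFrame, labels: pd.Series, genes, k: int = 3):
    """Leave-one-out k-nearest-neighbour prediction.

    Each sample is predicted by majority vote among its k nearest other
    samples (Euclidean distance over ``genes``).  Vote ties go to the
    class of the nearest neighbour within the tied classes; distance
    ties are resolved by sample order, keeping the procedure
    deterministic.

    Returns (predictions Series, per-class accuracy Series).
    """
    labels = labels.loc[expr.columns]
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = labels.value_counts()
    if (counts == 0).any():
        raise ValueError("every class needs at least one sample")
    n = len(labels)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    D = distance_matrix(expr, genes).to_numpy()
    lab = labels.to_numpy()
    preds = []
    for i in range(n):
        d = D[i].copy()
        d[i] = np.inf
        # argsort is stable -> equal distances resolve by sample order
        nn = np.argsort(d, kind="stable")[:k]
        votes = pd.Series(lab[nn]).value_counts()
        top = votes[votes == votes.iloc[0]].index
        if len(top) == 1:
            preds.append(top[0])
        else:
            tied = [j for j in nn if lab[j] in set(top)]
            preds.append(lab[tied[0]])
    preds = pd.Series(preds, index=labels.index, name="predicted")
    acc = {}
    for c in classes:
        mask = lab == c
        acc[c] = float(np.mean(preds.to_numpy()[mask] == c))
    return preds, pd.Series(acc, name="accuracy")


# ---------------------------------------------------------------------------
# accuracy curves
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Accuracy (mean and sd over replicates) versus number of genes."""

    gene_counts: tuple
    per_class: pd.DataFrame   # MultiIndex (class, n_genes) -> mean, sd
    overall: pd.DataFrame     # index n_genes -> mean, sd
    baseline_uniform: float
    baseline_permutation: pd.Series  # per class (+ 'overall')
    replicates: int
    restriction: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (cls, n), r in self.per_class.iterrows():
            rows.append({"restriction": self.restriction, "class": cls,
                         "n_genes": n, "mean_acc": r["mean"], "sd_acc": r["sd"],
                         "baseline": self.baseline_permutation[cls]})
        for n, r in self.overall.iterrows():
            rows.append({"restriction": self.restriction, "class": "overall",
                         "n_genes": n, "mean_acc": r["mean"], "sd_acc": r["sd"],
                         "baseline": self.baseline_permutation["overall"]})
        return pd.DataFrame(rows)


def _eligible_genes(expr: pd.DataFrame, genes: pd.DataFrame | None,
                    restriction: str, exclude_chromosomes=frozenset()):
    pool = expr.index
    if genes is None:
        return list(pool)
    ann = genes.loc[genes.index.intersection(pool)]
    keep = ann["biotype"] != "pseudogene"  # pseudogenes never enter
    if restriction == "lncRNA":
        keep &= ann["biotype"] == "lncRNA"
    elif restriction == "protein_coding":
        keep &= ann["biotype"] == "protein_coding"
    elif restriction not in ("all", "exclude_chromosomes"):
        raise ValueError(f"unknown restriction {restriction!r}")
    if exclude_chromosomes:
        keep &= ~ann["chromosome"].astype(str).isin(
            {str(c) for c in exclude_chromosomes})
    return list(ann.index[keep])


def _permutation_baseline(labels: pd.Series) -> pd.Series:
    freq = labels.value_counts(normalize=True)
    base = {c: float(freq[c]) for c in freq.index}
    base["overall"] = float((freq ** 2).sum())
    return pd.Series(base)


def accuracy_curve(expr: pd.DataFrame, labels: pd.Series,
                   genes: pd.DataFrame | None = None,
                   gene_counts=DEFAULT_GENE_COUNTS,
                   replicates: int = 100,
                   gene_subsample_frac: float = 0.5,
                   k: int = 3,
                   restriction: str = "all",
                   exclude_chromosomes=frozenset(),
                   rng: np.random.Generator | None = None,
                   ) -> ClassificationReport:
    """Repeated-subsampling KNN accuracy versus number of genes.

    Per replicate, ``gene_subsample_frac`` of the eligible genes is
    drawn without replacement, ranked by logCPM variance across the
    classified samples, and leave-one-out KNN is evaluated at each
    value in ``gene_counts``.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = rng or np.random.default_rng()
    labels = labels.loc[expr.columns]
    pool = _eligible_genes(expr, genes, restriction, exclude_chromosomes)
    n_draw = int(round(gene_subsample_frac * len(pool)))
    if max(gene_counts) > n_draw:
        raise ValueError(
            f"gene_counts up to {max(gene_counts)} exceed the per-replicate "
            f"pool of {n_draw} genes ({len(pool)} eligible)")
    classes = list(labels.unique())
    per_class = {(c, n): [] for c in classes for n in gene_counts}
    overall = {n: [] for n in gene_counts}
    pool_arr = np.array(pool)
    for _ in range(replicates):
        draw = rng.choice(len(pool_arr), size=n_draw, replace=False)
        drawn = pool_arr[draw]
        v = expr.loc[drawn].var(axis=1, ddof=1).to_numpy()
        order = drawn[np.argsort(-v, kind="stable")]
        for n in gene_counts:
            top = order[:n]
            preds, acc = knn_loo(expr, labels, top, k=k)
            for c in classes:
                per_class[(c, n)].append(acc[c])
            overall[n].append(float((preds == labels).mean()))
    pc = pd.DataFrame(
        {"mean": {key: np.mean(v) for key, v in per_class.items()},
         "sd": {key: np.std(v, ddof=1) if len(v) > 1 else 0.0
                for key, v in per_class.items()}})
    pc.index = pd.MultiIndex.from_tuples(pc.index, names=["class", "n_genes"])
    ov = pd.DataFrame(
        {"mean": {n: np.mean(v) for n, v in overall.items()},
         "sd": {n: np.std(v, ddof=1) if len(v) > 1 else 0.0
                for n, v in overall.items()}})
    ov.index.name = "n_genes"
    return ClassificationReport(
        gene_counts=tuple(gene_counts), per_class=pc, overall=ov,
        baseline_uniform=1.0 / len(classes),
        baseline_permutation=_permutation_baseline(labels),
        replicates=replicates, restriction=restriction)


def balanced_accuracy_curve(expr: pd.DataFrame, labels: pd.Series,
                            genes: pd.DataFrame | None = None,
                            gene_counts=DEFAULT_GENE_COUNTS,
                            replicates: int = 100,
                            gene_subsample_frac: float = 0.5,
                            k: int = 3,
                            balanced_n: int = 4,
                            restriction: str = "all",
                            rng: np.random.Generator | None = None,
                            ) -> ClassificationReport:
    """Class-balanced variant: undersample each class, then classify.

    Every replicate draws ``balanced_n`` samples per class (without
    replacement) and proceeds as :func:`accuracy_curve` on that subset;
    accuracy estimates therefore reflect equal class priors.
    """
    rng = rng or np.random.default_rng()
    labels = labels.loc[expr.columns]
    counts = labels.value_counts()
    small = counts[counts < balanced_n]
    if len(small):
        raise ValueError(
            f"class {small.index[0]!r} has {small.iloc[0]} samples; "
            f"{balanced_n} required for balancing")
    classes = list(labels.unique())
    pool = _eligible_genes(expr, genes, restriction)
    n_draw = int(round(gene_subsample_frac * len(pool)))
    if max(gene_counts) > n_draw:
        raise ValueError("gene_counts exceed the per-replicate gene pool")
    per_class = {(c, n): [] for c in classes for n in gene_counts}
    overall = {n: [] for n in gene_counts}
    pool_arr = np.array(pool)
    for _ in range(replicates):
        chosen = []
        for c in classes:
            ids = labels.index[labels == c].to_numpy()
            chosen.extend(rng.choice(ids, size=balanced_n, replace=False))
        sub_expr = expr[chosen]
        sub_labels = labels.loc[chosen]
        draw = rng.choice(len(pool_arr), size=n_draw, replace=False)
        drawn = pool_arr[draw]
        v = sub_expr.loc[drawn].var(axis=1, ddof=1).to_numpy()
        order = drawn[np.argsort(-v, kind="stable")]
        for n in gene_counts:
            preds, acc = knn_loo(sub_expr, sub_labels, order[:n], k=k)
            for c in classes:
                per_class[(c, n)].append(acc[c])
            overall[n].append(float((preds == sub_labels).mean()))
    pc = pd.DataFrame(
        {"mean": {key: np.mean(v) for key, v in per_class.items()},
         "sd": {key: np.std(v, ddof=1) if len(v) > 1 else 0.0
                for key, v in per_class.items()}})
    pc.index = pd.MultiIndex.from_tuples(pc.index, names=["class", "n_genes"])
    ov = pd.DataFrame(
        {"mean": {n: np.mean(v) for n, v in overall.items()},
         "sd": {n: np.std(v, ddof=1) if len(v) > 1 else 0.0
                for n, v in overall.items()}})
    ov.index.name = "n_genes"
    base = pd.Series({**{c: 1.0 / len(classes) for c in classes},
                      "overall": 1.0 / len(classes)})
    return ClassificationReport(
        gene_counts=tuple(gene_counts), per_class=pc, overall=ov,
        baseline_uniform=1.0 / len(classes), baseline_permutation=base,
        replicates=replicates, restriction=f"balanced:{restriction}")
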