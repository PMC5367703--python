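"""Co-expression modules via topological overlap.

Pairwise gene correlations are raised to a soft-threshold power to form
an unsigned adjacency, smoothed into a topological overlap matrix
(TOM), and clustered hierarchically (Ward linkage on 1 - TOM).  Initial
modules come from the static tree cut producing the most modules above
the minimum size; modules whose eigengenes are nearly collinear are
merged.  Module eigengenes (first principal components) are then
correlated with subtype membership indicators, and arbitrary gene sets
can be tested for over-representation within modules.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .config import SUBTYPES
from .diffexp import bh_fdr
from .epigenome import hypergeom_upper


def soft_adjacency(expr: pd.DataFrame, genes, power: float = 6.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |cor(x_i, x_j)|^power."""
    if power < 1:
        raise ValueError("power must be >= 1")
    genes = list(genes)
    sub = expr.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValueError(f"zero-variance gene {sd.index[sd == 0][0]!r}")
    r = np.corrcoef(sub.to_numpy())
    a = np.abs(r) ** power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=genes, columns=genes)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Unsigned TOM: shared-neighbour-smoothed adjacency in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with k the row sums and TOM_ii = 1.
    """
    a = adjacency.to_numpy(float)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def module_eigengene(expr: pd.DataFrame, module_genes) -> pd.Series:
    """First principal component of the standardised module submatrix.

    Scaled to unit variance; sign fixed so the mean correlation with
    member genes is non-negative.  A single-gene module returns that
    gene's standardised profile.
    """
    module_genes = list(module_genes)
    if not module_genes:
        raise ValueError("empty module")
    sub = expr.loc[module_genes].to_numpy(float)
    z = (sub - sub.mean(axis=1, keepdims=True))
    sd = z.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("zero-variance gene in module")
    z = z / sd
    if len(module_genes) == 1:
        eig = z[0]
    else:
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
    eig = eig / eig.std(ddof=1)
    corr = z @ eig / (len(eig) - 1)
    if corr.mean() < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns, name="eigengene")


def _static_cut(Z: np.ndarray, n_leaves: int, min_size: int) -> np.ndarray:
    """Cut height maximising the number of modules of size >= min_size."""
    heights = np.unique(Z[:, 2])
    cuts = np.concatenate([[0.0], (heights[:-1] + heights[1:]) / 2,
                           [heights[-1] + 1.0]])
    best_labels, best_count, best_h = None, -1, None
    for h in cuts:
        labels = hierarchy.fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(labels)
        count = int((sizes[1:] >= min_size).sum())
        if count >= best_count:  # >= keeps the coarsest among ties
            best_labels, best_count, best_h = labels, count, h
    return best_labels


def detect_modules(dissimilarity: pd.DataFrame, expr: pd.DataFrame,
                   min_module_size: int = 30,
                   merge_dissimilarity: float = 0.25,
                   min_membership: float = 0.5,
                   linkage_method: str = "ward") -> pd.Series:
    """Assign genes to co-expression modules (0 = unassigned).

    Ward linkage (the squared-update variant, as in R's ward.D2 on a
    distance matrix) on the TOM dissimilarity, a static cut keeping the
    most modules above ``min_module_size``, a cohesion filter (modules
    whose mean gene-eigengene correlation falls below
    ``min_membership`` are dissolved — this is what keeps unstructured
    genes unassigned), then iterative merging of module pairs whose
    eigengene dissimilarity (1 - r) is below ``merge_dissimilarity``.
    """
    d = dissimilarity.to_numpy(float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    gene_ids = list(dissimilarity.index)
    if len(gene_ids) < min_module_size:
        return pd.Series(0, index=gene_ids, name="module")
    Z = hierarchy.linkage(squareform(d, checks=False), method=linkage_method)
    raw = _static_cut(Z, len(gene_ids), min_module_size)
    labels = pd.Series(raw, index=gene_ids)
    sizes = labels.value_counts()
    keep = sizes.index[sizes >= min_module_size]
    labels[~labels.isin(keep)] = 0

    # dissolve incohesive modules (mean member-eigengene |r|)
    for m in [m for m in labels.unique() if m != 0]:
        members = labels.index[labels == m]
        eig = module_eigengene(expr, members)
        sub = expr.loc[members].to_numpy(float)
        z = sub - sub.mean(axis=1, keepdims=True)
        z /= z.std(axis=1, ddof=1, keepdims=True)
        kme = z @ eig.to_numpy() / (len(eig) - 1)
        if np.abs(kme).mean() < min_membership:
            labels[members] = 0

    # merge near-collinear modules by eigengene correlation
    while True:
        mods = sorted(m for m in labels.unique() if m != 0)
        if len(mods) < 2:
            break
        eig = {m: module_eigengene(expr, labels.index[labels == m])
               for m in mods}
        best = None
        for i, mi in enumerate(mods):
            for mj in mods[i + 1:]:
                diss = 1.0 - float(np.corrcoef(eig[mi], eig[mj])[0, 1])
                if diss < merge_dissimilarity and (
                        best is None or diss < best[0]):
                    best = (diss, mi, mj)
        if best is None:
            break
        _, mi, mj = best
        labels[labels == mj] = mi

    # relabel 1..M by decreasing size for stable output
    mods = [m for m in labels.value_counts().index if m != 0]
    mapping = {m: i + 1 for i, m in enumerate(mods)}
    mapping[0] = 0
    out = labels.map(mapping)
    out.name = "module"
    return out


def module_eigengenes(expr: pd.DataFrame, modules: pd.Series) -> pd.DataFrame:
    """Eigengene per module (columns: module ids, rows: samples)."""
    out = {}
    for m in sorted(set(modules.unique()) - {0}):
        out[m] = module_eigengene(expr, modules.index[modules == m])
    return pd.DataFrame(out)


def module_trait_correlation(eigengenes: pd.DataFrame,
                             samples: pd.DataFrame,
                             subtypes=SUBTYPES) -> pd.DataFrame:
    """Correlate eigengenes with 0/1 subtype-membership indicators.

    Pearson r with a t-distribution p-value per module x subtype cell;
    one BH correction across all cells.
    """
    rows = []
    n = len(eigengenes.index)
    for m in eigengenes.columns:
        e = eigengenes[m].to_numpy()
        for s in subtypes:
            ind = (samples.loc[eigengenes.index, "group"] == s).to_numpy(float)
            if ind.sum() < 2 or (len(ind) - ind.sum()) < 2:
                raise ValueError(f"subtype {s!r} needs >= 2 samples in and out")
            if np.std(e) == 0:
                r_val, p = np.nan, np.nan
            else:
                r_val, p = stats.pearsonr(e, ind)
            rows.append({"module": m, "subtype": s, "r": r_val, "pvalue": p})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
    out["significant"] = out["fdr"] < 0.1
    return out


def geneset_enrichment(module_genes, term_sets: dict, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of named gene sets in a module."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module = set(module_genes) & universe
    rows = []
    for term, members in sorted(term_sets.items()):
        members = set(members)
        if not members <= universe:
            raise ValueError(f"term {term!r} contains genes outside universe")
        k = len(module & members)
        p = hypergeom_upper(k, len(universe), len(members), len(module))
        rows.append({"term": term, "n_term": len(members),
                     "n_overlap": k, "pvalue": p})
    out = pd.DataFrame(rows).set_index("term")
    out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
    return out


def read_gmt(path) -> dict:
    """Read gene sets in GMT format (term, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) >= 3:
                sets[f[0]] = set(f[2:])
    return sets
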