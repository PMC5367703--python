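"""Normalisation and expression-matrix utilities.

Expression is summarised as log2 counts per million (logCPM) after
upper-quartile library-size normalisation, the scale on which every
downstream analysis (distances, classification, specificity scores,
co-expression) operates.
"""
from __future__ import annotations

import numpy as np
import pandas as pd


def upper_quartile_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample upper-quartile normalisation factors.

    For each sample the 75th percentile (linear interpolation) of the
    counts of genes with a nonzero total across samples is divided by
    the sample's library size; the resulting ratios are rescaled to
    have geometric mean one.  Effective library size = library size x
    factor.
    """
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise ValueError(f"sample {bad!r} has no counts")
    nonzero = counts.loc[counts.sum(axis=1) > 0]
    q = np.percentile(nonzero.to_numpy(), 75, axis=0)
    if (q == 0).any():
        bad = counts.columns[np.argmax(q == 0)]
        raise ValueError(f"sample {bad!r} has an all-zero upper quartile")
    raw = q / lib.to_numpy()
    factors = raw / np.exp(np.mean(np.log(raw)))
    return pd.Series(factors, index=counts.columns, name="uq_factor")


def effective_library_sizes(counts: pd.DataFrame,
                            factors: pd.Series | None = None) -> pd.Series:
    if factors is None:
        factors = upper_quartile_factors(counts)
    return counts.sum(axis=0) * factors


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None,
            prior_count: float = 1.0) -> pd.DataFrame:
    """log2 CPM with a pseudo-count.

    value = log2((count + prior) / (effective library size + 2*prior) * 1e6)

    The prior enters the numerator once and the denominator twice,
    keeping zero counts finite while leaving large counts essentially
    untouched.
    """
    if prior_count < 0:
        raise ValueError("prior_count must be non-negative")
    eff = effective_library_sizes(counts, factors).to_numpy()
    vals = np.log2((counts.to_numpy() + prior_count)
                   / (eff + 2.0 * prior_count)[None, :] * 1e6)
    out = pd.DataFrame(vals, index=counts.index, columns=counts.columns)
    out.attrs["normalization"] = "upper_quartile"
    out.attrs["prior_count"] = prior_count
    return out


def cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Linear counts per million on effective library sizes (no prior)."""
    eff = effective_library_sizes(counts, factors).to_numpy()
    return pd.DataFrame(counts.to_numpy() / eff[None, :] * 1e6,
                        index=counts.index, columns=counts.columns)


def top_variance_genes(expr: pd.DataFrame, n: int,
                       genes: pd.DataFrame | None = None,
                       exclude_biotypes: set | frozenset = frozenset(),
                       exclude_chromosomes: set | frozenset = frozenset(),
                       ) -> list[str]:
    """Genes ranked by descending logCPM variance across samples.

    Exclusions are applied first (by biotype and/or chromosome, using
    the gene-model table); ties are broken by gene id so the ranking is
    deterministic.
    """
    eligible = expr.index
    if genes is not None and (exclude_biotypes or exclude_chromosomes):
        ann = genes.loc[genes.index.intersection(eligible)]
        keep = ~ann["biotype"].isin(exclude_biotypes)
        keep &= ~ann["chromosome"].astype(str).isin(
            {str(c) for c in exclude_chromosomes})
        eligible = ann.index[keep]
    if n > len(eligible):
        raise ValueError(
            f"requested {n} genes but only {len(eligible)} are eligible")
    var = expr.loc[eligible].var(axis=1, ddof=1)
    # stable sort on an id-ordered series -> lexicographic ids inside ties
    order = var.loc[sorted(eligible)].sort_values(
        ascending=False, kind="mergesort")
    return list(order.index[:n])


def write_expression(expr: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# normalization: {expr.attrs.get('normalization', 'none')}\n")
        fh.write(f"# prior_count: {expr.attrs.get('prior_count', 0)}\n")
        expr.to_csv(fh, sep="\t", index_label="gene")
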