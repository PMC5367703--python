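"""Differential expression and dysregulation calls.

Each tumour subtype is contrasted against the normal control group in a
negative-binomial log-linear model with batch covariates, tested by
likelihood-ratio tests and corrected per contrast with Benjamini-
Hochberg.  Downstream calls distinguish leukemia-wide dysregulation
(concordant in all four subtypes) from subtype-specific dysregulation
(significant in exactly one), mirror the promoter-mark gene categories
(up / down / not DE), and score subtype specificity on the logCPM
scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import glm
from .config import SUBTYPES
from .expression import (cpm, effective_library_sizes, log_cpm,
                         upper_quartile_factors)

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class NBModelSet:
    """Fitted NB GLMs for the filtered genes (one model per gene)."""

    genes: pd.Index
    samples: pd.Index
    design: np.ndarray          # (S, P)
    columns: list               # design column names
    offset: np.ndarray          # (S,) log effective library sizes
    counts: np.ndarray          # (G, S) filtered counts
    dispersion: np.ndarray      # (G,) shrunk per-gene phi
    common_dispersion: float
    beta: np.ndarray            # (G, P) natural-log coefficients
    loglik: np.ndarray          # (G,) full-model log-likelihood
    converged: np.ndarray       # (G,) bool
    mean_logcpm: pd.Series

    def coef_log2fc(self, contrast: str) -> pd.Series:
        j = self.columns.index(f"group:{contrast}")
        return pd.Series(self.beta[:, j] / LN2, index=self.genes)


def build_design(samples: pd.DataFrame, reference: str = "Control"):
    """Intercept + group indicators (reference dropped) + batch indicators."""
    groups = [g for g in samples["group"].unique() if g != reference]
    groups = [g for g in SUBTYPES if g in groups] + \
             [g for g in groups if g not in SUBTYPES]
    cols = ["intercept"]
    mats = [np.ones(len(samples))]
    for g in groups:
        cols.append(f"group:{g}")
        mats.append((samples["group"] == g).to_numpy(float))
    batches = sorted(samples["batch"].astype(str).unique())
    for b in batches[1:]:
        cols.append(f"batch:{b}")
        mats.append((samples["batch"].astype(str) == b).to_numpy(float))
    X = np.column_stack(mats)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by greedy rank growth
        aliased, keep = [], []
        for j, name in enumerate(cols):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
            else:
                aliased.append(name)
        raise ValueError(f"design is not full rank; aliased columns: {aliased}")
    return X, cols


def filter_expressed(counts: pd.DataFrame, min_cpm: float = 1.0,
                     min_samples: int = 3) -> pd.Index:
    """Genes with CPM above ``min_cpm`` in at least ``min_samples`` samples."""
    c = cpm(counts)
    return counts.index[(c > min_cpm).sum(axis=1) >= min_samples]


def fit_nb_glm(counts: pd.DataFrame, samples: pd.DataFrame,
               prior_df: float = 10.0, min_cpm: float = 1.0,
               min_samples: int = 3) -> NBModelSet:
    """Fit one NB GLM per expressed gene (subtype + batch coefficients).

    Offsets are log effective library sizes from upper-quartile
    normalisation computed on the full matrix; low-expression genes
    (CPM <= ``min_cpm`` in fewer than ``min_samples`` samples) are
    excluded before dispersion estimation.
    """
    counts = counts[list(samples.index)]
    X, cols = build_design(samples)
    factors = upper_quartile_factors(counts)
    offset = np.log(effective_library_sizes(counts, factors).to_numpy())
    keep = filter_expressed(counts, min_cpm, min_samples)
    y = counts.loc[keep].to_numpy(float)
    disp = glm.estimate_dispersions(y, X, offset, prior_df=prior_df)
    beta, mu, _, conv = glm.irls_fit(y, X, offset, disp.per_gene)
    ll = glm.nb_loglik(y, mu, disp.per_gene)
    mean_logcpm = log_cpm(counts.loc[keep], factors).mean(axis=1)
    return NBModelSet(genes=keep, samples=counts.columns, design=X,
                      columns=cols, offset=offset, counts=y,
                      dispersion=disp.per_gene,
                      common_dispersion=disp.common, beta=beta, loglik=ll,
                      converged=conv, mean_logcpm=mean_logcpm)


def lrt_test(models: NBModelSet, contrast: str) -> pd.DataFrame:
    """Likelihood-ratio test dropping one subtype coefficient.

    The deviance difference between the full fit and the fit without the
    contrast's indicator is referred to chi-squared with 1 df.  Genes
    whose reduced fit failed to converge get NA p-values and are left
    out of the FDR denominator.
    """
    col = f"group:{contrast}"
    if col not in models.columns:
        raise ValueError(f"no samples / coefficient for contrast {contrast!r}")
    j = models.columns.index(col)
    X_red = np.delete(models.design, j, axis=1)
    beta0 = np.delete(models.beta, j, axis=1)
    beta_r, mu_r, _, conv_r = glm.irls_fit(
        models.counts, X_red, models.offset, models.dispersion, beta0=beta0)
    ll_red = glm.nb_loglik(models.counts, mu_r, models.dispersion)
    stat = np.maximum(2.0 * (models.loglik - ll_red), 0.0)
    p = stats.chi2.sf(stat, df=1)
    ok = models.converged & conv_r
    p = np.where(ok, p, np.nan)
    out = pd.DataFrame({
        "gene": models.genes,
        "contrast": contrast,
        "log2fc": models.beta[:, j] / LN2,
        "pvalue": p,
        "fdr": bh_fdr(p),
        "mean_logcpm": models.mean_logcpm.to_numpy(),
    })
    return out


def de_table(models: NBModelSet, contrasts=SUBTYPES) -> pd.DataFrame:
    """Long-form DE table over all subtype-vs-control contrasts."""
    parts = [lrt_test(models, c) for c in contrasts
             if f"group:{c}" in models.columns]
    if not parts:
        raise ValueError("no subtype contrasts present in the model")
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    q = p[mask]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = q.size
    if n == 0:
        return out
    order = np.argsort(q, kind="mergesort")
    scaled = q[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    res = np.empty(n)
    res[order] = np.minimum(adj, 1.0)
    out[mask] = res
    return out


# ---------------------------------------------------------------------------
# dysregulation calls
# ---------------------------------------------------------------------------

def call_dysregulation(de: pd.DataFrame, fdr_de: float = 1e-3,
                       logfc_updown: float = 2.0,
                       fdr_notde: float = 0.5) -> pd.DataFrame:
    """Classify genes by their pattern of dysregulation across subtypes.

    Returns a per-gene frame with:

    * ``leukemia_status`` — up / down when significant with the same
      sign in all four subtypes, mixed when significant everywhere with
      discordant signs, none otherwise;
    * ``specific_subtype`` — the subtype when significant in exactly
      one contrast;
    * ``fig_category`` — up / down (FDR < ``fdr_de`` and |log2FC| >
      ``logfc_updown`` in all subtypes), not_de (FDR > ``fdr_notde``
      everywhere), or other — the categories used in the promoter-mark
      analysis;
    * ``is_det`` — significant in at least one contrast.
    """
    need = set(SUBTYPES)
    have = set(de["contrast"].unique())
    if not need <= have:
        raise ValueError(f"missing contrasts: {sorted(need - have)}")
    fdr = de.pivot(index="gene", columns="contrast", values="fdr")[list(SUBTYPES)]
    lfc = de.pivot(index="gene", columns="contrast", values="log2fc")[list(SUBTYPES)]
    sig = (fdr <= fdr_de).fillna(False)
    n_sig = sig.sum(axis=1)

    all_sig = sig.all(axis=1)
    up_all = all_sig & (lfc > 0).all(axis=1)
    down_all = all_sig & (lfc < 0).all(axis=1)
    status = pd.Series("none", index=fdr.index)
    status[all_sig] = "mixed"
    status[up_all] = "up"
    status[down_all] = "down"

    specific = pd.Series("none", index=fdr.index)
    one = n_sig == 1
    specific[one] = sig.loc[one].idxmax(axis=1)

    strong = (fdr < fdr_de).fillna(False)
    fig_up = (strong & (lfc > logfc_updown)).all(axis=1)
    fig_down = (strong & (lfc < -logfc_updown)).all(axis=1)
    not_de = (fdr > fdr_notde).fillna(False).all(axis=1)
    fig = pd.Series("other", index=fdr.index)
    fig[not_de] = "not_de"
    fig[fig_up] = "up"
    fig[fig_down] = "down"

    return pd.DataFrame({
        "leukemia_status": status,
        "specific_subtype": specific,
        "fig_category": fig,
        "is_det": n_sig >= 1,
    })


def specificity_score(expr: pd.DataFrame, samples: pd.DataFrame,
                      subtype_fold: float = 4.0) -> pd.DataFrame:
    """Subtype-specificity scores on the logCPM scale.

    For each gene and focal tumour subtype, the score is the difference
    between the gene's mean logCPM in the focal subtype and its mean in
    the *closest* other tumour subtype (the one with the nearest group
    mean).  The 4-fold flag requires the focal mean to differ from the
    pooled mean of all other tumour samples by at least
    ``log2(subtype_fold)``.
    """
    tumor = samples.index[samples["group"] != "Control"]
    present = [s for s in SUBTYPES
               if (samples.loc[tumor, "group"] == s).any()]
    if len(present) < 2:
        raise ValueError("need at least two tumour subtypes")
    means = {}
    for s in present:
        ids = samples.index[(samples["group"] == s)]
        means[s] = expr[list(ids)].mean(axis=1)
    means = pd.DataFrame(means)
    out = {}
    for s in present:
        others = [o for o in present if o != s]
        diff = means[others].sub(means[s], axis=0).abs()
        closest = diff.idxmin(axis=1)
        closest_mean = means[others].to_numpy()[
            np.arange(len(means)),
            [others.index(c) for c in closest]]
        score = means[s] - closest_mean
        pooled_ids = samples.index[samples["group"].isin(others)]
        pooled = expr[list(pooled_ids)].mean(axis=1)
        flag = (means[s] - pooled).abs() >= np.log2(subtype_fold)
        out[(s, "score")] = score
        out[(s, "fourfold")] = flag
    res = pd.DataFrame(out)
    res.columns = pd.MultiIndex.from_tuples(res.columns,
                                            names=["subtype", "field"])
    return res


# ---------------------------------------------------------------------------
# cross-dataset comparison
# ---------------------------------------------------------------------------

def compare_de_tables(deA: pd.DataFrame, deB: pd.DataFrame,
                      threshold: float = 1e-3) -> dict:
    """Overlap and effect-size agreement between two DE tables.

    Gene universes are intersected; significance is FDR <= threshold in
    each table.  The expected overlap under independent random draws is
    nA * nB / N, and correlations are computed on the genes significant
    in both.
    """
    a = deA.drop_duplicates("gene").set_index("gene")
    b = deB.drop_duplicates("gene").set_index("gene")
    universe = a.index.intersection(b.index)
    if len(universe) == 0:
        raise ValueError("empty shared gene universe")
    a, b = a.loc[universe], b.loc[universe]
    sigA = a.index[a["fdr"] <= threshold]
    sigB = b.index[b["fdr"] <= threshold]
    overlap = sigA.intersection(sigB)
    expected = len(sigA) * len(sigB) / len(universe)
    result = {
        "n_universe": len(universe),
        "n_sig_a": len(sigA),
        "n_sig_b": len(sigB),
        "n_overlap": len(overlap),
        "expected_overlap": expected,
        "fold_enrichment": (len(overlap) / expected) if expected > 0 else np.nan,
        "pearson_r": np.nan,
        "spearman_r": np.nan,
        "sign_concordance": np.nan,
    }
    if len(overlap) >= 2:
        x = a.loc[overlap, "log2fc"].to_numpy()
        y = b.loc[overlap, "log2fc"].to_numpy()
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            result["pearson_r"] = float(stats.pearsonr(x, y)[0])
            result["spearman_r"] = float(stats.spearmanr(x, y)[0])
        result["sign_concordance"] = float(np.mean(np.sign(x) == np.sign(y)))
    return result


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Sample odds ratio and Fisher exact p for a 2x2 table [[a,b],[c,d]]."""
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError(f"zero margin in 2x2 table [[{a},{b}],[{c},{d}]]")
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    p = stats.fisher_exact([[a, b], [c, d]])[1]
    return float(odds), float(p)


def biotype_specificity_odds(calls: pd.DataFrame,
                             genes: pd.DataFrame) -> dict:
    """Are differentially expressed lncRNAs more often subtype-specific?

    Builds the 2x2 table (lncRNA vs other biotype) x (subtype-specific
    vs not) over DETs and returns the sample odds ratio with a Fisher
    exact p-value.
    """
    det = calls.index[calls["is_det"]]
    if len(det) == 0:
        raise ValueError("no differentially expressed genes")
    bio = genes.loc[det, "biotype"]
    is_lnc = bio == "lncRNA"
    is_spec = calls.loc[det, "specific_subtype"] != "none"
    a = int((is_lnc & is_spec).sum())
    b = int((is_lnc & ~is_spec).sum())
    c = int((~is_lnc & is_spec).sum())
    d = int((~is_lnc & ~is_spec).sum())
    odds, p = odds_ratio_2x2(a, b, c, d)
    return {"odds_ratio": odds, "fisher_p": p,
            "table": {"a": a, "b": b, "c": c, "d": d}}
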