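"""Interval arithmetic and peak-enrichment statistics.

Promoter windows are anchored on each gene's most upstream TSS and
tested for overlap with histone-mark or transcription-factor peak sets
(BED semantics throughout: 0-based, half-open).  Bivalency — a promoter
carrying both activating H3K4me3 and repressive H3K27me3 — is compared
between dysregulation categories, and TF-peak enrichment over a
background gene set is scored with the hypergeometric upper tail.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr
from .io import PeakSet

log = logging.getLogger("callsig")


# ---------------------------------------------------------------------------
# windows and overlap
# ---------------------------------------------------------------------------

def tss_windows(genes: pd.DataFrame, flank: int = 5000,
                most_upstream: bool = True) -> pd.DataFrame:
    """Promoter windows [TSS - flank, TSS + flank), clipped at zero.

    The anchor is the most upstream TSS: the smallest coordinate on the
    plus strand, the largest on the minus strand.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    anchors = []
    for gid, r in genes.iterrows():
        sites = r["tss"]
        if most_upstream:
            t = min(sites) if r["strand"] == "+" else max(sites)
        else:
            t = sites[0]
        anchors.append((gid, str(r["chromosome"]), t))
    df = pd.DataFrame(anchors, columns=["gene", "chromosome", "tss"])
    df["start"] = np.maximum(df["tss"] - flank, 0)
    df["end"] = df["tss"] + flank
    return df.set_index("gene")[["chromosome", "start", "end", "tss"]]


def overlaps(queries: pd.DataFrame, peaks: PeakSet | pd.DataFrame) -> pd.Series:
    """Whether each query interval overlaps >= 1 peak by >= 1 bp.

    Uses per-chromosome sorted boundary arrays: an interval [s, e)
    overlaps some peak iff the number of peak starts below e exceeds
    the number of peak ends at or below s.  Input order of either set
    is irrelevant.
    """
    pk = peaks.intervals if isinstance(peaks, PeakSet) else peaks
    if (pk["start"] >= pk["end"]).any() or (pk["start"] < 0).any():
        raise ValueError("malformed peak interval")
    if (queries["start"] >= queries["end"]).any():
        raise ValueError("malformed query interval")
    out = np.zeros(len(queries), bool)
    q_chrom = queries["chromosome"].astype(str).to_numpy()
    q_start = queries["start"].to_numpy()
    q_end = queries["end"].to_numpy()
    for ch, grp in pk.groupby(pk["chromosome"].astype(str)):
        starts = np.sort(grp["start"].to_numpy())
        ends = np.sort(grp["end"].to_numpy())
        mask = q_chrom == ch
        if not mask.any():
            continue
        n_before = np.searchsorted(starts, q_end[mask], side="left")
        n_done = np.searchsorted(ends, q_start[mask], side="right")
        out[mask] = (n_before - n_done) > 0
    return pd.Series(out, index=queries.index, name="overlaps")


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

def metagene_profile(peaks: PeakSet, windows: pd.DataFrame,
                     bins: int = 50) -> np.ndarray:
    """Fraction of windows whose i-th bin touches a peak, per bin.

    Each window is split into ``bins`` equal-width bins; the profile is
    the per-bin fraction of windows with at least one overlapping peak.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if len(windows) == 0:
        return np.zeros(bins)
    starts = windows["start"].to_numpy(float)
    ends = windows["end"].to_numpy(float)
    chroms = windows["chromosome"].astype(str).to_numpy()
    edges = np.linspace(0, 1, bins + 1)
    width = (ends - starts)[:, None]
    bin_start = np.floor(starts[:, None] + width * edges[:-1]).astype(int)
    bin_end = np.ceil(starts[:, None] + width * edges[1:]).astype(int)
    bin_end = np.maximum(bin_end, bin_start + 1)
    flat = pd.DataFrame({
        "chromosome": np.repeat(chroms, bins),
        "start": bin_start.ravel(),
        "end": bin_end.ravel(),
    })
    hit = overlaps(flat, peaks).to_numpy().reshape(len(windows), bins)
    return hit.mean(axis=0)


def gene_body_windows(genes: pd.DataFrame, flank: int = 2000) -> pd.DataFrame:
    """Gene bodies with flanks, for body-mark (e.g. H3K36me3) profiles."""
    df = pd.DataFrame({
        "chromosome": genes["chromosome"].astype(str),
        "start": np.maximum(genes["start"] - flank, 0),
        "end": genes["end"] + flank,
    }, index=genes.index)
    return df


# ---------------------------------------------------------------------------
# bivalency
# ---------------------------------------------------------------------------

def bivalency_fractions(k27: PeakSet, k4: PeakSet, windows: pd.DataFrame,
                        categories: pd.Series) -> pd.DataFrame:
    """Per-category fractions of K27-marked and bivalent promoters.

    ``categories`` maps gene -> category (up / down / not_de / other).
    The returned frame has one row per category with the fraction of
    genes whose promoter window overlaps H3K27me3, the fraction
    overlapping both marks (bivalent), and counts; ``fold_up_vs_notde``
    in ``.attrs`` is the bivalency enrichment of the up category over
    the not-DE background.
    """
    common = windows.index.intersection(categories.index)
    win = windows.loc[common]
    cat = categories.loc[common]
    has27 = overlaps(win, k27)
    has4 = overlaps(win, k4)
    biv = has27 & has4
    rows = {}
    for c in pd.unique(cat):
        mask = (cat == c).to_numpy()
        n = int(mask.sum())
        if n == 0:
            log.warning("category %r is empty", c)
            rows[c] = {"n": 0, "frac_k27": np.nan, "frac_bivalent": np.nan}
            continue
        rows[c] = {"n": n,
                   "frac_k27": float(has27.to_numpy()[mask].mean()),
                   "frac_bivalent": float(biv.to_numpy()[mask].mean())}
    out = pd.DataFrame(rows).T
    out.index.name = "category"
    if "up" in out.index and "not_de" in out.index:
        ref = out.loc["not_de", "frac_bivalent"]
        out.attrs["fold_up_vs_notde"] = (
            float(out.loc["up", "frac_bivalent"] / ref) if ref > 0 else np.nan)
    return out


# ---------------------------------------------------------------------------
# TF enrichment
# ---------------------------------------------------------------------------

def hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def tf_enrichment(tf_peaks: dict[str, PeakSet], windows: pd.DataFrame,
                  target_genes, background_genes, de: pd.DataFrame,
                  fdr_enrich: float = 0.1) -> pd.DataFrame:
    """Peak enrichment of each TF on target promoters, with TF expression.

    For every TF the promoter windows of the background ("expressed")
    genes define the universe; the hypergeometric upper tail scores the
    overlap between TF-bound genes and the target set, and the ratio is
    the hit fraction in targets over the hit fraction in background.
    Each record carries the TF gene's own expression change: the
    subtype log2FC of smallest magnitude (sign kept).  A TF is called
    significant when both its enrichment FDR and its expression FDR are
    below ``fdr_enrich``.
    """
    background = pd.Index(sorted(set(background_genes)))
    targets = pd.Index(sorted(set(target_genes)))
    if not set(targets) <= set(background):
        raise ValueError("target genes must be a subset of the background")
    win = windows.loc[windows.index.intersection(background)]
    de_by_gene = de.set_index(["gene", "contrast"])
    rows = []
    for tf, peaks in sorted(tf_peaks.items()):
        hit = overlaps(win, peaks)
        hit_genes = set(win.index[hit])
        N = len(background)
        K = len(hit_genes)
        n = len(targets)
        k = len(hit_genes & set(targets))
        p = hypergeom_upper(k, N, K, n)
        ratio = ((k / n) / (K / N)) if (n > 0 and K > 0) else np.nan
        sub = de[de["gene"] == tf]
        if len(sub):
            j = sub["log2fc"].abs().idxmin()
            min_lfc = float(sub.loc[j, "log2fc"])
            tf_fdr = float(sub["fdr"].min())
        else:
            min_lfc, tf_fdr = np.nan, np.nan
        rows.append({"tf": tf, "n_target_hits": k, "n_target": n,
                     "n_background_hits": K, "n_background": N,
                     "ratio": ratio, "pvalue": p,
                     "min_subtype_log2fc": min_lfc, "tf_de_fdr": tf_fdr})
    out = pd.DataFrame(rows).set_index("tf")
    out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
    out["significant"] = ((out["fdr"] < fdr_enrich)
                          & (out["tf_de_fdr"] < fdr_enrich).fillna(False))
    return out
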