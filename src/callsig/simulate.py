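"""Synthetic leukemia cohort with known ground truth.

Generates everything the pipeline consumes — an integer count matrix,
sample metadata, gene models and peak tracks — from an explicit
generative model, so every downstream stage can be validated against
planted truth:

* counts are negative-binomial with mean
  ``L_s * q_g * 2^{beta_g,group(s)} * (c_s,chr(g) / 2) * b_g,batch(s)``
  (library scale, relative abundance, planted group log2 fold change,
  chromosomal copy-number ratio, batch factor) and common dispersion
  ``phi`` (Var = mu + phi mu^2);
* a fraction of genes is leukemia-wide up/down-regulated (same planted
  log2FC in all four subtypes) and a fraction subtype-specific;
* high-hyperdiploid samples gain each frequently gained autosome
  independently with a set probability (copy number 3, multiplicative
  3/2 on the mean);
* promoter peak tracks plant bivalency (H3K27me3 + H3K4me3) on
  up-regulated genes at an enriched rate, H3K36me3 body peaks on
  down-regulated genes, and TF peaks on designated target genes.

A transcription of the real study's cohort-characteristics table is
packaged as :func:`table1_fixture` for parser-level checks.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from .config import AUTOSOMES, SUBTYPES
from .io import PeakSet, read_sample_table


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Generative parameters for the synthetic cohort.

    Group sizes default to the real cohort's composition (11 HeH, 22
    t(12;21), 4 t(9;22), 19 Other, 3 controls).  ``signal_chromosomes``
    optionally confines all planted differential expression to a subset
    of autosomes (used to study dosage-vs-signature questions);
    ``None`` places signal genes anywhere.
    """

    n_genes: int = 2000
    biotype_proportions: dict = field(default_factory=lambda: {
        "protein_coding": 0.62, "lncRNA": 0.28,
        "pseudogene": 0.06, "other": 0.04})
    n_samples: dict = field(default_factory=lambda: {
        "HeH": 11, "t(12;21)": 22, "t(9;22)": 4, "Other": 19, "Control": 3})
    frac_de: float = 0.15          # leukemia-wide DE genes (half up, half down)
    frac_specific: float = 0.08    # subtype-specific genes (split over 4)
    lfc_mean: float = 2.0          # |log2FC| magnitude, normal(mean, sd)
    lfc_sd: float = 0.75
    de_abundance_cap: float = 0.98  # DE planted below this abundance quantile
    dispersion: float = 0.1        # NB phi; 0 -> Poisson
    libsize_meanlog: float = float(np.log(1e6))
    libsize_sdlog: float = 0.25
    abundance_sdlog: float = 1.2   # spread of relative gene abundances
    batch_sd: float = 0.1          # sd of per-gene log-normal batch factors
    n_batches: int = 2
    trisomy_prob: float = 0.8      # P(gain) per frequently gained autosome
    heh_gained: tuple = ("4", "6", "10", "14", "17", "18", "21")
    bivalency_baseline: float = 0.033
    bivalency_enrichment: float = 3.3
    k4_active_rate: float = 0.5
    k27_solo_rate: float = 0.05
    k36_baseline: float = 0.25
    k36_enrichment: float = 3.0
    n_tfs: int = 12
    tf_baseline: float = 0.1
    tf_enrichment: float = 3.0
    signal_chromosomes: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or sum(self.n_samples.values()) < 2:
            raise ValueError("degenerate configuration: need genes and samples")
        total = sum(self.biotype_proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError("biotype proportions must sum to 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not (0 <= self.frac_de <= 1 and 0 <= self.frac_specific <= 1):
            raise ValueError("fractions must be in [0, 1]")


@dataclass
class SimTruth:
    """Planted ground truth for a simulated cohort."""

    genes: pd.DataFrame        # category, lfc per subtype, biotype, chromosome
    samples: pd.DataFrame      # group, batch
    copy_number: pd.DataFrame  # samples x autosomes, integer copies
    is_bivalent_in_control: pd.Series | None = None
    tf_targets: dict | None = None


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _child_rngs(seed: int, n: int):
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _make_gene_models(cfg: SimConfig, rng) -> pd.DataFrame:
    n = cfg.n_genes
    ids = [f"G{i:05d}" for i in range(1, n + 1)]
    chroms = rng.choice(AUTOSOMES, size=n)
    biotypes = rng.choice(list(cfg.biotype_proportions),
                          p=list(cfg.biotype_proportions.values()), size=n)
    strands = rng.choice(["+", "-"], size=n)
    rows = []
    offsets = {ch: 10_000 for ch in AUTOSOMES}
    for gid, ch, bt, st in zip(ids, chroms, biotypes, strands):
        length = int(rng.integers(2_000, 20_000))
        start = offsets[ch]
        offsets[ch] = start + length + 30_000  # generous intergenic gap
        end = start + length
        n_tss = int(rng.integers(1, 3))
        span = max(int(0.2 * length), 1)
        if st == "+":
            tss = tuple(sorted({start + int(rng.integers(0, span))
                                for _ in range(n_tss)}))
        else:
            tss = tuple(sorted({end - 1 - int(rng.integers(0, span))
                                for _ in range(n_tss)}))
        rows.append({"gene": gid, "chromosome": ch, "start": start,
                     "end": end, "strand": st, "biotype": bt, "tss": tss})
    return pd.DataFrame(rows).set_index("gene")


def _plant_effects(cfg: SimConfig, genes: pd.DataFrame, abundance, rng):
    n = cfg.n_genes
    category = pd.Series("null", index=genes.index)
    lfc = pd.DataFrame(0.0, index=genes.index, columns=list(SUBTYPES))
    eligible = pd.Series(True, index=genes.index)
    # the most abundant transcripts stay unperturbed: large fold changes
    # on them would shift the whole library composition, which real
    # cohorts (and count normalisation) do not exhibit
    cap = np.quantile(abundance, cfg.de_abundance_cap)
    eligible &= pd.Series(abundance < cap, index=genes.index)
    if cfg.signal_chromosomes is not None:
        allowed = {str(c) for c in cfg.signal_chromosomes}
        eligible &= genes["chromosome"].isin(allowed)
    candidates = genes.index[eligible].to_numpy()
    n_leuk = int(round(cfg.frac_de * n))
    n_spec_each = int(round(cfg.frac_specific * n / len(SUBTYPES)))
    need = n_leuk + n_spec_each * len(SUBTYPES)
    if need > len(candidates):
        raise ValueError("not enough candidate genes for the planted signal")
    chosen = rng.choice(candidates, size=need, replace=False)
    leuk = chosen[:n_leuk]
    mags = np.clip(rng.normal(cfg.lfc_mean, cfg.lfc_sd, size=need), 0.5, None)
    for i, g in enumerate(leuk):
        sign = 1.0 if i < (n_leuk + 1) // 2 else -1.0
        category[g] = "leukemia_up" if sign > 0 else "leukemia_down"
        lfc.loc[g, :] = sign * mags[i]
    pos = n_leuk
    for s in SUBTYPES:
        for g in chosen[pos:pos + n_spec_each]:
            category[g] = f"specific({s})"
            lfc.loc[g, s] = rng.choice([-1.0, 1.0]) * mags[pos]
            pos += 1
    return category, lfc


def _make_samples(cfg: SimConfig, rng):
    rows = []
    copy = {}
    order = [g for g in ("HeH", "t(12;21)", "t(9;22)", "Other", "Control")
             if g in cfg.n_samples]
    for group in order:
        n = cfg.n_samples[group]
        for i in range(n):
            sid = f"{_slug(group)}_{i + 1:02d}"
            batch = f"B{i % cfg.n_batches + 1}"
            gains = frozenset()
            copies = {ch: 2 for ch in AUTOSOMES}
            if group == "HeH":
                gained = [ch for ch in cfg.heh_gained
                          if rng.random() < cfg.trisomy_prob]
                gains = frozenset(gained)
                for ch in gained:
                    copies[ch] = 3
            dna_index = round((46 + len(gains)) / 46, 2)
            is_tumor = group != "Control"
            events = frozenset()
            if is_tumor and rng.random() < 0.2:
                events = frozenset({"R", "D"} if rng.random() < 0.5 else {"R"})
            rows.append({
                "id": sid, "group": group,
                "sex": "F" if rng.random() < 0.5 else "M",
                "blast_rate": round(float(rng.uniform(50, 100)), 1)
                if is_tumor else np.nan,
                "age_months": int(rng.integers(12, 200)) if is_tumor else 0,
                "dna_index": dna_index if is_tumor else np.nan,
                "karyotype_gains": gains,
                "risk_group": "Standard" if rng.random() < 0.5 else "High",
                "events": events,
                "batch": batch,
            })
            copy[sid] = copies
    samples = pd.DataFrame(rows).set_index("id")
    copy_number = pd.DataFrame(copy).T.reindex(columns=list(AUTOSOMES))
    copy_number.index.name = "id"
    return samples, copy_number


def _slug(group: str) -> str:
    return (group.replace("(", "").replace(")", "")
            .replace(";", "_").replace("t(", "t"))


def simulate_counts(cfg: SimConfig):
    """Draw the synthetic cohort.

    Returns ``(counts, samples, genes, truth)``: an integer gene x
    sample count matrix, the sample table, the gene models, and the
    planted :class:`SimTruth`.
    """
    rng_genes, rng_fx, rng_samples, rng_counts = _child_rngs(cfg.seed, 4)
    genes = _make_gene_models(cfg, rng_genes)
    q = rng_counts.lognormal(0.0, cfg.abundance_sdlog, size=cfg.n_genes)
    q /= q.sum()
    category, lfc = _plant_effects(cfg, genes, q, rng_fx)
    samples, copy_number = _make_samples(cfg, rng_samples)
    lib = rng_counts.lognormal(cfg.libsize_meanlog, cfg.libsize_sdlog,
                               size=len(samples))
    batches = sorted(samples["batch"].unique())
    batch_fac = pd.DataFrame(1.0, index=genes.index, columns=batches)
    for b in batches[1:]:
        batch_fac[b] = rng_counts.lognormal(0.0, cfg.batch_sd,
                                            size=cfg.n_genes)

    chrom_idx = genes["chromosome"].to_numpy()
    mu = np.empty((cfg.n_genes, len(samples)))
    for j, (sid, srow) in enumerate(samples.iterrows()):
        group = srow["group"]
        fold = np.ones(cfg.n_genes) if group == "Control" \
            else np.exp2(lfc[group].to_numpy())
        copies = copy_number.loc[sid].to_numpy()
        copy_ratio = copies[[AUTOSOMES.index(c) for c in chrom_idx]] / 2.0
        mu[:, j] = (lib[j] * q * fold * copy_ratio
                    * batch_fac[srow["batch"]].to_numpy())

    if cfg.dispersion < 1e-8:
        counts = rng_counts.poisson(mu)
    else:
        shape = 1.0 / cfg.dispersion
        lam = rng_counts.gamma(shape, scale=mu * cfg.dispersion)
        counts = rng_counts.poisson(lam)
    counts = pd.DataFrame(counts.astype(np.int64), index=genes.index,
                          columns=pd.Index(list(samples.index)))

    truth_genes = pd.DataFrame({
        "category": category,
        "biotype": genes["biotype"],
        "chromosome": genes["chromosome"],
    }).join(lfc.add_prefix("lfc_"))
    truth = SimTruth(genes=truth_genes,
                     samples=samples[["group", "batch"]].copy(),
                     copy_number=copy_number)
    return counts, samples, genes, truth


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def simulate_peaks(genes: pd.DataFrame, truth: SimTruth, cfg: SimConfig,
                   rng: np.random.Generator | None = None):
    """Plant histone-mark and TF peak tracks consistent with the truth.

    Up-regulated genes receive co-occurring H3K27me3 + H3K4me3 promoter
    peaks (bivalency) at ``bivalency_baseline * bivalency_enrichment``;
    all other genes at the baseline rate.  Down-regulated genes carry
    H3K36me3 gene-body peaks at an enriched rate.  Half of the TFs are
    planted as "deregulation-associated": their peaks hit leukemia-wide
    DE genes at ``tf_baseline * tf_enrichment``.

    Returns ``(marks, tfs)``: dicts of :class:`PeakSet` keyed by mark
    name / TF gene id.  ``truth`` is updated in place with bivalency
    flags and TF target sets.
    """
    rng = rng or _child_rngs(cfg.seed + 101, 1)[0]
    cat = truth.genes["category"]
    anchors = {}
    for gid, r in genes.iterrows():
        t = min(r["tss"]) if r["strand"] == "+" else max(r["tss"])
        anchors[gid] = (str(r["chromosome"]), int(t))

    k27_rows, k4_rows, k36_rows = [], [], []
    bivalent = pd.Series(False, index=genes.index)
    p_biv_up = min(cfg.bivalency_baseline * cfg.bivalency_enrichment, 1.0)
    p_k36_down = min(cfg.k36_baseline * cfg.k36_enrichment, 1.0)
    for gid, r in genes.iterrows():
        ch, t = anchors[gid]
        is_up = cat[gid] == "leukemia_up"
        is_down = cat[gid] == "leukemia_down"
        p_biv = p_biv_up if is_up else cfg.bivalency_baseline
        if rng.random() < p_biv:
            bivalent[gid] = True
            k27_rows.append({"chromosome": ch,
                             "start": max(t - 1500, 0), "end": t + 500})
            k4_rows.append({"chromosome": ch,
                            "start": max(t - 200, 0), "end": t + 800})
        else:
            # solo marks are mutually exclusive so the bivalent rate is
            # exactly the planted one
            u = rng.random()
            if u < cfg.k27_solo_rate:
                k27_rows.append({"chromosome": ch,
                                 "start": max(t - 1500, 0), "end": t + 500})
            elif u < cfg.k27_solo_rate + cfg.k4_active_rate:
                k4_rows.append({"chromosome": ch,
                                "start": max(t - 200, 0), "end": t + 800})
        p36 = p_k36_down if is_down else cfg.k36_baseline
        if rng.random() < p36:
            s, e = int(r["start"]), int(r["end"])
            span = e - s
            k36_rows.append({"chromosome": ch,
                             "start": s + int(0.2 * span),
                             "end": s + max(int(0.8 * span), int(0.2 * span) + 1)})
    marks = {
        "H3K27me3": PeakSet("H3K27me3", pd.DataFrame(
            k27_rows, columns=["chromosome", "start", "end"])),
        "H3K4me3": PeakSet("H3K4me3", pd.DataFrame(
            k4_rows, columns=["chromosome", "start", "end"])),
        "H3K36me3": PeakSet("H3K36me3", pd.DataFrame(
            k36_rows, columns=["chromosome", "start", "end"])),
    }

    # TF peaks: TF identities are gene ids so expression lookups work
    de_genes = genes.index[cat.isin(["leukemia_up", "leukemia_down"])]
    null_genes = genes.index[cat == "null"]
    n_de_tfs = min(cfg.n_tfs // 2, len(de_genes))
    tf_ids = list(rng.choice(de_genes, size=n_de_tfs, replace=False)) + \
        list(rng.choice(null_genes, size=cfg.n_tfs - n_de_tfs, replace=False))
    tfs = {}
    targets = {}
    is_de = pd.Series(cat.isin(["leukemia_up", "leukemia_down"]),
                      index=genes.index)
    for i, tf in enumerate(tf_ids):
        enriched = i < (cfg.n_tfs + 1) // 2  # the DE-drawn TFs are enriched
        rows = []
        tgt = set()
        for gid in genes.index:
            ch, t = anchors[gid]
            p = cfg.tf_baseline * (cfg.tf_enrichment
                                   if enriched and is_de[gid] else 1.0)
            if rng.random() < min(p, 1.0):
                off = int(rng.integers(-3000, 2000))
                rows.append({"chromosome": ch, "start": max(t + off, 0),
                             "end": max(t + off, 0) + 1000,
                             "cells": "synthetic"})
                tgt.add(gid)
        tfs[str(tf)] = PeakSet(str(tf), pd.DataFrame(
            rows, columns=["chromosome", "start", "end", "cells"]))
        targets[str(tf)] = tgt
    truth.is_bivalent_in_control = bivalent
    truth.tf_targets = targets
    return marks, tfs


# ---------------------------------------------------------------------------
# packaged cohort table
# ---------------------------------------------------------------------------

def table1_fixture() -> pd.DataFrame:
    """The 56-patient cohort-characteristics table, packaged.

    A transcription of the study cohort's published characteristics
    (subtype, sex, blast rate, age, DNA index, gained chromosomes,
    risk group, relapse/death events, protocol era), parsed by the
    standard sample-table reader.
    """
    return read_sample_table(StringIO(_TABLE1_TSV))


_TABLE1_TSV = """\
Subtype\tID\tSex\tBlast Rate (%)\tAge (months)\tDNA Index\tKaryotype\tPrognostic Risk Group\tEvents\tDFCI Protocol
HHD\t315\tF\t98\t127\t1.12\t\tHigh\tR\t95-01
HHD\t327\tM\t98.5\t72\t1.13\t\tStandard\t\t95-01
HHD\t39\tM\t-\t49\t1.14\t\tStandard\t\t91-01
HHD\t442\tM\t95.5\t48\t1.12\t4,6,21,X\tHigh\t\t2000-01
HHD\t659\tM\t99.5\t35\t1.16\t2,4,6,10,14,18,21,X 3?\tHigh\tR\t2000-01
HHD\t670\tM\t92.5\t33\t1.2\t2,4,6,9,10,14,17,21,X\tHigh\tR\t2000-01
HHD\t777\tF\t89\t33\t1.15\t4,6,10,14,17,21\tHigh\t\t2005-01
HHD\t801\tM\t93\t48\t1.17\t4,6,8,10,14,17,18,21,X\tHigh\t\t2005-01
HHD\t813\tF\t74\t51\t1.18\t4,5,6,10,14,17,21,X\tStandard\t\t2005-01
HHD\t819\tM\t97\t48\t1.12\t4,6,14,21\tHigh\t\t2005-01
HHD\t826\tF\t50.2\t13\t1.25\t4,5,6,7,8,10,11,12,14,15,17,21,22\tStandard\t\t2005-01
Other\t399\tM\t96.5\t43\t1\t8,X\tStandard\tR,D\t95-01
Other\t41\tM\t-\t127\t1.07\t\tHigh\t\t91-01
Other\t419\tM\t93.5\t172\t1\tNone\tHigh\t\t2000-01
Other\t436\tF\t94.5\t99\t1\tNone\tStandard\t\t2000-01
Other\t446\tF\t90.5\t106\t-\tNone\tHigh\t\t2000-01
Other\t447\tF\t97.5\t129\t1\t21c\tHigh\tR,D\t2000-01
Other\t553\tM\t99.4\t81\t1\tNone\tStandard\t\t2000-01
Other\t579\tM\t95.5\t75\t1\tNone\tHigh\tR,D\t2000-01
Other\t580\tF\t97\t52\t1\t\tStandard\t\t2000-01
Other\t595\tM\t97\t155\t1\t5\tHigh\tR,D\t2000-01
Other\t596\tF\t96.5\t22\t1\tNone\tStandard\t\t2000-01
Other\t599\tM\t100\t88\t1\tNone\tHigh\t\t2000-01
Other\t608\tM\t83\t47\t1\tNone\tHigh\t\t2000-01
Other\t617\tF\t93\t46\t1\t\tStandard\t\t2000-01
Other\t720\tF\t94.5\t37\t1\tNone\tStandard\tR,D\t2005-01
Other\t756\tF\t92.5\t30\t1\tNone\tHigh\t\t2005-01
Other\t757\tF\t96.5\t127\t1\tNone\tHigh\t\t2005-01
Other\t794\tM\t100\t168\t1\t\tHigh\t\t2005-01
Other\t831\tF\t91\t187\t1\tX\tHigh\t\t2005-01
t(12;21)\t220\tM\t92.5\t69\t1\t\tHigh\t\t95-01
t(12;21)\t373\tF\t97.5\t55\t1\t\tHigh\t\t95-01
t(12;21)\t392\tM\t97\t84\t1\tNone\tStandard\t\t95-01
t(12;21)\t411\tF\t86.8\t57\t1\tNone\tStandard\t\t95-01
t(12;21)\t413\tF\t83.2\t40\t1\tNone\tStandard\t\t2000-01
t(12;21)\t420\tM\t97.5\t57\t1\t\tHigh\t\t2000-01
t(12;21)\t443\tF\t99.5\t32\t1\tNone\tHigh\t\t2000-01
t(12;21)\t5\tM\t-\t63\t1\t\tStandard\t\t91-01
t(12;21)\t614\tF\t96\t48\t1\tNone\tHigh\t\t2000-01
t(12;21)\t676\tF\t93\t43\t1\t\tStandard\t\t2000-01
t(12;21)\t691\tM\t97.5\t30\t1\t\tStandard\t\t2005-01
t(12;21)\t696\tF\t98\t51\t1\t\tVery High\t\t2005-01
t(12;21)\t73\tF\t-\t78\t1\t\tStandard\t\t95-01
t(12;21)\t732\tF\t96\t33\t1\tNone\tStandard\t\t2005-01
t(12;21)\t753\tF\t95\t61\t1\tNone\tStandard\t\t2005-01
t(12;21)\t814\tF\t93\t107\t1\tNone\tHigh\tR,D\t2005-01
t(12;21)\t817\tF\t93\t67\t1\tNone\tStandard\t\t2005-01
t(12;21)\t824\tM\t87\t66\t1\tNone\tStandard\t\t2005-01
t(12;21)\t827\tM\t76.5\t45\t1\t21\tHigh\t\t2005-01
t(12;21)\t832\tM\t98.5\t61\t1\t\tStandard\t\t2005-01
t(12;21)\t854\tF\t91.5\t31\t1\tNone\tStandard\t\t2005-01
t(12;21)\t856\tM\t92\t30\t1\tNone\tStandard\t\t2005-01
t(9;22)\t485\tM\t96.4\t77\t1\tNone\tHigh\tR,D\t2000-01
t(9;22)\t697\tM\t96\t113\t1\tNone\tHigh\tD\t2005-01
t(9;22)\t790\tM\t88.5\t171\t1\tNot enough information\tHigh\tR\t-
t(9;22)\t825\tF\t91\t138\t1\tNone\tHigh\t\t2005-01
"""
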