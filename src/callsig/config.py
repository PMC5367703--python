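"""Run configuration.

Every analysis threshold lives in :class:`RunConfig` so a run can be
reproduced from a single YAML file plus a seed.  Defaults are the values
used throughout the pipeline: a strict FDR of 1e-3 for differential
expression, a 4-fold rule for subtype specificity, 3-nearest-neighbour
classification on the 500 top-variance genes, and so on.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable

import yaml

#: Autosome names used throughout; the dosage analysis is autosome-only.
AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23))

#: Chromosome names accepted in karyotype strings.
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X", "Y")

#: Tumour subtypes, in canonical order.
SUBTYPES: tuple[str, ...] = ("HeH", "t(12;21)", "t(9;22)", "Other")

#: All sample groups (tumour subtypes plus the normal comparator).
GROUPS: tuple[str, ...] = SUBTYPES + ("Control",)


@dataclass
class RunConfig:
    """Thresholds and sizes shared by all pipeline stages.

    Parameters
    ----------
    seed
        Master seed; stage-specific child seeds are derived from it.
    fdr_de
        FDR cutoff for calling a gene differentially expressed (DET).
    fdr_enrich
        FDR cutoff for TF-peak and gene-set enrichment.
    logfc_updown
        |log2FC| required (in all subtypes) for the up/down categories
        used in the promoter-mark analysis.
    fdr_notde
        Genes whose FDR exceeds this in every subtype form the "not DE"
        background category.
    subtype_fold
        Linear fold change (focal subtype vs pooled others) for the
        subtype-specificity flag.
    knn_k
        Neighbours for leave-one-out KNN classification.
    n_top_mds
        Top-variance genes used for distance matrices / MDS.
    n_top_wgcna
        Top-variance genes entering co-expression module detection.
    replicates
        Gene-subsampling replicates for accuracy curves.
    gene_subsample_frac
        Fraction of eligible genes drawn per replicate.
    balanced_n
        Samples drawn per class in the class-balanced protocol.
    tss_window
        Flank (bp) on each side of the most upstream TSS.
    cpm_min_dosage
        CPM floor applied in both groups before dosage fold changes.
    heh_gained
        Autosomes frequently gained in high-hyperdiploid leukemia.
    prior_count
        Pseudo-count used when computing log-CPM.
    merge_dissimilarity
        Eigengene dissimilarity (1 - r) below which co-expression
        modules are merged.
    """

    seed: int = 0
    fdr_de: float = 1e-3
    fdr_enrich: float = 0.1
    logfc_updown: float = 2.0
    fdr_notde: float = 0.5
    subtype_fold: float = 4.0
    knn_k: int = 3
    n_top_mds: int = 500
    n_top_wgcna: int = 5000
    replicates: int = 100
    gene_subsample_frac: float = 0.5
    balanced_n: int = 4
    tss_window: int = 5000
    cpm_min_dosage: float = 30.0
    heh_gained: tuple = ("4", "6", "10", "14", "17", "18", "21")
    prior_count: float = 1.0
    merge_dissimilarity: float = 0.25

    def __post_init__(self) -> None:
        for name in ("fdr_de", "fdr_enrich", "fdr_notde", "gene_subsample_frac"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")
        for name in ("knn_k", "n_top_mds", "n_top_wgcna", "replicates",
                     "balanced_n", "tss_window"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        if self.prior_count < 0:
            raise ValueError("prior_count must be non-negative")
        self.heh_gained = tuple(str(c) for c in self.heh_gained)
        bad = set(self.heh_gained) - set(AUTOSOMES)
        if bad:
            raise ValueError(f"heh_gained must be autosome names; bad: {sorted(bad)}")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["heh_gained"] = list(self.heh_gained)
        return d

    def config_hash(self) -> str:
        """Stable hash of the configuration (for run manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
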