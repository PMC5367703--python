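"""Readers and writers for the on-disk formats the pipeline consumes.

In-memory containers are plain pandas objects with documented layouts:

* **counts** — ``DataFrame`` of integers, genes in rows (unique ids as
  index), samples in columns.
* **sample table** — ``DataFrame`` indexed by sample id with columns
  ``group, sex, blast_rate, age_months, dna_index, karyotype_gains,
  risk_group, events, batch``; ``karyotype_gains`` and ``events`` hold
  frozensets.
* **gene models** — ``DataFrame`` indexed by gene id with columns
  ``chromosome, start, end, strand, biotype, tss`` where ``start/end``
  follow BED semantics (0-based, half-open) and ``tss`` is a tuple of
  transcript 5' positions.  GTF input (1-based, closed) is converted to
  this convention on read.
* **peaks** — :class:`PeakSet`, a named collection of BED intervals.

All TSV outputs carry ``#``-prefixed metadata lines before the header.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CHROMOSOMES, GROUPS

log = logging.getLogger("callsig")

BIOTYPES = ("protein_coding", "lncRNA", "pseudogene", "other")

_SUBTYPE_ALIASES = {
    "heh": "HeH",
    "hhd": "HeH",  # the cohort table prints high hyperdiploidy as HHD
    "t(12;21)": "t(12;21)",
    "t(9;22)": "t(9;22)",
    "other": "Other",
    "control": "Control",
    "hcb": "Control",
}


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def read_counts(path, samples: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a gene x sample TSV of integer counts.

    First column holds gene ids, the header row sample ids.  Duplicate
    gene ids are rejected; if ``samples`` is given, the column set must
    match its index exactly.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.integer):
            as_float = pd.to_numeric(vals, errors="coerce")
            bad = vals.index[as_float.isna() | (as_float % 1 != 0)]
            if len(bad):
                raise ValueError(
                    f"non-integer count at row {bad[0]!r}, column {col!r}")
            df[col] = as_float.astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts are not allowed")
    if samples is not None:
        missing = set(samples.index) - set(df.columns)
        extra = set(df.columns) - set(samples.index)
        if missing or extra:
            raise ValueError(
                "count columns do not match sample metadata: "
                f"missing {sorted(missing)[:5]}, unexpected {sorted(extra)[:5]}")
        df = df[list(samples.index)]
    df.index.name = "gene"
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "subtype": "group", "group": "group",
    "id": "id", "sample": "id", "sample_id": "id",
    "sex": "sex",
    "blast_rate": "blast_rate", "blast_rate_pct": "blast_rate",
    "age_months": "age_months", "age": "age_months",
    "dna_index": "dna_index",
    "karyotype": "karyotype", "karyotype_gains": "karyotype",
    "risk_group": "risk_group", "prognostic_risk_group": "risk_group",
    "events": "events",
    "protocol": "batch", "dfci_protocol": "batch", "batch": "batch",
}


def _norm_header(name: str) -> str:
    key = re.sub(r"[^a-z0-9();,]+", "_", name.strip().lower()).strip("_")
    key = re.sub(r"_+", "_", key)
    key = re.sub(r"_?\(.*\)$", "", key)  # drop unit suffixes like "(%)"
    return key


def parse_karyotype(cell: str) -> frozenset:
    """Split a gained-chromosome cell into valid chromosome names.

    Cohort tables contain entries like ``"3?"``, ``"21c"`` or prose
    ("Not enough information"); such tokens are dropped with a warning
    rather than raising.
    """
    if cell is None:
        return frozenset()
    text = str(cell).strip()
    if text in ("", "-", "None", "nan"):
        return frozenset()
    tokens = [t for t in re.split(r"[,\s]+", text) if t]
    good, bad = [], []
    for tok in tokens:
        if tok in CHROMOSOMES:
            good.append(tok)
        else:
            bad.append(tok)
    if bad:
        log.warning("dropping unparseable karyotype tokens %s in %r", bad, text)
    return frozenset(good)


def read_sample_table(path) -> pd.DataFrame:
    """Read a cohort-characteristics TSV into a sample table.

    Expected columns mirror a clinical cohort table: subtype, id, sex,
    blast rate, age, DNA index, karyotype (comma-separated gained
    chromosomes), risk group, events (subset of R/D), protocol era.
    The protocol column doubles as the batch factor.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                      comment="#")
    cols = {}
    for c in raw.columns:
        key = _norm_header(c)
        if key in _COLUMN_ALIASES:
            cols[c] = _COLUMN_ALIASES[key]
    raw = raw.rename(columns=cols)
    if "id" not in raw.columns or "group" not in raw.columns:
        raise ValueError("sample table needs at least subtype and id columns")

    # subtype is often printed only on the first row of each block
    grp = raw["group"].replace("", np.nan).ffill()
    groups = []
    for g in grp:
        key = str(g).strip().lower()
        if key not in _SUBTYPE_ALIASES:
            raise ValueError(
                f"unknown subtype label {g!r}; accepted: "
                f"{sorted(set(_SUBTYPE_ALIASES.values()))}")
        groups.append(_SUBTYPE_ALIASES[key])

    def _num(col):
        if col not in raw.columns:
            return pd.Series(np.nan, index=raw.index)
        return pd.to_numeric(raw[col].replace({"-": np.nan, "": np.nan}),
                             errors="coerce")

    def _events(cell):
        toks = frozenset(t for t in re.split(r"[,\s]+", str(cell).strip()) if t)
        bad = toks - {"R", "D"}
        if bad:
            raise ValueError(f"unknown event codes {sorted(bad)}")
        return toks

    table = pd.DataFrame({
        "group": groups,
        "sex": [s if s in ("F", "M") else "unknown"
                for s in raw.get("sex", pd.Series("", index=raw.index))],
        "blast_rate": _num("blast_rate"),
        "age_months": _num("age_months"),
        "dna_index": _num("dna_index"),
        "karyotype_gains": [parse_karyotype(c) for c in
                            raw.get("karyotype", pd.Series("", index=raw.index))],
        "risk_group": raw.get("risk_group", pd.Series("", index=raw.index)),
        "events": [_events(c) for c in
                   raw.get("events", pd.Series("", index=raw.index))],
        "batch": raw.get("batch", pd.Series("", index=raw.index)),
    }, index=pd.Index([str(i).strip() for i in raw["id"]], name="id"))

    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    ctrl = table["group"] == "Control"
    if any(len(k) for k in table.loc[ctrl, "karyotype_gains"]):
        raise ValueError("Control samples must have empty karyotype gains")
    if (table["dna_index"].dropna() <= 0).any():
        raise ValueError("DNA index must be positive where present")
    return table


def write_sample_table(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out["karyotype_gains"] = [
        ",".join(sorted(k, key=_chrom_key)) for k in out["karyotype_gains"]]
    out["events"] = [",".join(sorted(e)) for e in out["events"]]
    out.to_csv(path, sep="\t", index_label="id")


def _chrom_key(c: str):
    return (0, int(c)) if c.isdigit() else (1, c)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(path) -> pd.DataFrame:
    """Read gene models from GTF or from the package's BED-like dialect.

    The BED dialect has columns ``chrom start end gene_id score strand
    biotype tss`` with ``tss`` a comma-separated position list (see
    README).  GTF gene records must carry a ``gene_biotype`` (or
    ``biotype``) attribute; records without one are classified "other".
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _read_gtf(path)
    return _read_gene_bed(path)


def _read_gene_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chromosome", "start", "end", "gene", "score",
                            "strand", "biotype", "tss"],
                     dtype={"chromosome": str})
    df["tss"] = [tuple(int(x) for x in str(t).split(",")) for t in df["tss"]]
    df = df.drop(columns="score").set_index("gene")
    return _validate_gene_models(df)


def _read_gtf(path) -> pd.DataFrame:
    genes: dict[str, dict] = {}
    tss: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"malformed GTF line: {line[:80]!r}")
            chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
            att = dict(re.findall(r'(\w+) "([^"]*)"', attrs))
            gid = att.get("gene_id")
            if gid is None:
                raise ValueError("GTF record without gene_id")
            start0, end0 = int(start) - 1, int(end)  # to 0-based half-open
            if feature == "gene":
                biotype = att.get("gene_biotype", att.get("biotype"))
                if biotype is None:
                    log.warning("gene %s has no biotype; classifying 'other'", gid)
                    biotype = "other"
                elif biotype not in BIOTYPES:
                    biotype = "other"
                genes[gid] = {"chromosome": str(chrom), "start": start0,
                              "end": end0, "strand": strand, "biotype": biotype}
            elif feature == "transcript":
                tss.setdefault(gid, set()).add(end0 - 1 if strand == "-" else start0)
    rows = {}
    for gid, rec in genes.items():
        sites = tss.get(gid)
        if not sites:  # fall back to the gene's own 5' end
            sites = {rec["end"] - 1 if rec["strand"] == "-" else rec["start"]}
        rows[gid] = {**rec, "tss": tuple(sorted(sites))}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene"
    return _validate_gene_models(df)


def _validate_gene_models(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        raise ValueError("duplicate gene ids in gene models")
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"gene {bad}: body start must be < end")
    if (df["start"] < 0).any():
        raise ValueError("negative coordinates in gene models")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be '+' or '-'")
    if any(len(t) == 0 for t in df["tss"]):
        raise ValueError("every gene needs at least one TSS")
    return df[["chromosome", "start", "end", "strand", "biotype", "tss"]]


def write_gene_models(genes: pd.DataFrame, path) -> None:
    """Write gene models in the BED-like dialect (see read_gene_models)."""
    with open(path, "w") as fh:
        for gid, r in genes.iterrows():
            tss = ",".join(str(t) for t in r["tss"])
            fh.write(f"{r['chromosome']}\t{r['start']}\t{r['end']}\t{gid}"
                     f"\t0\t{r['strand']}\t{r['biotype']}\t{tss}\n")


def write_gtf(genes: pd.DataFrame, path) -> None:
    """Write gene models as a minimal GTF (gene + one transcript per TSS)."""
    with open(path, "w") as fh:
        for gid, r in genes.iterrows():
            s1, e1 = r["start"] + 1, r["end"]  # back to 1-based closed
            attrs = f'gene_id "{gid}"; gene_biotype "{r["biotype"]}";'
            fh.write(f"{r['chromosome']}\tcallsig\tgene\t{s1}\t{e1}\t.\t"
                     f"{r['strand']}\t.\t{attrs}\n")
            for i, t in enumerate(r["tss"]):
                if r["strand"] == "+":
                    ts1, te1 = t + 1, e1
                else:
                    ts1, te1 = s1, t + 1
                fh.write(f"{r['chromosome']}\tcallsig\ttranscript\t{ts1}\t{te1}"
                         f"\t.\t{r['strand']}\t.\t{attrs} "
                         f'transcript_id "{gid}.t{i}";\n')


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """Named set of genomic intervals with BED semantics.

    Intervals are kept sorted by (chromosome, start).  ``cells`` carries
    optional per-interval cell-type annotations (comma-joined string),
    mirroring clustered TF-peak layouts.
    """

    name: str
    intervals: pd.DataFrame  # columns: chromosome, start, end [, cells]

    def __post_init__(self):
        df = self.intervals
        need = {"chromosome", "start", "end"}
        if not need <= set(df.columns):
            raise ValueError(f"PeakSet needs columns {sorted(need)}")
        if (df["start"] >= df["end"]).any():
            raise ValueError(f"PeakSet {self.name}: start must be < end")
        if (df["start"] < 0).any():
            raise ValueError(f"PeakSet {self.name}: negative coordinate")
        self.intervals = (df.assign(chromosome=df["chromosome"].astype(str))
                          .sort_values(["chromosome", "start", "end"],
                                       kind="mergesort")
                          .reset_index(drop=True))

    def __len__(self):
        return len(self.intervals)


def read_peaks(path, name: str | None = None) -> PeakSet:
    """Read a BED file (3+ columns) into a PeakSet.

    Column 4, when present, is a name field; column 5 a comma-separated
    cell-type list (clustered TF-peak dialect).
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            rec = {"chromosome": f[0], "start": int(f[1]), "end": int(f[2])}
            if len(f) > 4:
                rec["cells"] = f[4]
            rows.append(rec)
    df = pd.DataFrame(rows, columns=["chromosome", "start", "end", "cells"]
                      if rows and "cells" in rows[0] else
                      ["chromosome", "start", "end"])
    return PeakSet(name or Path(path).stem, df)


def write_peaks(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for _, r in peaks.intervals.iterrows():
            cols = [str(r["chromosome"]), str(r["start"]), str(r["end"]),
                    peaks.name]
            if "cells" in peaks.intervals.columns:
                cols.append(str(r["cells"]))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------

def read_de_table(path) -> pd.DataFrame:
    """Read a long-form DE table TSV (gene, contrast, log2fc, pvalue, fdr).

    External two-column-style tables (gene, log2fc, fdr) are accepted
    for cross-dataset comparisons; a missing contrast column is filled
    with 'external'.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str})
    if "contrast" not in df.columns:
        df["contrast"] = "external"
    for col in ("gene", "log2fc", "fdr"):
        if col not in df.columns:
            raise ValueError(f"DE table {path} lacks column {col!r}")
    return df


def write_de_table(de: pd.DataFrame, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        de.to_csv(fh, sep="\t", index=False)
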