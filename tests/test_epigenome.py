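"""Interval arithmetic, promoter windows, bivalency and TF enrichment."""
from math import comb

import numpy as np
import pandas as pd
import pytest

from callsig import epigenome
from callsig.io import PeakSet


def _genes(rows):
    return pd.DataFrame(rows).set_index("gene")


def _peaks(name, triples):
    return PeakSet(name, pd.DataFrame(
        [{"chromosome": c, "start": s, "end": e} for c, s, e in triples]))


# ---------------------------------------------------------------------------
# TSS windows
# ---------------------------------------------------------------------------

def test_tss_window_clipping_and_strand():
    genes = _genes([
        {"gene": "plus", "chromosome": "1", "start": 100, "end": 5000,
         "strand": "+", "biotype": "protein_coding", "tss": (100, 150)},
        {"gene": "minus", "chromosome": "1", "start": 100, "end": 200,
         "strand": "-", "biotype": "protein_coding", "tss": (100, 150)},
    ])
    win = epigenome.tss_windows(genes, flank=5000)
    # + strand: most upstream TSS is 100; window clipped at 0
    assert win.loc["plus", "start"] == 0 and win.loc["plus", "end"] == 5100
    # - strand: most upstream TSS is the largest coordinate
    assert win.loc["minus", "tss"] == 150
    with pytest.raises(ValueError, match="flank"):
        epigenome.tss_windows(genes, flank=0)


# ---------------------------------------------------------------------------
# overlaps
# ---------------------------------------------------------------------------

def test_overlap_half_open_boundaries():
    peaks = _peaks("p", [("1", 10, 20)])
    q = pd.DataFrame({"chromosome": ["1", "1", "1", "2"],
                      "start": [0, 9, 20, 10], "end": [10, 20, 30, 20]})
    out = epigenome.overlaps(q, peaks)
    assert list(out) == [False, True, False, False]


def brute_force_overlaps(q, pk):
    out = []
    for _, a in q.iterrows():
        hit = False
        for _, b in pk.iterrows():
            if (a["chromosome"] == b["chromosome"]
                    and a["start"] < b["end"] and b["start"] < a["end"]):
                hit = True
                break
        out.append(hit)
    return np.array(out)


def test_overlaps_matches_brute_force(rng):
    for _ in range(25):
        npk, nq = rng.integers(1, 30), rng.integers(1, 30)
        pk = pd.DataFrame({
            "chromosome": rng.choice(["1", "2"], npk),
            "start": rng.integers(0, 500, npk)})
        pk["end"] = pk["start"] + rng.integers(1, 80, npk)
        q = pd.DataFrame({
            "chromosome": rng.choice(["1", "2"], nq),
            "start": rng.integers(0, 500, nq)})
        q["end"] = q["start"] + rng.integers(1, 80, nq)
        fast = epigenome.overlaps(q, PeakSet("r", pk))
        assert np.array_equal(fast.to_numpy(), brute_force_overlaps(q, pk))


def test_overlaps_input_order_irrelevant(rng):
    pk = pd.DataFrame({"chromosome": ["1"] * 6,
                       "start": [50, 10, 90, 30, 70, 0]})
    pk["end"] = pk["start"] + 15
    q = pd.DataFrame({"chromosome": ["1"] * 4,
                      "start": [5, 40, 60, 200], "end": [8, 45, 100, 300]})
    a = epigenome.overlaps(q, PeakSet("a", pk))
    b = epigenome.overlaps(q, PeakSet("b", pk.iloc[::-1].reset_index(
        drop=True)))
    assert (a == b).all()


def test_overlaps_rejects_malformed():
    with pytest.raises(ValueError):
        epigenome.overlaps(pd.DataFrame({"chromosome": ["1"], "start": [5],
                                         "end": [5]}),
                           _peaks("p", [("1", 0, 10)]))


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

def test_metagene_profile_extremes_and_central_bin():
    win = pd.DataFrame({"chromosome": ["1", "1"], "start": [0, 1000],
                        "end": [500, 1500]})
    full = _peaks("full", [("1", 0, 2000)])
    assert np.allclose(epigenome.metagene_profile(full, win, bins=5), 1.0)
    empty = _peaks("none", [("2", 0, 2000)])
    assert np.allclose(epigenome.metagene_profile(empty, win, bins=5), 0.0)
    # a peak covering exactly the central fifth of each window
    central = _peaks("mid", [("1", 200, 300), ("1", 1200, 1300)])
    prof = epigenome.metagene_profile(central, win, bins=5)
    assert np.allclose(prof, [0, 0, 1, 0, 0])


# ---------------------------------------------------------------------------
# bivalency
# ---------------------------------------------------------------------------

def test_bivalency_hand_counts():
    genes = _genes([
        {"gene": g, "chromosome": "1", "start": i * 100_000,
         "end": i * 100_000 + 1_000, "strand": "+",
         "biotype": "protein_coding", "tss": (i * 100_000,)}
        for i, g in enumerate(["u1", "u2", "n1", "n2"])])
    win = epigenome.tss_windows(genes, flank=5000)
    k27 = _peaks("k27", [("1", 0, 100), ("1", 100_000, 100_100),
                         ("1", 200_000, 200_100)])
    k4 = _peaks("k4", [("1", 0, 100), ("1", 100_000, 100_100),
                       ("1", 200_000, 200_100)])
    cat = pd.Series(["up", "up", "not_de", "not_de"],
                    index=["u1", "u2", "n1", "n2"])
    out = epigenome.bivalency_fractions(k27, k4, win, cat)
    assert out.loc["up", "frac_bivalent"] == 1.0
    assert out.loc["not_de", "frac_bivalent"] == 0.5
    assert out.attrs["fold_up_vs_notde"] == pytest.approx(2.0)


def test_bivalency_all_marked_gives_fold_one():
    genes = _genes([
        {"gene": f"g{i}", "chromosome": "1", "start": i * 50_000,
         "end": i * 50_000 + 1_000, "strand": "+",
         "biotype": "protein_coding", "tss": (i * 50_000,)}
        for i in range(4)])
    win = epigenome.tss_windows(genes, flank=1000)
    peaks = _peaks("m", [("1", i * 50_000, i * 50_000 + 10) for i in range(4)])
    cat = pd.Series(["up", "up", "not_de", "not_de"], index=genes.index)
    out = epigenome.bivalency_fractions(peaks, peaks, win, cat)
    assert (out["frac_bivalent"] == 1.0).all()
    assert out.attrs["fold_up_vs_notde"] == pytest.approx(1.0)


def test_bivalency_unaffected_by_peak_order(rng):
    genes = _genes([
        {"gene": f"g{i}", "chromosome": "1", "start": i * 50_000,
         "end": i * 50_000 + 1_000, "strand": "+",
         "biotype": "protein_coding", "tss": (i * 50_000,)}
        for i in range(6)])
    win = epigenome.tss_windows(genes, flank=2000)
    triples = [("1", int(s), int(s) + 500)
               for s in rng.integers(0, 300_000, 12)]
    cat = pd.Series(["up", "up", "up", "not_de", "not_de", "not_de"],
                    index=genes.index)
    a = epigenome.bivalency_fractions(_peaks("a", triples),
                                      _peaks("a", triples[::-1]), win, cat)
    b = epigenome.bivalency_fractions(_peaks("b", triples[::-1]),
                                      _peaks("b", triples), win, cat)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def enumerate_upper_tail(k, N, K, n):
    """Exhaustive hypergeometric upper tail by enumerating draws."""
    total = comb(N, n)
    favourable = sum(
        comb(K, x) * comb(N - K, n - x)
        for x in range(k, min(K, n) + 1))
    return favourable / total


def test_hypergeom_worked_example():
    # universe 10, background hits 5, targets 4, all 4 hit
    p = epigenome.hypergeom_upper(4, 10, 5, 4)
    assert p == pytest.approx(5 / 210, rel=1e-9)


@pytest.mark.parametrize("N", [5, 8, 12])
def test_hypergeom_matches_enumeration(N, rng):
    for _ in range(30):
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(0, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        assert epigenome.hypergeom_upper(k, N, K, n) == pytest.approx(
            enumerate_upper_tail(k, N, K, n), abs=1e-12)


def _tf_setup():
    genes = _genes([
        {"gene": f"g{i}", "chromosome": "1", "start": i * 100_000,
         "end": i * 100_000 + 1_000, "strand": "+",
         "biotype": "protein_coding", "tss": (i * 100_000,)}
        for i in range(10)])
    win = epigenome.tss_windows(genes, flank=1000)
    hits = [f"g{i}" for i in range(5)]  # TF binds genes 0-4
    peaks = _peaks("g9", [("1", int(g[1]) * 100_000, int(g[1]) * 100_000 + 10)
                          for g in hits])
    de = pd.DataFrame({
        "gene": [f"g{i}" for i in range(10)] * 1,
        "contrast": "HeH",
        "log2fc": np.linspace(-1, 1, 10),
        "fdr": [0.01] * 10,
    })
    return genes, win, peaks, de


def test_tf_enrichment_worked_example():
    genes, win, peaks, de = _tf_setup()
    background = {f"g{i}" for i in range(10)}
    targets = {f"g{i}" for i in range(4)}  # all 4 targets are bound
    out = epigenome.tf_enrichment({"g9": peaks}, win, targets, background, de)
    row = out.loc["g9"]
    assert row["pvalue"] == pytest.approx(5 / 210, rel=1e-9)
    assert row["ratio"] == pytest.approx((4 / 4) / (5 / 10))
    assert row["min_subtype_log2fc"] == pytest.approx(1.0)


def test_tf_enrichment_targets_equal_background():
    genes, win, peaks, de = _tf_setup()
    background = {f"g{i}" for i in range(10)}
    out = epigenome.tf_enrichment({"g9": peaks}, win, background,
                                  background, de)
    assert out.loc["g9", "ratio"] == pytest.approx(1.0)
    assert out.loc["g9", "pvalue"] == pytest.approx(1.0)


def test_tf_missing_from_de_kept_but_not_significant():
    genes, win, peaks, de = _tf_setup()
    background = {f"g{i}" for i in range(10)}
    targets = {f"g{i}" for i in range(4)}
    out = epigenome.tf_enrichment({"absent": peaks}, win, targets,
                                  background, de)
    assert np.isnan(out.loc["absent", "min_subtype_log2fc"])
    assert not out.loc["absent", "significant"]


def test_tf_targets_must_be_subset():
    genes, win, peaks, de = _tf_setup()
    with pytest.raises(ValueError, match="subset"):
        epigenome.tf_enrichment({"g9": peaks}, win, {"zz"}, {"g1"}, de)
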