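"""NB-GLM differential expression, FDR, calls, scores, comparisons."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from callsig import diffexp, glm
from callsig.config import SUBTYPES
from conftest import two_group_counts


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def test_single_group_fit_recovers_means():
    counts, samples = two_group_counts(seed=1, n_genes=60, n_per_group=8)
    samples["group"] = "Control"
    m = diffexp.fit_nb_glm(counts, samples)
    # intercept-only design: fitted rate = normalised mean
    assert m.design.shape[1] == 1
    rate = np.exp(m.beta[:, 0])
    obs = (counts.loc[m.genes].to_numpy()
           / np.exp(m.offset)[None, :]).mean(axis=1)
    assert np.allclose(rate, obs, rtol=0.05)


def test_coefficients_match_statsmodels_oracle():
    """Per-gene IRLS agrees with an independent GLM implementation."""
    sm = pytest.importorskip("statsmodels.api")
    counts, samples = two_group_counts(seed=2, n_genes=25, n_per_group=6)
    m = diffexp.fit_nb_glm(counts, samples, min_samples=1)
    X, off = m.design, m.offset
    for i in range(0, len(m.genes), 5):
        res = sm.GLM(m.counts[i], X,
                     family=sm.families.NegativeBinomial(
                         alpha=m.dispersion[i]),
                     offset=off).fit()
        assert np.allclose(m.beta[i], res.params, atol=1e-4)


def test_poisson_limit_consistency():
    """Exact 4x planted ratio, tiny dispersion -> log2FC estimate ~2.

    The planted genes carry a negligible share of the library so the
    estimate is not confounded by composition.
    """
    lfc = np.zeros(800)
    lfc[:10] = 2.0
    counts, samples = two_group_counts(seed=3, n_genes=800, n_per_group=40,
                                       phi=1e-4, lfc=lfc)
    m = diffexp.fit_nb_glm(counts, samples)
    est = m.coef_log2fc("HeH")
    planted = est.index[est.index.isin([f"G{i:04d}" for i in range(10)])]
    assert est[planted].mean() == pytest.approx(2.0, abs=0.05)


def test_lfc_recovery_slope_near_one():
    grid = np.array([-3, -2, -1, 0, 1, 2, 3], float)
    lfc = np.zeros(1200)
    rng = np.random.default_rng(5)
    idx = rng.choice(1200, size=70, replace=False)
    for i, level in enumerate(grid):
        lfc[idx[i * 10:(i + 1) * 10]] = level
    counts, samples = two_group_counts(seed=5, n_genes=1200, n_per_group=20,
                                       lfc=lfc)
    m = diffexp.fit_nb_glm(counts, samples)
    est = m.coef_log2fc("HeH")
    planted = pd.Series(lfc, index=counts.index).loc[m.genes]
    slope = np.polyfit(planted, est, 1)[0]
    assert slope == pytest.approx(1.0, abs=0.05)


def test_rank_deficient_design_names_alias():
    counts, samples = two_group_counts(seed=6, n_genes=20, n_per_group=4)
    samples["batch"] = np.where(samples["group"] == "HeH", "B2", "B1")
    with pytest.raises(ValueError, match="aliased.*batch:B2"):
        diffexp.fit_nb_glm(counts, samples)


def test_missing_contrast_errors(fitted):
    with pytest.raises(ValueError, match="t\\(1;19\\)"):
        diffexp.lrt_test(fitted, "t(1;19)")


# ---------------------------------------------------------------------------
# calibration and power
# ---------------------------------------------------------------------------

def test_null_pvalues_approximately_uniform():
    counts, samples = two_group_counts(seed=11, n_genes=1500, n_per_group=15)
    m = diffexp.fit_nb_glm(counts, samples)
    de = diffexp.lrt_test(m, "HeH")
    p = de["pvalue"].dropna()
    assert stats.kstest(p, "uniform").pvalue > 0.01
    assert (de["fdr"] <= 1e-3).mean() <= 2e-3


def test_strong_planted_gene_has_tiny_pvalue():
    lfc = np.zeros(300)
    lfc[0] = 3.0
    counts, samples = two_group_counts(seed=12, n_genes=300, n_per_group=12,
                                       lfc=lfc)
    m = diffexp.fit_nb_glm(counts, samples)
    de = diffexp.lrt_test(m, "HeH").set_index("gene")
    assert de.loc["G0000", "pvalue"] < 1e-6


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def test_bh_single_and_hand_stepup():
    assert diffexp.bh_fdr([0.03])[0] == pytest.approx(0.03)
    out = diffexp.bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests
    p = rng.uniform(size=200)
    ours = diffexp.bh_fdr(p)
    ref = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(ours, ref)


def test_bh_monotone_and_validates(rng):
    p = np.sort(rng.uniform(size=50))
    fdr = diffexp.bh_fdr(p)
    assert (np.diff(fdr) >= -1e-12).all()
    assert (fdr >= p).all()
    with pytest.raises(ValueError):
        diffexp.bh_fdr([1.2])
    out = diffexp.bh_fdr([0.1, np.nan, 0.5])
    assert np.isnan(out[1]) and not np.isnan(out[0])


# ---------------------------------------------------------------------------
# dysregulation calls
# ---------------------------------------------------------------------------

def _toy_de(rows):
    recs = []
    for gene, per_subtype in rows.items():
        for s, (lfc, fdr) in zip(SUBTYPES, per_subtype):
            recs.append({"gene": gene, "contrast": s, "log2fc": lfc,
                         "pvalue": fdr, "fdr": fdr, "mean_logcpm": 5.0})
    return pd.DataFrame(recs)


def test_call_dysregulation_examples():
    de = _toy_de({
        "up_all": [(3, 1e-4)] * 4,
        "heh_only": [(2, 1e-4), (0.1, 0.9), (0.1, 0.9), (0.1, 0.9)],
        "quiet": [(0.0, 0.9)] * 4,
        "mixed": [(3, 1e-4), (-3, 1e-4), (3, 1e-4), (3, 1e-4)],
    })
    calls = diffexp.call_dysregulation(de)
    assert calls.loc["up_all", "leukemia_status"] == "up"
    assert calls.loc["up_all", "fig_category"] == "up"
    assert calls.loc["heh_only", "specific_subtype"] == "HeH"
    assert calls.loc["quiet", "fig_category"] == "not_de"
    assert calls.loc["mixed", "leukemia_status"] == "mixed"
    assert not calls.loc["quiet", "is_det"]


def test_call_dysregulation_order_invariant():
    de = _toy_de({"a": [(3, 1e-4)] * 4, "b": [(0, 0.9)] * 4})
    shuffled = de.sample(frac=1.0, random_state=0).reset_index(drop=True)
    a = diffexp.call_dysregulation(de).sort_index()
    b = diffexp.call_dysregulation(shuffled).sort_index()
    pd.testing.assert_frame_equal(a, b)


def test_call_dysregulation_missing_contrast():
    de = _toy_de({"a": [(3, 1e-4)] * 4})
    with pytest.raises(ValueError, match="missing contrasts"):
        diffexp.call_dysregulation(de[de["contrast"] != "HeH"])


def test_calls_recover_planted_categories(fitted, de_table, default_cohort):
    counts, samples, genes, truth = default_cohort
    calls = diffexp.call_dysregulation(de_table)
    tg = truth.genes.loc[fitted.genes]
    # concordance in all four contrasts needs adequate power everywhere,
    # so recovery is asserted on the strongly planted genes
    strong = tg["lfc_HeH"].abs() >= 2
    up = tg.index[(tg["category"] == "leukemia_up") & strong]
    down = tg.index[(tg["category"] == "leukemia_down") & strong]
    assert (calls.loc[up, "leukemia_status"] == "up").mean() > 0.9
    assert (calls.loc[down, "leukemia_status"] == "down").mean() > 0.9
    for s in SUBTYPES:
        spec = tg.index[(tg["category"] == f"specific({s})")
                        & (tg[f"lfc_{s}"].abs() >= 2)]
        assert (calls.loc[spec, "specific_subtype"] == s).mean() > 0.8


# ---------------------------------------------------------------------------
# specificity scores
# ---------------------------------------------------------------------------

def _expr_with_group_means(means):
    """One gene; two samples per subtype at the given means."""
    cols, vals, groups = [], [], []
    for s, mu in means.items():
        for r in range(2):
            cols.append(f"{s}_{r}")
            vals.append(mu)
            groups.append(s)
    expr = pd.DataFrame([vals], index=["g"], columns=cols)
    samples = pd.DataFrame({"group": groups, "batch": "B1"}, index=cols)
    return expr, samples


def test_specificity_score_hand_example():
    expr, samples = _expr_with_group_means(
        {"HeH": 10.0, "t(12;21)": 2.0, "t(9;22)": 3.0, "Other": 3.0})
    out = diffexp.specificity_score(expr, samples)
    # closest other subtype to HeH has mean 3 -> score 7
    assert out.loc["g", ("HeH", "score")] == pytest.approx(7.0)
    # pooled others mean (2+3+3)/3 = 2.667 -> |diff| = 7.33 >= 2 -> flagged
    assert bool(out.loc["g", ("HeH", "fourfold")])


def test_specificity_score_flat_and_threshold():
    expr, samples = _expr_with_group_means(
        {"HeH": 5.0, "t(12;21)": 5.0, "t(9;22)": 5.0, "Other": 5.0})
    out = diffexp.specificity_score(expr, samples)
    assert out.loc["g", ("HeH", "score")] == pytest.approx(0.0)
    assert not bool(out.loc["g", ("HeH", "fourfold")])
    expr2, samples2 = _expr_with_group_means(
        {"HeH": 10.0, "t(12;21)": 8.1, "t(9;22)": 8.1, "Other": 8.1})
    out2 = diffexp.specificity_score(expr2, samples2)
    assert not bool(out2.loc["g", ("HeH", "fourfold")])  # 1.9 < 2


# ---------------------------------------------------------------------------
# cross-dataset comparison and odds ratios
# ---------------------------------------------------------------------------

def test_compare_identical_tables():
    de = pd.DataFrame({"gene": [f"g{i}" for i in range(50)],
                       "log2fc": np.linspace(-2, 2, 50),
                       "fdr": [1e-4] * 10 + [0.5] * 40})
    rep = diffexp.compare_de_tables(de, de, threshold=1e-3)
    assert rep["n_overlap"] == rep["n_sig_a"] == 10
    assert rep["pearson_r"] == pytest.approx(1.0)
    assert rep["sign_concordance"] == 1.0


def test_compare_expected_overlap_formula_and_monte_carlo(rng):
    N, nA, nB = 100, 10, 20
    genes = [f"g{i}" for i in range(N)]
    obs = []
    for _ in range(300):
        sa = set(rng.choice(genes, nA, replace=False))
        sb = set(rng.choice(genes, nB, replace=False))
        da = pd.DataFrame({"gene": genes, "log2fc": 1.0,
                           "fdr": [1e-4 if g in sa else 0.5 for g in genes]})
        db = pd.DataFrame({"gene": genes, "log2fc": 1.0,
                           "fdr": [1e-4 if g in sb else 0.5 for g in genes]})
        rep = diffexp.compare_de_tables(da, db)
        assert rep["expected_overlap"] == pytest.approx(nA * nB / N)
        obs.append(rep["n_overlap"])
    assert np.mean(obs) == pytest.approx(nA * nB / N, abs=0.25)


def test_odds_ratio_hand_examples():
    odds, _ = diffexp.odds_ratio_2x2(2, 8, 1, 9)
    assert odds == pytest.approx(2.25)
    odds_eq, _ = diffexp.odds_ratio_2x2(3, 12, 5, 20)  # a/b == c/d
    assert odds_eq == pytest.approx(1.0)
    with pytest.raises(ValueError, match="margin"):
        diffexp.odds_ratio_2x2(0, 0, 3, 4)


def test_biotype_specificity_odds_on_synthetic(fitted, de_table,
                                               default_cohort):
    counts, samples, genes, truth = default_cohort
    calls = diffexp.call_dysregulation(de_table)
    rep = diffexp.biotype_specificity_odds(calls, genes)
    t = rep["table"]
    assert t["a"] + t["b"] + t["c"] + t["d"] == int(calls["is_det"].sum())
    assert rep["odds_ratio"] > 0
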