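"""Age/sex trend statistics: OLS, F-tests, BH, BIC, stepwise, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plexquant.simulate import CohortSpec, protein_matrix_from_peptides, simulate_cohort
from plexquant.trends import (
    NOT_CATEGORIZED,
    TrendConfig,
    analyze_matrix,
    bh_adjust,
    classify_age_model,
    cross_tissue_analysis,
    cross_tissue_test,
    f_test,
    fit_protein_model,
    hypergeom_overrep,
    overrepresentation_table,
    read_gmt,
    stepwise_trend,
)


def make_design(ages=(3.0, 12.0, 20.0), sexes=("F", "M"), reps=3, tissues=("t1",)):
    rows = []
    for tissue in tissues:
        for age, sex, rep in itertools.product(ages, sexes, range(reps)):
            rows.append(
                {
                    "sample_id": f"{tissue}_{age:g}_{sex}_{rep}",
                    "age_months": age,
                    "sex": sex,
                    "tissue": tissue,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


DESIGN = make_design()


# ---------------------------------------------------------------------------
# OLS fits


def test_exact_interpolation_recovers_coefficients():
    age = DESIGN["age_months"].to_numpy()
    male = (DESIGN["sex"] == "M").to_numpy(float)
    y = 0.1 * age + 0.5 * male
    fit = fit_protein_model(y, DESIGN, "continuous", ("age", "sex"))
    params = fit.params()
    assert params["age"] == pytest.approx(0.1, abs=1e-10)
    assert params["sex[M]"] == pytest.approx(0.5, abs=1e-10)
    assert fit.rss == pytest.approx(0.0, abs=1e-18)


def test_fit_matches_statsmodels_oracle():
    """Independent route: statsmodels OLS on the same toy data."""
    import statsmodels.api as sm

    rng = np.random.default_rng(0)
    design = make_design(reps=1)  # 6 samples
    y = rng.normal(size=len(design))
    fit = fit_protein_model(y, design, "continuous", ("age", "sex"))
    X = sm.add_constant(
        np.column_stack(
            [design["age_months"], (design["sex"] == "M").astype(float)]
        )
    )
    ref = sm.OLS(y, X).fit()
    np.testing.assert_allclose(fit.coef, ref.params, atol=1e-10)
    assert fit.rss == pytest.approx(ref.ssr, abs=1e-10)


def test_fit_order_invariance():
    rng = np.random.default_rng(1)
    y = rng.normal(size=len(DESIGN))
    fit = fit_protein_model(y, DESIGN, "categorical", ("age", "sex"))
    perm = rng.permutation(len(DESIGN))
    fit_p = fit_protein_model(
        y[perm], DESIGN.iloc[perm].reset_index(drop=True), "categorical", ("age", "sex")
    )
    np.testing.assert_allclose(fit.coef, fit_p.coef, atol=1e-10)
    assert fit.rss == pytest.approx(fit_p.rss)


def test_rank_deficient_design_rejected():
    design = make_design(sexes=("F",))
    y = np.zeros(len(design))
    with pytest.raises(ValueError, match="rank-deficient"):
        fit_protein_model(y, design, "continuous", ("age", "sex"))


def test_misaligned_and_missing_y():
    with pytest.raises(ValueError):
        fit_protein_model(np.zeros(5), DESIGN)
    y = np.zeros(len(DESIGN))
    y[0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit_protein_model(y, DESIGN)


# ---------------------------------------------------------------------------
# F-tests


def test_f_test_matches_statsmodels_anova():
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    y = rng.normal(size=len(DESIGN)) + 0.05 * DESIGN["age_months"].to_numpy()
    full = fit_protein_model(y, DESIGN, "continuous", ("age", "sex"))
    null = fit_protein_model(y, DESIGN, "continuous", ("sex",))
    p = f_test(full, null)
    X_full = sm.add_constant(
        np.column_stack(
            [DESIGN["age_months"], (DESIGN["sex"] == "M").astype(float)]
        )
    )
    ref = sm.OLS(y, X_full).fit()
    # age is column 1; single-restriction F test
    p_ref = float(ref.f_test("x1 = 0").pvalue)
    assert p == pytest.approx(p_ref, abs=1e-12)


def test_f_test_rejects_non_nested_and_saturated():
    y = np.random.default_rng(3).normal(size=len(DESIGN))
    full = fit_protein_model(y, DESIGN, "continuous", ("age", "sex"))
    with pytest.raises(ValueError):
        f_test(full, full)
    null_big = fit_protein_model(y, DESIGN, "categorical", ("age", "sex"))
    with pytest.raises(ValueError):
        f_test(full, null_big)  # "null" has more parameters


def test_type_one_error_calibration():
    """Null simulation: 10,000 proteins with no age effect; the age
    F-test rejects at ~5% and its p-values are ~uniform."""
    rng = np.random.default_rng(12345)
    Y = rng.normal(size=(10000, len(DESIGN)))
    matrix = pd.DataFrame(Y, columns=DESIGN["sample_id"])
    res = analyze_matrix(matrix, DESIGN)
    frac = float((res["p_age"] < 0.05).mean())
    assert 0.04 <= frac <= 0.06
    sorted_p = np.sort(res["p_age"].to_numpy())
    ks = np.max(np.abs(sorted_p - np.arange(1, 10001) / 10000))
    assert ks < 0.02


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_hand_computed_examples():
    assert bh_adjust([0.04]) == pytest.approx([0.04])
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    # step-up with distinct values: (0.01, 0.04, 0.03) ->
    # sorted (0.01*3/1, 0.03*3/2, 0.04*3/3) -> monotone (0.03, 0.04, 0.045)?
    # no: 0.01*3=0.03, 0.03*1.5=0.045, 0.04*1=0.04 -> enforce monotone from
    # largest: (0.03, 0.04, 0.04) mapped back to input order
    np.testing.assert_allclose(bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])


def test_bh_rejects_out_of_range():
    for bad in ([-0.1], [1.5], [np.nan]):
        with pytest.raises(ValueError):
            bh_adjust(bad)


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_bh_dominates_p_and_preserves_order(p):
    adj = bh_adjust(p)
    assert (adj >= np.asarray(p) - 1e-12).all()
    assert (adj <= 1.0 + 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# BIC classification


def _simulate_patterns(kind, n_proteins=500, sd=0.1, seed=20):
    rng = np.random.default_rng(seed)
    age = DESIGN["age_months"].to_numpy()
    Y = np.empty((n_proteins, len(DESIGN)))
    for i in range(n_proteins):
        if kind == "linear":
            mean = 0.05 * age
        elif kind == "step":  # jump at 12 months only
            mean = np.where(age >= 12.0, 1.0, 0.0)
        Y[i] = mean + rng.normal(0.0, sd, size=len(DESIGN))
    return Y


def test_bic_recovers_continuous_trends():
    Y = _simulate_patterns("linear")
    classes = [classify_age_model(y, DESIGN)[2] for y in Y]
    rate = classes.count("continuous") / len(classes)
    assert rate >= 0.80


def test_bic_recovers_step_trends():
    Y = _simulate_patterns("step")
    classes = [classify_age_model(y, DESIGN)[2] for y in Y]
    rate = classes.count("non-continuous") / len(classes)
    assert rate >= 0.80


def test_bic_tie_goes_to_continuous():
    """Group means exactly collinear with age: equal RSS, so the smaller
    parameter count decides for the continuous model."""
    design = make_design(sexes=("F",))
    age = design["age_months"].to_numpy()
    # identical within-group deviation pattern, means on a line
    dev = np.tile([-0.1, 0.0, 0.1], len(design) // 3)
    y = 0.05 * age + dev
    bic_c, bic_cat, cls = classify_age_model(y, design)
    assert bic_c < bic_cat
    assert cls == "continuous"


def test_bic_requires_three_ages():
    design = make_design(ages=(3.0, 20.0))
    with pytest.raises(ValueError, match=">= 3"):
        classify_age_model(np.zeros(len(design)), design)


# ---------------------------------------------------------------------------
# Stepwise trends


def _pattern_y(means, sd, seed=0):
    rng = np.random.default_rng(seed)
    age = DESIGN["age_months"].to_numpy()
    lookup = dict(zip((3.0, 12.0, 20.0), means))
    return np.array([lookup[a] for a in age]) + rng.normal(0, sd, len(DESIGN))


def test_stepwise_up_up():
    assert stepwise_trend(_pattern_y((0.0, 1.0, 2.0), 0.05, seed=1), DESIGN) == "Up-Up"


def test_stepwise_up_down():
    assert stepwise_trend(_pattern_y((0.0, 1.0, 0.0), 0.05, seed=2), DESIGN) == "Up-Down"


def test_stepwise_flat_down():
    assert (
        stepwise_trend(_pattern_y((0.0, 0.0, -1.0), 0.05, seed=3), DESIGN)
        == "Flat-Down"
    )


def test_stepwise_not_significant_sentinel():
    y = _pattern_y((0.0, 0.0, 0.0), 0.05, seed=4)
    assert stepwise_trend(y, DESIGN, significant=False) == NOT_CATEGORIZED


def test_stepwise_matches_bic_qualitatively():
    """Monotone planted patterns are predominantly classified continuous,
    non-monotone ones non-continuous."""
    n = 100
    up_up, up_down = 0, 0
    for i in range(n):
        # monotone ramp linear in age (an Up-Up stepwise pattern)
        y1 = _pattern_y((0.18, 0.72, 1.2), 0.1, seed=1000 + i)
        y2 = _pattern_y((0.0, 1.0, 0.0), 0.1, seed=2000 + i)
        if classify_age_model(y1, DESIGN)[2] == "continuous":
            up_up += 1
        if classify_age_model(y2, DESIGN)[2] == "non-continuous":
            up_down += 1
    assert up_up / n >= 0.8
    assert up_down / n >= 0.8


# ---------------------------------------------------------------------------
# Cross-tissue consistency


def test_cross_tissue_consistent_slopes():
    """A slope shared by all three tissues is classified consistent for
    >= 90% of proteins."""
    spec = CohortSpec(
        n_proteins=500,
        tissues=("cortex", "hippocampus", "striatum"),
        frac_age_linear=1.0,
        frac_age_step=0.0,
        frac_sex=0.0,
        frac_age_by_sex=0.0,
        frac_age_by_tissue=0.0,
        seed=31,
    )
    peptides, design, _ = simulate_cohort(spec)
    matrix = np.log2(protein_matrix_from_peptides(peptides))
    out = cross_tissue_analysis(matrix, design)
    rate = float((out["consistency"] == "consistent").mean())
    assert rate >= 0.90


def test_cross_tissue_detects_tissue_specific_slope():
    design = make_design(tissues=("t1", "t2", "t3"))
    rng = np.random.default_rng(7)
    age = design["age_months"].to_numpy()
    in_t1 = (design["tissue"] == "t1").to_numpy(float)
    rows = {}
    for i in range(60):
        rows[f"P{i}"] = 0.12 * age * in_t1 + rng.normal(0, 0.1, len(design))
    matrix = pd.DataFrame.from_dict(rows, orient="columns").T
    matrix.columns = design["sample_id"]
    out = cross_tissue_analysis(matrix, design)
    assert (out["fdr_interaction"] < 0.1).mean() >= 0.9
    assert (out["consistency"] == "tissue-distinct").mean() >= 0.9


def test_cross_tissue_single_tissue_errors():
    y = np.zeros(len(DESIGN))
    with pytest.raises(ValueError, match="tissues"):
        cross_tissue_test(y, DESIGN)


def test_cross_tissue_excludes_incomplete_proteins():
    design = make_design(tissues=("t1", "t2"))
    rng = np.random.default_rng(8)
    matrix = pd.DataFrame(
        rng.normal(size=(3, len(design))),
        index=["A", "B", "C"],
        columns=design["sample_id"],
    )
    matrix.iloc[1, 0] = np.nan
    out = cross_tissue_analysis(matrix, design)
    assert out.loc["B", "consistency"] == "excluded"
    assert out.loc["A", "consistency"] != "excluded"


# ---------------------------------------------------------------------------
# Hypergeometric over-representation


def test_hypergeom_trivial_and_enumeration():
    assert hypergeom_overrep(0, 5, 4, 10) == pytest.approx(1.0)
    # N=10, K=5, n=4, k=4: only C(5,4)*C(5,0)=5 of C(10,4)=210 draws
    assert hypergeom_overrep(4, 5, 4, 10) == pytest.approx(5 / 210, abs=1e-12)


def test_hypergeom_matches_combinatorial_enumeration():
    N, K, n = 20, 7, 9
    total = math.comb(N, n)
    for k in range(0, min(K, n) + 1):
        upper = sum(
            math.comb(K, j) * math.comb(N - K, n - j)
            for j in range(k, min(K, n) + 1)
        )
        assert hypergeom_overrep(k, K, n, N) == pytest.approx(
            upper / total, abs=1e-12
        )
    # pmf normalization to 1e-12
    pmf_sum = sum(
        math.comb(K, j) * math.comb(N - K, n - j) for j in range(min(K, n) + 1)
    )
    assert pmf_sum / total == pytest.approx(1.0, abs=1e-12)


def test_hypergeom_rejects_inconsistent_counts():
    with pytest.raises(ValueError):
        hypergeom_overrep(5, 4, 10, 20)  # hits > set size
    with pytest.raises(ValueError):
        hypergeom_overrep(1, 30, 5, 20)  # set larger than universe


def test_overrepresentation_table(tmp_path):
    gmt = tmp_path / "sets.gmt"
    gmt.write_text(
        "setA\tdesc\tP1\tP2\tP3\n"
        "setB\tdesc\tP8\tP9\n"
        "short_line\n"
    )
    sets = read_gmt(gmt)
    assert set(sets) == {"setA", "setB"}
    universe = [f"P{i}" for i in range(10)]
    out = overrepresentation_table(["P1", "P2", "P3"], universe, sets)
    assert out.loc[0, "set"] == "setA"
    assert out.loc[0, "hits"] == 3
    # enumeration: P(all 3 of 3 selected in a 3-member set) = 1/C(10,3)
    assert out.loc[0, "p"] == pytest.approx(1 / math.comb(10, 3), abs=1e-12)
    assert (out["fdr"] >= out["p"] - 1e-12).all()


# ---------------------------------------------------------------------------
# Pipeline-level properties


def test_parameter_recovery_on_default_cohort():
    """Estimated continuous-age coefficients cover the planted slope at
    the nominal 95% confidence level for linear/null proteins.

    The interval uses the 97.5% t-quantile at the fit's residual df
    (~2.13 SE at n = 18); a plain 2-SE band covers only ~93.6% under a
    t with 15 df, so the t-based interval is the calibrated check.
    """
    from scipy import stats as sps

    spec = CohortSpec(n_proteins=500, seed=42)
    peptides, design, truth = simulate_cohort(spec)
    matrix = np.log2(protein_matrix_from_peptides(peptides))
    truth = truth.set_index("protein")
    ok = 0
    total = 0
    for prot in matrix.index:
        # step proteins have no single planted slope; age-by-sex proteins'
        # marginal slope differs from the planted per-sex slope
        if truth.loc[prot, "effect_class"] == "step":
            continue
        if truth.loc[prot, "age_by_sex_coef"] != 0.0:
            continue
        fit = fit_protein_model(matrix.loc[prot], design, "continuous", ("age", "sex"))
        slope_idx = fit.names.index("age")
        se = np.sqrt(fit.sigma2 * fit.xtx_inv[slope_idx, slope_idx])
        tq = sps.t.ppf(0.975, fit.df_resid)
        total += 1
        if abs(fit.params()["age"] - truth.loc[prot, "age_slope"]) <= tq * se:
            ok += 1
    assert ok / total >= 0.95


def test_analyze_matrix_full_pipeline():
    spec = CohortSpec(n_proteins=300, seed=17)
    peptides, design, truth = simulate_cohort(spec)
    matrix = np.log2(protein_matrix_from_peptides(peptides))
    res = analyze_matrix(matrix, design, TrendConfig())
    assert len(res) == 300
    # FDR dominates p for every family
    for col in ("age", "age_cat", "sex", "interaction"):
        assert (res[f"fdr_{col}"] >= res[f"p_{col}"] - 1e-12).all()
    truth = truth.set_index("protein").loc[res.index]
    linear = truth["effect_class"] == "linear"
    null = truth["effect_class"] == "null"
    # planted slopes are detected far more often than null proteins
    assert (res.loc[linear.values, "fdr_age"] < 0.1).mean() > 0.6
    assert (res.loc[null.values, "fdr_age"] < 0.1).mean() < 0.15
    # significant monotone proteins carry signed slope matching the plant
    sig = (res["fdr_age"] < 0.1).values & linear.values
    if sig.any():
        agreement = np.sign(res.loc[sig, "age_coef"]) == np.sign(
            truth.loc[sig, "age_slope"]
        )
        assert agreement.mean() > 0.95
    assert set(res["age_model_class"]) <= {
        "continuous",
        "non-continuous",
        "not-significant",
    }
    categorized = res["step_category"] != NOT_CATEGORIZED
    assert (res.loc[categorized, "fdr_age_cat"] < 0.01).all()


def test_low_sn_peptides_show_coefficient_shrinkage():
    """Peptides near the S/N floor lose trend signal: their age
    coefficients shrink toward zero and track the protein coefficient
    less well than high-S/N peptides do."""
    spec = CohortSpec(
        n_proteins=300,
        frac_age_linear=1.0,
        frac_age_step=0.0,
        frac_sex=0.0,
        frac_age_by_sex=0.0,
        intercept_mean=6.0,
        intercept_sd=1.0,
        peptides_per_protein=2,
        peptide_offset_sd=2.5,
        sn_floor=8.0,
        seed=55,
    )
    peptides, design, truth = simulate_cohort(spec)
    truth = truth.set_index("protein")
    log2_pep = np.log2(peptides)

    pep_coef = {}
    for key in peptides.index:
        fit = fit_protein_model(log2_pep.loc[key], design, "continuous", ("age",))
        pep_coef[key] = fit.params()["age"]

    mean_sn = peptides.mean(axis=1)
    rows = []
    for (prot, pep), coef in pep_coef.items():
        rows.append(
            {
                "protein": prot,
                "coef": coef,
                "mean_sn": mean_sn.loc[(prot, pep)],
                "planted": truth.loc[prot, "age_slope"],
            }
        )
    frame = pd.DataFrame(rows)
    low = frame[frame["mean_sn"] <= frame["mean_sn"].median()]
    high = frame[frame["mean_sn"] > frame["mean_sn"].median()]
    # attenuation: low-S/N coefficients are closer to zero on average
    ratio_low = (low["coef"] / low["planted"]).median()
    ratio_high = (high["coef"] / high["planted"]).median()
    assert ratio_low < ratio_high
    corr_low = low["coef"].corr(low["planted"])
    corr_high = high["coef"].corr(high["planted"])
    assert corr_low < corr_high
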