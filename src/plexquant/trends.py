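"""Per-protein age/sex trend modeling.

For each protein p within a tissue the log2 abundance y is fit by
ordinary least squares to

    y = intercept + age + sex                    (main-effects model)
    y = intercept + age + sex + age-by-sex       (interaction model)

where age enters either as a continuous covariate in months (one slope
coefficient) or as a categorical factor (one coefficient per non-baseline
age group).  Each term is tested with an F-test against the model
excluding that term, and p-values are Benjamini-Hochberg adjusted across
proteins.  Whether a protein's trajectory is better described by the
continuous or the categorical age model is decided by the Bayesian
Information Criterion on the two (non-nested) fits; significant
trajectories are further categorized into stepwise trends ("Up-Up",
"Up-Down", ...) by testing each adjacent-age contrast in the categorical
model.  Across tissues, a joint model with tissue main effects and an
age-by-tissue interaction separates proteins aging consistently in every
tissue from tissue-specific trajectories.

All proteins within a tissue share one design matrix, so the fits are
vectorized: a single pseudoinverse serves every protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TrendConfig",
    "OlsFit",
    "build_design_matrix",
    "fit_protein_model",
    "f_test",
    "bh_adjust",
    "classify_age_model",
    "stepwise_trend",
    "cross_tissue_test",
    "cross_tissue_analysis",
    "hypergeom_overrep",
    "analyze_matrix",
    "read_gmt",
    "overrepresentation_table",
]

NOT_CATEGORIZED = "not-categorized"


@dataclass(frozen=True)
class TrendConfig:
    """Significance thresholds for the trend pipeline.

    fdr_age
        BH-FDR below which a protein counts as having an age difference
        (gates the continuous vs non-continuous BIC classification).
    fdr_stepwise
        Stricter gate for stepwise trend categorization, reflecting the
        larger scope for over-fitting multi-step patterns.
    interaction_floor
        Cross-tissue consistency requires the age-by-tissue interaction
        FDR to be *above* this floor (no evidence of tissue-specific
        aging) in addition to a marginal age FDR below ``fdr_age``.
    step_alpha
        Per-contrast significance for labeling an adjacent-age step Up
        or Down rather than Flat.
    """

    fdr_age: float = 0.1
    fdr_sex: float = 0.1
    fdr_stepwise: float = 0.01
    interaction_floor: float = 0.2
    step_alpha: float = 0.05


# ---------------------------------------------------------------------------
# Design matrices and OLS


def _age_columns(design: pd.DataFrame, age_coding: str) -> tuple[np.ndarray, list[str]]:
    age = design["age_months"].to_numpy(float)
    if age_coding == "continuous":
        return age[:, None], ["age"]
    if age_coding == "categorical":
        levels = np.sort(np.unique(age))
        cols = [(age == lev).astype(float) for lev in levels[1:]]
        names = [f"age[{lev:g}]" for lev in levels[1:]]
        if not cols:
            raise ValueError("categorical age coding needs >= 2 distinct ages")
        return np.column_stack(cols), names
    raise ValueError(f"unknown age_coding: {age_coding!r}")


def build_design_matrix(
    design: pd.DataFrame,
    age_coding: str = "continuous",
    terms: Sequence[str] = ("age", "sex"),
) -> tuple[np.ndarray, list[str]]:
    """Build the OLS design matrix for the requested terms.

    Supported terms: ``age``, ``sex`` (indicator, M = 1, so the sex
    coefficient is the male-female log2 difference), ``tissue``
    (indicators vs the first tissue), ``age:sex`` and ``age:tissue``
    interactions (age coded per ``age_coding``).  An intercept is always
    included.  Raises on a rank-deficient result (e.g. a sex term with
    one sex present).
    """
    n = len(design)
    cols: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["intercept"]
    age_block: Optional[np.ndarray] = None
    age_names: list[str] = []
    if "age" in terms or "age:sex" in terms or "age:tissue" in terms:
        age_block, age_names = _age_columns(design, age_coding)
    if "age" in terms:
        cols.append(age_block)
        names.extend(age_names)
    if "sex" in terms:
        male = (design["sex"].astype(str) == "M").to_numpy(float)[:, None]
        cols.append(male)
        names.append("sex[M]")
    tissue_block: Optional[np.ndarray] = None
    tissue_names: list[str] = []
    if "tissue" in terms or "age:tissue" in terms:
        tissues = design["tissue"].astype(str)
        levels = sorted(tissues.unique())
        tissue_block = np.column_stack(
            [(tissues == lev).to_numpy(float) for lev in levels[1:]]
        ) if len(levels) > 1 else np.empty((n, 0))
        tissue_names = [f"tissue[{lev}]" for lev in levels[1:]]
    if "tissue" in terms:
        if tissue_block.shape[1] == 0:
            raise ValueError("tissue term requested but only one tissue present")
        cols.append(tissue_block)
        names.extend(tissue_names)
    if "age:sex" in terms:
        male = (design["sex"].astype(str) == "M").to_numpy(float)[:, None]
        cols.append(age_block * male)
        names.extend([f"{a}:sex[M]" for a in age_names])
    if "age:tissue" in terms:
        if tissue_block is None or tissue_block.shape[1] == 0:
            raise ValueError("age:tissue interaction needs >= 2 tissues")
        inter = np.column_stack(
            [
                age_block[:, i] * tissue_block[:, j]
                for i in range(age_block.shape[1])
                for j in range(tissue_block.shape[1])
            ]
        )
        cols.append(inter)
        names.extend(
            f"{a}:{t}" for a in age_names for t in tissue_names
        )
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for terms {tuple(terms)} "
            f"with age_coding={age_coding!r} (columns: {names})"
        )
    return X, names


@dataclass
class OlsFit:
    """One OLS fit: coefficients, residual sum of squares, dimensions."""

    coef: np.ndarray
    names: list[str]
    rss: float
    n: int
    k: int
    xtx_inv: np.ndarray
    terms: tuple[str, ...]

    @property
    def df_resid(self) -> int:
        return self.n - self.k

    def params(self) -> dict[str, float]:
        return dict(zip(self.names, self.coef))

    @property
    def sigma2(self) -> float:
        if self.df_resid <= 0:
            raise ValueError("no residual degrees of freedom")
        return self.rss / self.df_resid

    def bic(self) -> float:
        """Gaussian linear-model BIC: n*ln(RSS/n) + k_total*ln(n), with
        k_total = #coefficients + 1 counting the residual variance."""
        if self.rss <= 0:
            raise ValueError("BIC undefined for a perfect (RSS = 0) fit")
        return self.n * np.log(self.rss / self.n) + (self.k + 1) * np.log(self.n)


def fit_protein_model(
    y: np.ndarray | pd.Series,
    design: pd.DataFrame,
    age_coding: str = "continuous",
    terms: Sequence[str] = ("age", "sex"),
) -> OlsFit:
    """Ordinary least squares fit of one protein's log2 abundances.

    ``design`` rows align with ``y``; ``terms`` selects the model.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != len(design):
        raise ValueError("y must be 1-D and aligned with the design rows")
    if np.isnan(y).any():
        raise ValueError("missing values in y; complete data required per tissue")
    X, names = build_design_matrix(design, age_coding=age_coding, terms=terms)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    xtx_inv = np.linalg.inv(X.T @ X)
    return OlsFit(
        coef=coef,
        names=names,
        rss=rss,
        n=len(y),
        k=X.shape[1],
        xtx_inv=xtx_inv,
        terms=tuple(terms),
    )


def f_test(full: OlsFit, null: OlsFit) -> float:
    """Partial F-test of a full model against a nested null model.

    Returns the p-value for the extra coefficients of the full model.
    """
    if full.n != null.n:
        raise ValueError("models fit on different sample sizes")
    if not set(null.terms) <= set(full.terms) or null.k >= full.k:
        raise ValueError("null model must be strictly nested in the full model")
    df_num = full.k - null.k
    df_den = full.df_resid
    if df_den <= 0:
        raise ValueError("full model has no residual degrees of freedom")
    num = max(null.rss - full.rss, 0.0) / df_num
    if full.rss <= 0:
        return 0.0 if num > 0 else 1.0
    f_stat = num / (full.rss / df_den)
    return float(stats.f.sf(f_stat, df_num, df_den))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# BIC classification and stepwise categories


def classify_age_model(
    y: np.ndarray | pd.Series, design: pd.DataFrame
) -> tuple[float, float, str]:
    """Compare continuous vs categorical age fits by BIC.

    Returns (bic_continuous, bic_categorical, class); the class is the
    model with the lower BIC, ties going to the more parsimonious
    continuous model.  Refuses designs with fewer than 3 distinct ages
    (with 2 the codings are equivalent).
    """
    ages = np.unique(design["age_months"].to_numpy(float))
    if len(ages) < 3:
        raise ValueError(
            f"continuous vs non-continuous classification needs >= 3 distinct "
            f"ages; got {len(ages)}"
        )
    terms = ("age", "sex") if design["sex"].nunique() > 1 else ("age",)
    fit_c = fit_protein_model(y, design, age_coding="continuous", terms=terms)
    fit_cat = fit_protein_model(y, design, age_coding="categorical", terms=terms)
    bic_c, bic_cat = fit_c.bic(), fit_cat.bic()
    cls = "continuous" if bic_c <= bic_cat else "non-continuous"
    return bic_c, bic_cat, cls


def stepwise_trend(
    y: np.ndarray | pd.Series,
    design: pd.DataFrame,
    significant: bool = True,
    step_alpha: float = 0.05,
) -> str:
    """Categorize an age trajectory as stepwise changes between adjacent
    age groups, e.g. "Up-Up" or "Flat-Down".

    Fits the categorical age model (plus sex when both sexes are
    present) and tests each adjacent-age contrast with a t-test on the
    model's residual variance; a step is Up/Down when the contrast is
    positive/negative and significant at ``step_alpha``, else Flat.

    ``significant`` carries the caller's overall categorical-age FDR
    gate; when False the sentinel ``"not-categorized"`` is returned.
    """
    if not significant:
        return NOT_CATEGORIZED
    terms = ("age", "sex") if design["sex"].nunique() > 1 else ("age",)
    fit = fit_protein_model(y, design, age_coding="categorical", terms=terms)
    ages = np.sort(design["age_months"].unique())
    # coefficient j is mean(age_{j+1}) - mean(age_0); adjacent steps are
    # successive differences of those coefficients
    age_idx = [fit.names.index(f"age[{lev:g}]") for lev in ages[1:]]
    labels = []
    for step in range(len(ages) - 1):
        contrast = np.zeros(fit.k)
        contrast[age_idx[step]] = 1.0
        if step > 0:
            contrast[age_idx[step - 1]] = -1.0
        est = float(contrast @ fit.coef)
        se = float(np.sqrt(fit.sigma2 * contrast @ fit.xtx_inv @ contrast))
        if se == 0:
            labels.append("Flat")
            continue
        p = 2.0 * stats.t.sf(abs(est / se), fit.df_resid)
        if p < step_alpha and est > 0:
            labels.append("Up")
        elif p < step_alpha and est < 0:
            labels.append("Down")
        else:
            labels.append("Flat")
    return "-".join(labels)


# ---------------------------------------------------------------------------
# Cross-tissue consistency


def cross_tissue_test(
    y: np.ndarray | pd.Series,
    design: pd.DataFrame,
    age_coding: str = "continuous",
) -> tuple[float, float]:
    """Test the age main effect and the age-by-tissue interaction.

    Fits the joint model intercept + age + sex + tissue + age-by-tissue.
    The marginal age p-value compares the main-effects model with and
    without the age term; the interaction p-value compares the joint
    model to the main-effects model.  Requires >= 2 tissues.

    Returns (p_age_marginal, p_age_by_tissue).
    """
    if design["tissue"].nunique() < 2:
        raise ValueError("cross-tissue test needs >= 2 tissues")
    has_sex = design["sex"].nunique() > 1
    base = ("sex", "tissue") if has_sex else ("tissue",)
    main = ("age",) + base
    full = main + ("age:tissue",)
    fit_null = fit_protein_model(y, design, age_coding, terms=base)
    fit_main = fit_protein_model(y, design, age_coding, terms=main)
    fit_full = fit_protein_model(y, design, age_coding, terms=full)
    return f_test(fit_main, fit_null), f_test(fit_full, fit_main)


def cross_tissue_analysis(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    config: TrendConfig | None = None,
    age_coding: str = "continuous",
) -> pd.DataFrame:
    """Consistency classification across tissues for every protein.

    ``matrix`` is proteins x samples on the log2 scale; proteins with
    missing values in any tissue are excluded and reported in the
    ``excluded`` column.  After BH adjustment across proteins, a protein
    ages *consistently* when fdr_age < config.fdr_age and
    fdr_interaction > config.interaction_floor, and *tissue-distinct*
    when the interaction FDR falls below config.fdr_age.
    """
    config = config or TrendConfig()
    design = design.set_index("sample_id").loc[matrix.columns].reset_index()
    complete = matrix.notna().all(axis=1)
    rows = []
    for prot in matrix.index:
        if not complete.loc[prot]:
            rows.append((prot, np.nan, np.nan, True))
            continue
        p_age, p_int = cross_tissue_test(matrix.loc[prot], design, age_coding)
        rows.append((prot, p_age, p_int, False))
    out = pd.DataFrame(
        rows, columns=["protein", "p_age", "p_interaction", "excluded"]
    ).set_index("protein")
    tested = ~out["excluded"]
    out["fdr_age"] = np.nan
    out["fdr_interaction"] = np.nan
    out.loc[tested, "fdr_age"] = bh_adjust(out.loc[tested, "p_age"])
    out.loc[tested, "fdr_interaction"] = bh_adjust(out.loc[tested, "p_interaction"])
    consistent = (out["fdr_age"] < config.fdr_age) & (
        out["fdr_interaction"] > config.interaction_floor
    )
    distinct = out["fdr_interaction"] < config.fdr_age
    out["consistency"] = np.select(
        [out["excluded"], consistent, distinct],
        ["excluded", "consistent", "tissue-distinct"],
        default="neither",
    )
    return out


# ---------------------------------------------------------------------------
# Over-representation


def hypergeom_overrep(hits_in_set: int, set_size: int, selected: int, universe: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= hits_in_set).

    Drawing ``selected`` proteins from a universe of ``universe`` of
    which ``set_size`` belong to the gene set, the p-value is the
    probability of observing at least ``hits_in_set`` set members.
    """
    k, K, n, N = hits_in_set, set_size, selected, universe
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(
            f"inconsistent counts: hits={k}, set={K}, selected={n}, universe={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def overrepresentation_table(
    selected: Sequence[str],
    universe: Sequence[str],
    gene_sets: dict[str, Sequence[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` (vs ``universe``)
    in each gene set, BH-adjusted across sets."""
    uni = set(universe)
    sel = set(selected) & uni
    rows = []
    for name, members in gene_sets.items():
        mem = set(members) & uni
        if not mem:
            continue
        hits = len(sel & mem)
        p = hypergeom_overrep(hits, len(mem), len(sel), len(uni))
        rows.append({"set": name, "set_size": len(mem), "hits": hits, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"])
        out = out.sort_values("p").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Whole-matrix pipeline (vectorized across proteins)


def _batch_ols(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of every row of Y (proteins x samples) on shared design X.

    Returns (coefficients proteins x k, RSS per protein).
    """
    pinv = np.linalg.pinv(X)
    B = Y @ pinv.T
    resid = Y - B @ X.T
    return B, np.einsum("ij,ij->i", resid, resid)


def _batch_f_test(
    rss_full: np.ndarray, k_full: int, rss_null: np.ndarray, k_null: int, n: int
) -> np.ndarray:
    df_num = k_full - k_null
    df_den = n - k_full
    num = np.maximum(rss_null - rss_full, 0.0) / df_num
    den = rss_full / df_den
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.where(den > 0, num / den, np.inf)
    return stats.f.sf(f_stat, df_num, df_den)


def analyze_matrix(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    config: TrendConfig | None = None,
) -> pd.DataFrame:
    """Full single-tissue trend analysis for a log2 protein matrix.

    Parameters
    ----------
    matrix : DataFrame
        Proteins x samples, log2 scale.  Columns must match
        ``design['sample_id']`` (or the design's ``channel`` column).
    design : DataFrame
        One row per sample: sample_id (or channel), age_months, sex.
    config : TrendConfig

    Returns one row per protein with continuous-model age and sex
    coefficients, F-test p-values for age (both codings), sex and the
    age-by-sex interaction, BH FDRs across proteins, the BIC pair and
    continuous/non-continuous class for proteins passing the age FDR
    gate, and the stepwise trend category for proteins passing the
    stricter stepwise gate.
    """
    config = config or TrendConfig()
    key = "sample_id" if "sample_id" in design.columns else "channel"
    design = design.set_index(key).loc[matrix.columns].reset_index()
    Y = matrix.to_numpy(float)
    if np.isnan(Y).any():
        raise ValueError("matrix contains missing values; filter proteins first")
    n = Y.shape[1]
    has_sex = design["sex"].nunique() > 1
    base_terms = ("sex",) if has_sex else ()
    ages = np.sort(design["age_months"].unique())

    def _design(age_coding, terms):
        return build_design_matrix(design, age_coding=age_coding, terms=terms)[0]

    X_null = _design("continuous", base_terms) if base_terms else np.ones((n, 1))
    X_cont = _design("continuous", ("age",) + base_terms)
    X_cat = _design("categorical", ("age",) + base_terms)
    B_cont, rss_cont = _batch_ols(Y, X_cont)
    B_cat, rss_cat = _batch_ols(Y, X_cat)
    _, rss_null = _batch_ols(Y, X_null)

    p_age = _batch_f_test(rss_cont, X_cont.shape[1], rss_null, X_null.shape[1], n)
    p_age_cat = _batch_f_test(rss_cat, X_cat.shape[1], rss_null, X_null.shape[1], n)

    out = pd.DataFrame(index=matrix.index)
    out["age_coef"] = B_cont[:, 1]
    out["p_age"] = p_age
    out["p_age_cat"] = p_age_cat

    if has_sex:
        X_nosex = _design("continuous", ("age",))
        _, rss_nosex = _batch_ols(Y, X_nosex)
        out["sex_coef"] = B_cont[:, 2]
        out["p_sex"] = _batch_f_test(
            rss_cont, X_cont.shape[1], rss_nosex, X_nosex.shape[1], n
        )
        X_int = _design("continuous", ("age", "sex", "age:sex"))
        _, rss_int = _batch_ols(Y, X_int)
        out["p_interaction"] = _batch_f_test(
            rss_int, X_int.shape[1], rss_cont, X_cont.shape[1], n
        )
    else:
        out["sex_coef"] = np.nan
        out["p_sex"] = np.nan
        out["p_interaction"] = np.nan

    out["fdr_age"] = bh_adjust(out["p_age"])
    out["fdr_age_cat"] = bh_adjust(out["p_age_cat"])
    if has_sex:
        out["fdr_sex"] = bh_adjust(out["p_sex"])
        out["fdr_interaction"] = bh_adjust(out["p_interaction"])
    else:
        out["fdr_sex"] = np.nan
        out["fdr_interaction"] = np.nan

    # BIC classification, gated on the age FDR under either coding
    k_cont_total = X_cont.shape[1] + 1
    k_cat_total = X_cat.shape[1] + 1
    with np.errstate(divide="ignore"):
        out["bic_continuous"] = n * np.log(rss_cont / n) + k_cont_total * np.log(n)
        out["bic_categorical"] = n * np.log(rss_cat / n) + k_cat_total * np.log(n)
    significant = (
        (out["fdr_age"] < config.fdr_age) | (out["fdr_age_cat"] < config.fdr_age)
    ).to_numpy()
    classes = np.where(
        out["bic_continuous"] <= out["bic_categorical"],
        "continuous",
        "non-continuous",
    )
    out["age_model_class"] = np.where(
        significant if len(ages) >= 3 else False, classes, "not-significant"
    )

    # stepwise categories for the strongly significant categorical fits
    step_gate = (out["fdr_age_cat"] < config.fdr_stepwise).to_numpy()
    categories = []
    for i, prot in enumerate(matrix.index):
        if not step_gate[i]:
            categories.append(NOT_CATEGORIZED)
        else:
            categories.append(
                stepwise_trend(
                    Y[i], design, significant=True, step_alpha=config.step_alpha
                )
            )
    out["step_category"] = categories
    return out
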