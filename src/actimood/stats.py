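"""Group-comparison statistics.

Variable preparation (quintiles with inversion, category condensation),
pairwise case-control logistic regression with two covariate sets, a Fisher's
exact fallback for sparse tables, the objective-vs-subjective sleep
discrepancy procedure and its multinomial model, Benjamini-Hochberg FDR, and
descriptive tests (Pearson chi-squared with Cramér's V, one-way ANOVA with
eta-squared, reconstructible from printed summary statistics).

Odds-ratio orientation: the first-named group of a comparison is coded 1, so
OR > 1 means the exposure is more likely in that group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from scipy.stats.contingency import expected_freq, odds_ratio
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

__all__ = [
    "ModelSpec",
    "ComparisonResult",
    "COMPARISONS",
    "make_quintiles",
    "condense_categories",
    "neuroticism_score",
    "sleep_discrepancy",
    "bh_fdr",
    "chi_squared_table",
    "oneway_anova_summary",
    "oneway_anova_raw",
    "fisher_exact_2x2",
    "fit_group_logistic",
    "multinomial_discrepancy",
    "apply_fdr",
]

COMPARISONS = {
    "BD_vs_UM": ("BD", "UM"),
    "UM_vs_control": ("UM", "CONTROL"),
    "BD_vs_control": ("BD", "CONTROL"),
}

PARTLY_COVARIATES = ["age", "C(sex)", "townsend", "C(education)", "C(ethnicity)"]
FULLY_EXTRA = ["bmi", "C(smoking)", "C(alcohol)", "psychotropic"]


# ---------------------------------------------------------------------------
# variable preparation


def make_quintiles(values, invert: bool = False) -> pd.Series:
    """Quintile labels 1-5 from pooled-sample quantile boundaries.

    Boundaries are type-7 (linear-interpolation) sample quantiles; ties on a
    boundary fall into the lower bin. ``invert=True`` negates values first so
    that label 5 marks the *low* end of the raw scale (used for RA, IS, AA
    and sleep efficiency, where lower raw values are the negative outcome).
    Missing values stay missing.
    """
    s = pd.Series(values, dtype=float)
    x = -s if invert else s.copy()
    obs = x.dropna()
    if obs.nunique() < 5:
        raise ValueError(f"need >= 5 distinct values to form quintiles, got {obs.nunique()}")
    bounds = np.quantile(obs.to_numpy(), [0.2, 0.4, 0.6, 0.8], method="linear")
    labels = np.searchsorted(bounds, x.to_numpy(), side="left") + 1.0
    labels[x.isna().to_numpy()] = np.nan
    return pd.Series(labels, index=s.index)


_CONDENSE_MAPS = {
    "chronotype": {
        "definitely_morning": "early",
        "more_morning": "intermediate",
        "more_evening": "intermediate",
        "definitely_evening": "late",
        "do_not_know": None,
        "prefer_not_answer": None,
    },
    "happiness": {
        "extremely_happy": "happy",
        "very_happy": "happy",
        "moderately_happy": "happy",
        "moderately_unhappy": "unhappy",
        "very_unhappy": "unhappy",
        "extremely_unhappy": "unhappy",
        "do_not_know": None,
        "prefer_not_answer": None,
    },
    "getting_up": {
        "very_easy": "not_difficult",
        "fairly_easy": "not_difficult",
        "not_very_easy": "difficult",
        "not_at_all_easy": "difficult",
        "do_not_know": None,
        "prefer_not_answer": None,
    },
}

# analysis reference categories
REFERENCES = {
    "chronotype": "intermediate",
    "happiness": "happy",
    "getting_up": "not_difficult",
    "sleep_duration": "regular",
}


def condense_categories(kind: str, values):
    """Condense a raw questionnaire item into its analysis categories.

    Non-response codes ("do not know" / "prefer not to answer") become
    missing. Unknown codes raise, naming the code.
    """
    if kind not in _CONDENSE_MAPS:
        raise ValueError(f"unknown item kind {kind!r}; expected one of {sorted(_CONDENSE_MAPS)}")
    mapping = _CONDENSE_MAPS[kind]

    def one(v):
        if v is None or (not isinstance(v, str) and pd.isna(v)):
            return None
        if v not in mapping:
            raise ValueError(f"unknown {kind} code {v!r}")
        return mapping[v]

    if isinstance(values, (pd.Series, np.ndarray, list, tuple)):
        s = pd.Series(values, dtype=object)
        return s.map(one)
    return one(values)


def neuroticism_score(items: Sequence) -> float:
    """Sum of 12 binary neuroticism items; missing if any item is missing."""
    items = list(items)
    if len(items) != 12:
        raise ValueError(f"expected 12 items, got {len(items)}")
    vals = pd.Series(items, dtype=float)
    if vals.isna().any():
        return float("nan")
    if not vals.isin([0.0, 1.0]).all():
        raise ValueError("items must be binary (0/1)")
    return float(vals.sum())


def sleep_discrepancy(subjective_h, objective_h, napping: Optional[str]) -> tuple:
    """(category, diff_minutes) for the subjective-vs-objective comparison.

    Regular nappers are excluded (subjective reports include naps, the
    objective estimate does not). Objective duration is rounded to the
    nearest hour; ``diff = subjective - rounded objective`` with diff > 0 an
    overestimation and diff < 0 an underestimation. ``diff_minutes`` is the
    unrounded subjective - objective difference in minutes.
    """
    if napping == "regular":
        return "excluded", float("nan")
    if pd.isna(subjective_h) or pd.isna(objective_h):
        return "excluded", float("nan")
    rounded = math.floor(float(objective_h) + 0.5)  # half rounds up
    diff = float(subjective_h) - rounded
    minutes = (float(subjective_h) - float(objective_h)) * 60.0
    if diff == 0:
        return "accurate", minutes
    return ("overestimation" if diff > 0 else "underestimation"), minutes


# ---------------------------------------------------------------------------
# descriptive tests


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi_squared_table(counts) -> tuple:
    """Pearson chi-squared on a contingency table: (statistic, df, Cramér's V)."""
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or min(c.shape) < 2:
        raise ValueError("need a table of at least 2x2")
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    stat, _, dof, _ = sps.chi2_contingency(c, correction=False)
    n = c.sum()
    v = math.sqrt(stat / (n * (min(c.shape) - 1)))
    return float(stat), int(dof), float(v)


def oneway_anova_summary(means, sds, ns) -> tuple:
    """One-way ANOVA reconstructed from group means, SDs and sizes.

    Returns (F, (df_between, df_within), eta_squared). F is NaN when the
    within-group variance is zero (undefined ratio).
    """
    m = np.asarray(means, dtype=float)
    s = np.asarray(sds, dtype=float)
    n = np.asarray(ns, dtype=float)
    k = m.size
    if k < 2 or s.size != k or n.size != k:
        raise ValueError("need >= 2 groups with matching means/sds/ns")
    if (n < 2).any():
        raise ValueError("every group needs n >= 2")
    N = n.sum()
    grand = (n * m).sum() / N
    ssb = (n * (m - grand) ** 2).sum()
    ssw = ((n - 1) * s**2).sum()
    df1, df2 = k - 1, N - k
    eta2 = ssb / (ssb + ssw) if (ssb + ssw) > 0 else float("nan")
    if ssw <= 0:
        return float("nan"), (int(df1), int(df2)), float(eta2)
    f = (ssb / df1) / (ssw / df2)
    return float(f), (int(df1), int(df2)), float(eta2)


def oneway_anova_raw(groups: Sequence[Sequence[float]]) -> tuple:
    """One-way ANOVA from raw samples via the summary-statistic identity."""
    means = [np.mean(g) for g in groups]
    sds = [np.std(g, ddof=1) for g in groups]
    ns = [len(g) for g in groups]
    return oneway_anova_summary(means, sds, ns)


def fisher_exact_2x2(table) -> tuple:
    """(conditional-MLE odds ratio, two-sided exact p) for a 2x2 table.

    An empty margin makes the OR undefined (NaN) with p = 1.
    """
    c = np.asarray(table, dtype=int)
    if c.shape != (2, 2) or (c < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (c.sum(axis=0) == 0).any() or (c.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    p = float(sps.fisher_exact(c)[1])
    or_ = float(odds_ratio(c).statistic)
    return or_, p


# ---------------------------------------------------------------------------
# logistic / multinomial models


@dataclass
class ModelSpec:
    """One exposure x group-pair x adjustment model."""

    comparison: str  # key of COMPARISONS
    exposure: str  # column name
    exposure_type: str = "categorical"  # or "continuous"
    reference: Optional[str] = None  # reference category
    adjustment: str = "fully"  # "unadjusted" | "partly" | "fully"
    objective: bool = False  # include season of accelerometer wear

    def covariate_terms(self) -> List[str]:
        if self.adjustment == "unadjusted":
            return []
        terms = list(PARTLY_COVARIATES)
        if self.objective:
            terms.append("C(season)")
        if self.adjustment == "fully":
            terms += FULLY_EXTRA
        elif self.adjustment != "partly":
            raise ValueError(f"unknown adjustment {self.adjustment!r}")
        return terms

    def exposure_term(self) -> str:
        if self.exposure_type == "continuous":
            return self.exposure
        if self.reference is not None:
            return f"C({self.exposure}, Treatment(reference={self.reference!r}))"
        return f"C({self.exposure})"


@dataclass
class ComparisonResult:
    """OR and uncertainty for one exposure level in one group comparison."""

    comparison: str
    exposure: str
    level: Optional[str]
    reference: Optional[str]
    adjustment: str
    or_: float
    ci_low: float
    ci_high: float
    p: float
    n_cases: int
    n_controls: int
    method: str = "logistic"
    p_fdr: Optional[float] = None
    converged: bool = True
    note: str = ""

    def as_row(self) -> dict:
        return {
            "comparison": self.comparison,
            "exposure": self.exposure,
            "level": self.level,
            "reference": self.reference,
            "adjustment": self.adjustment,
            "odds_ratio": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "p_fdr": self.p_fdr,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "method": self.method,
            "converged": self.converged,
            "note": self.note,
        }


def _model_frame(df: pd.DataFrame, spec: ModelSpec, group_col: str) -> pd.DataFrame:
    g1, g2 = COMPARISONS[spec.comparison]
    sub = df[df[group_col].isin([g1, g2])].copy()
    sub["_outcome"] = (sub[group_col] == g1).astype(int)
    needed = [spec.exposure] + [t.strip("C()").split(",")[0].replace("(", "") for t in spec.covariate_terms()]
    cols = ["_outcome"] + [c for c in dict.fromkeys(needed)]
    sub = sub[cols].dropna()
    return sub


def fit_group_logistic(
    df: pd.DataFrame,
    spec: ModelSpec,
    group_col: str = "group",
) -> List[ComparisonResult]:
    """Fit one pairwise logistic model; one result per exposure level.

    The first-named group of ``spec.comparison`` is the outcome (coded 1);
    the exposure coefficient(s) are exponentiated to odds ratios with Wald
    95% intervals. Separation or non-convergence yields flagged results
    (``converged=False``) instead of raising.
    """
    if spec.comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {spec.comparison!r}")
    sub = _model_frame(df, spec, group_col)
    n_cases = int(sub["_outcome"].sum())
    n_controls = int(len(sub) - n_cases)
    base = ComparisonResult(
        comparison=spec.comparison, exposure=spec.exposure, level=None,
        reference=spec.reference, adjustment=spec.adjustment,
        or_=float("nan"), ci_low=float("nan"), ci_high=float("nan"), p=float("nan"),
        n_cases=n_cases, n_controls=n_controls,
    )
    if n_cases == 0 or n_controls == 0:
        return [replace(base, converged=False, note="empty group")]
    if sub[spec.exposure].nunique(dropna=True) < 2:
        return [replace(base, converged=False, note="exposure has no variation")]

    formula = "_outcome ~ " + " + ".join([spec.exposure_term()] + spec.covariate_terms())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.logit(formula, data=sub)
            try:
                fit = model.fit(disp=0, maxiter=200)
            except (np.linalg.LinAlgError, PerfectSeparationError):
                # singular Newton step (sparse dummies at small n): quasi-Newton copes
                fit = model.fit(disp=0, maxiter=500, method="bfgs")
        converged = bool(fit.mle_retvals.get("converged", True))
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as exc:
        return [replace(base, converged=False, note=f"fit failed: {exc}")]

    results = []
    with np.errstate(over="ignore"):
        ci = np.exp(fit.conf_int())
    for name in fit.params.index:
        if spec.exposure_type == "continuous":
            if name != spec.exposure:
                continue
            level = None
        else:
            if not name.startswith(f"C({spec.exposure}"):
                continue
            level = name.split("[T.", 1)[1].rstrip("]") if "[T." in name else name
        beta = float(fit.params[name])
        se = float(fit.bse[name])
        if abs(beta) > 20 or not np.isfinite(se) or se > 100:
            # quasi-separation / singular covariance: the MLE is unidentified
            results.append(replace(base, level=level, converged=False,
                                   note="quasi-separation"))
            continue
        results.append(
            replace(
                base,
                level=level,
                or_=float(np.exp(fit.params[name])),
                ci_low=float(ci.loc[name, 0]),
                ci_high=float(ci.loc[name, 1]),
                p=float(fit.pvalues[name]),
                converged=converged,
                note="" if converged else "did not converge",
            )
        )
    if not results:
        return [replace(base, converged=False, note="exposure dropped from design")]
    return results


def sparse_levels(
    df: pd.DataFrame,
    spec: ModelSpec,
    group_col: str = "group",
    min_expected: float = 5.0,
) -> List[str]:
    """Exposure levels whose level-vs-reference 2x2 has an expected cell < min_expected."""
    if spec.exposure_type != "categorical" or spec.reference is None:
        return []
    g1, g2 = COMPARISONS[spec.comparison]
    sub = df[df[group_col].isin([g1, g2])][[group_col, spec.exposure]].dropna()
    out = []
    for level in sorted(sub[spec.exposure].unique()):
        if level == spec.reference:
            continue
        tab = np.array(
            [
                [((sub[group_col] == g) & (sub[spec.exposure] == level)).sum(),
                 ((sub[group_col] == g) & (sub[spec.exposure] == spec.reference)).sum()]
                for g in (g1, g2)
            ],
            dtype=float,
        )
        if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            out.append(str(level))
        elif expected_freq(tab).min() < min_expected:
            out.append(str(level))
    return out


def fisher_level_result(
    df: pd.DataFrame, spec: ModelSpec, level: str, group_col: str = "group"
) -> ComparisonResult:
    """Unadjusted exact-test result for one sparse exposure level."""
    g1, g2 = COMPARISONS[spec.comparison]
    sub = df[df[group_col].isin([g1, g2])][[group_col, spec.exposure]].dropna()
    a = int(((sub[group_col] == g1) & (sub[spec.exposure] == level)).sum())
    b = int(((sub[group_col] == g1) & (sub[spec.exposure] == spec.reference)).sum())
    c = int(((sub[group_col] == g2) & (sub[spec.exposure] == level)).sum())
    d = int(((sub[group_col] == g2) & (sub[spec.exposure] == spec.reference)).sum())
    or_, p = fisher_exact_2x2([[a, b], [c, d]])
    return ComparisonResult(
        comparison=spec.comparison, exposure=spec.exposure, level=str(level),
        reference=spec.reference, adjustment="unadjusted",
        or_=or_, ci_low=float("nan"), ci_high=float("nan"), p=p,
        n_cases=a + b, n_controls=c + d, method="fisher",
        note="sparse cells; exact test, unadjusted",
    )


def multinomial_discrepancy(
    df: pd.DataFrame,
    adjustment: str = "fully",
    outcome_col: str = "discrepancy_cat",
    group_col: str = "group",
    objective: bool = True,
) -> List[ComparisonResult]:
    """Multinomial model of sleep-duration estimation accuracy.

    Outcome levels: accurate (reference), underestimation, overestimation;
    predictor of interest is group (control as reference) with the usual
    covariate sets. Returns one result per outcome level x non-reference
    group.
    """
    levels = ["accurate", "underestimation", "overestimation"]
    sub = df[df[outcome_col].isin(levels)].copy()
    present = sub[outcome_col].nunique()
    if present < 3:
        raise ValueError(
            f"outcome has {present} categories; use a binary logistic model instead"
        )
    spec = ModelSpec(
        comparison="BD_vs_control", exposure=group_col, exposure_type="categorical",
        reference="CONTROL", adjustment=adjustment, objective=objective,
    )
    sub["_y"] = sub[outcome_col].map({lev: i for i, lev in enumerate(levels)}).astype(int)
    needed = [group_col] + [t.strip("C()").split(",")[0].replace("(", "") for t in spec.covariate_terms()]
    sub = sub[["_y"] + list(dict.fromkeys(needed))].dropna()
    formula = "_y ~ " + " + ".join(
        [f"C({group_col}, Treatment(reference='CONTROL'))"] + spec.covariate_terms()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = smf.mnlogit(formula, data=sub).fit(disp=0, maxiter=300)
    converged = bool(fit.mle_retvals.get("converged", True))

    results: List[ComparisonResult] = []
    params, pvals, bse = fit.params, fit.pvalues, fit.bse
    z = sps.norm.ppf(0.975)
    for j, outcome_level in enumerate(levels[1:]):
        col = params.columns[j]
        for name in params.index:
            if not name.startswith(f"C({group_col}"):
                continue
            grp = name.split("[T.", 1)[1].rstrip("]")
            beta, se = float(params.loc[name, col]), float(bse.loc[name, col])
            results.append(
                ComparisonResult(
                    comparison=f"{grp}_vs_control",
                    exposure=f"sleep_discrepancy:{outcome_level}",
                    level=outcome_level,
                    reference="accurate",
                    adjustment=adjustment,
                    or_=float(np.exp(beta)),
                    ci_low=float(np.exp(beta - z * se)),
                    ci_high=float(np.exp(beta + z * se)),
                    p=float(pvals.loc[name, col]),
                    n_cases=int((sub[group_col] == grp).sum()),
                    n_controls=int((sub[group_col] == "CONTROL").sum()),
                    method="multinomial",
                    converged=converged,
                )
            )
    return results


def apply_fdr(results: List[ComparisonResult], which_adjustment: str = "fully") -> None:
    """BH-adjust, in place, the p-values of the given adjustment family."""
    idx = [i for i, r in enumerate(results)
           if r.adjustment == which_adjustment and np.isfinite(r.p)]
    if not idx:
        return
    adjusted = bh_fdr([results[i].p for i in idx])
    for i, q in zip(idx, adjusted):
        results[i].p_fdr = float(q)
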