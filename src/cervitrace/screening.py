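"""Screening-performance evaluation of cervical-length measurements.

Given a cohort of per-subject lengths and delivery outcomes this
module converts lengths to multiples of the median (MoM), runs the
group comparisons (Shapiro-Wilk normality screen, Student t tests,
one-way ANOVA with post hoc t tests), fits covariate-adjusted
logistic regressions, and quantifies discrimination by the area under
the ROC curve with DeLong variance estimates — including the paired
DeLong test for comparing two measurement methods on the same
subjects.  A closed-form two-sample power calculation mirrors the
usual sample-size audit for detecting a mean cervical-length deficit.

Risk-score orientation: a shorter cervix means higher risk, so scores
fed to the ROC machinery are negated lengths (or MoMs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phantoms import GROUPS, ScreeningCohort

METHOD_COLUMNS = {
    "single": "cl_single_mm",
    "two": "cl_two_mm",
    "ai": "cl_ai_mm",
}


def _method_column(method: str) -> str:
    if method in METHOD_COLUMNS:
        return METHOD_COLUMNS[method]
    if method in METHOD_COLUMNS.values():
        return method
    raise ValueError(f"unknown method {method!r}; expected one of "
                     f"{sorted(METHOD_COLUMNS)} or a cl_* column name")


# ---------------------------------------------------------------------------
# cohort summary & MoM
# ---------------------------------------------------------------------------

def cohort_summary(cohort: ScreeningCohort) -> pd.DataFrame:
    """Group counts and shares: term and overall-preterm rows carry the
    percentage of the whole cohort; the preterm subgroups carry their
    share of all spontaneous preterm births.  Percentages are rounded
    to one decimal."""
    t = cohort.table
    n_total = len(t)
    n_term = int((t["outcome"] == "term").sum())
    n_32_36 = int((t["outcome"] == "sptb_32_36").sum())
    n_lt32 = int((t["outcome"] == "sptb_lt32").sum())
    n_sptb = n_32_36 + n_lt32
    rows = [
        ("term", n_term, round(100.0 * n_term / n_total, 1)),
        ("sptb_lt37", n_sptb, round(100.0 * n_sptb / n_total, 1)),
        ("sptb_32_36", n_32_36,
         round(100.0 * n_32_36 / n_sptb, 1) if n_sptb else np.nan),
        ("sptb_lt32", n_lt32,
         round(100.0 * n_lt32 / n_sptb, 1) if n_sptb else np.nan),
    ]
    return pd.DataFrame(rows, columns=["group", "n", "percent"])


def compute_mom(cohort: ScreeningCohort, method: str,
                reference: str = "all") -> pd.DataFrame:
    """Divide each subject's length by the reference-population median.

    ``reference`` is "all" (whole cohort, default) or "term_only".
    Returns a table (subject_id, method, cl_mm, mom, median_used).
    """
    col = _method_column(method)
    t = cohort.table
    ref = t if reference == "all" else t[t["outcome"] == "term"]
    if reference not in ("all", "term_only"):
        raise ValueError("reference must be 'all' or 'term_only'")
    if len(ref) == 0:
        raise ValueError("reference population is empty")
    med = float(ref[col].median())
    if med <= 0:
        raise ValueError("reference median must be positive")
    return pd.DataFrame({
        "subject_id": t["subject_id"],
        "method": col,
        "cl_mm": t[col],
        "mom": t[col] / med,
        "median_used": med,
    })


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def group_compare(cohort: ScreeningCohort, method: str,
                  groups: tuple[str, ...] = GROUPS) -> dict:
    """Normality screen plus t tests and ANOVA across outcome groups.

    Returns a dict with per-group Shapiro-Wilk results, pairwise
    term-vs-preterm Student t tests, and (for three or more groups)
    one-way ANOVA with post hoc pairwise t tests.
    """
    col = _method_column(method)
    samples = {g: cohort.group(g)[col].to_numpy() for g in groups}
    sizes = {g: len(v) for g, v in samples.items()}
    present = [g for g in groups if sizes[g] >= 2]
    if len(present) < 2:
        raise ValueError("need at least two groups with >= 2 subjects")
    if all(np.var(samples[g]) == 0 for g in present):
        raise ValueError("all groups are degenerate (zero variance)")

    shapiro = {}
    for g in present:
        v = samples[g]
        if len(v) >= 3 and np.var(v) > 0:
            w, p = stats.shapiro(v)
            shapiro[g] = {"W": float(w), "p": float(p), "n": len(v)}
        else:
            shapiro[g] = {"W": np.nan, "p": np.nan, "n": len(v)}

    pairwise = {}
    for g in present:
        if g == "term" or "term" not in present:
            continue
        tstat, p = stats.ttest_ind(samples["term"], samples[g])
        pairwise[f"term_vs_{g}"] = {"t": float(tstat), "p": float(p)}
    # pooled preterm contrast when both subgroups exist
    if "term" in present and sizes.get("sptb_32_36", 0) + sizes.get("sptb_lt32", 0) >= 2:
        pooled = np.concatenate([samples.get("sptb_32_36", np.empty(0)),
                                 samples.get("sptb_lt32", np.empty(0))])
        if len(pooled) >= 2:
            tstat, p = stats.ttest_ind(samples["term"], pooled)
            pairwise["term_vs_sptb_lt37"] = {"t": float(tstat), "p": float(p)}

    result = {"method": col, "group_sizes": sizes, "shapiro": shapiro,
              "t_tests": pairwise}
    if len(present) >= 2:
        f, p = stats.f_oneway(*[samples[g] for g in present])
        posthoc = {}
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                tt, pp = stats.ttest_ind(samples[a], samples[b])
                posthoc[f"{a}_vs_{b}"] = {"t": float(tt), "p": float(pp)}
        result["anova"] = {"F": float(f), "p": float(p), "post_hoc": posthoc}
    return result


# ---------------------------------------------------------------------------
# ROC / AUROC with DeLong variance
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auroc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int


@dataclass
class ROCComparison:
    delta_auroc: float
    p_value: float
    method: str = "paired DeLong"


def _placement_values(cases: np.ndarray, controls: np.ndarray):
    """DeLong structural components via midranks; ties count 1/2."""
    m, n = len(cases), len(controls)
    allv = np.concatenate([cases, controls])
    ranks = stats.rankdata(allv)
    rc = ranks[:m]
    rn = ranks[m:]
    rank_cases = stats.rankdata(cases)
    rank_controls = stats.rankdata(controls)
    auc = (rc.sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rc - rank_cases) / n          # per-case placements
    v01 = 1.0 - (rn - rank_controls) / m  # per-control placements
    return auc, v10, v01


def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    return cases, controls


def auroc(scores, labels, alpha: float = 0.05) -> ROCResult:
    """AUROC by Mann-Whitney ranking (ties at 1/2) with a DeLong
    normal-approximation confidence interval truncated to [0, 1]."""
    cases, controls = _split_scores(scores, labels)
    auc, v10, v01 = _placement_values(cases, controls)
    var = (np.var(v10, ddof=1) / len(v10) if len(v10) > 1 else 0.0) + \
          (np.var(v01, ddof=1) / len(v01) if len(v01) > 1 else 0.0)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return ROCResult(
        auroc=float(auc),
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_cases=len(cases),
        n_controls=len(controls),
    )


def compare_auroc(scores_a, scores_b, labels) -> ROCComparison:
    """Paired DeLong test for two correlated ROC curves on the same
    subjects; two-sided p from the normal approximation."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors differ in length")
    ca, na = _split_scores(scores_a, labels)
    cb, nb = _split_scores(scores_b, labels)
    auc_a, v10a, v01a = _placement_values(ca, na)
    auc_b, v10b, v01b = _placement_values(cb, nb)
    m, n = len(ca), len(na)
    delta = float(auc_a - auc_b)
    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return ROCComparison(delta_auroc=delta, p_value=p)


def risk_scores(cohort: ScreeningCohort, method: str, use_mom: bool = False,
                case_groups: tuple[str, ...] = ("sptb_32_36", "sptb_lt32")):
    """(scores, labels) for ROC analysis: shorter cervix => higher
    risk, so scores are negated lengths (or MoMs)."""
    col = _method_column(method)
    t = cohort.table
    values = compute_mom(cohort, method)["mom"].to_numpy() if use_mom \
        else t[col].to_numpy()
    labels = t["outcome"].isin(case_groups).astype(int).to_numpy()
    return -values, labels


# ---------------------------------------------------------------------------
# adjusted logistic regression
# ---------------------------------------------------------------------------

DEFAULT_COVARIATES = ("age", "bmi", "parity", "prior_ptb_or_surgery")


def logistic_adjusted(cohort: ScreeningCohort, method: str,
                      covariates=DEFAULT_COVARIATES,
                      case_groups: tuple[str, ...] = ("sptb_32_36", "sptb_lt32"),
                      ) -> pd.DataFrame:
    """Maximum-likelihood logistic regression of preterm outcome on the
    chosen length measurement, adjusted for the given covariates.

    Returns a coefficient table (coef, se, z, p, odds ratios per mm
    and per 0.1 MoM-equivalent unit).  Degenerate covariate columns
    raise instead of being silently dropped.
    """
    import statsmodels.api as sm

    col = _method_column(method)
    t = cohort.table
    y = t["outcome"].isin(case_groups).astype(int).to_numpy()
    if y.sum() < 10:
        raise ValueError(f"need >= 10 events, have {int(y.sum())}")
    if y.sum() == len(y):
        raise ValueError("no controls present")
    cols = [col, *covariates]
    for c in cols:
        if c not in t.columns:
            raise ValueError(f"covariate column {c!r} missing from cohort table")
        if np.var(t[c].to_numpy(dtype=float)) == 0:
            raise ValueError(f"covariate column {c!r} is constant; refusing to fit")
    x = sm.add_constant(t[cols].astype(float), has_constant="add")
    try:
        fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
    except Exception as exc:  # separation / non-convergence
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge (separation?)")
    out = pd.DataFrame({
        "coef": fit.params,
        "se": fit.bse,
        "z": fit.tvalues,
        "p": fit.pvalues,
        "odds_ratio": np.exp(fit.params),
    })
    med = float(t[col].median())
    out.loc[col, "or_per_0.1mom"] = float(np.exp(fit.params[col] * 0.1 * med))
    return out


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def power_two_sample(n1: int, n2: int, delta_mm: float, sd_mm: float,
                     alpha: float = 0.05) -> float:
    """Two-sided normal-approximation power for a two-sample mean
    comparison: Phi(lambda - z) + Phi(-lambda - z) with
    lambda = |delta| / (sd * sqrt(1/n1 + 1/n2)).  At delta = 0 this
    returns alpha (the type-I error rate)."""
    if n1 <= 0 or n2 <= 0 or sd_mm <= 0:
        raise ValueError("sample sizes and SD must be positive")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    lam = abs(delta_mm) / (sd_mm * np.sqrt(1.0 / n1 + 1.0 / n2))
    z = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(lam - z) + stats.norm.cdf(-lam - z))


# ---------------------------------------------------------------------------
# full evaluation report
# ---------------------------------------------------------------------------

def evaluate_cohort(cohort: ScreeningCohort, use_mom: bool = False) -> dict:
    """MoM tables, group tests, per-method AUROCs and the pairwise
    AUROC comparisons — the full screening evaluation in one call."""
    summary = cohort_summary(cohort)
    mom = {m: compute_mom(cohort, m) for m in METHOD_COLUMNS}
    tests = {}
    for m in METHOD_COLUMNS:
        try:
            tests[m] = group_compare(cohort, m)
        except ValueError:
            tests[m] = None
    roc = {}
    scores = {}
    for m in METHOD_COLUMNS:
        s, labels = risk_scores(cohort, m, use_mom=use_mom)
        scores[m] = s
        try:
            roc[m] = auroc(s, labels)
        except ValueError:
            roc[m] = None
    comparisons = {}
    if roc.get("ai") is not None:
        _, labels = risk_scores(cohort, "ai", use_mom=use_mom)
        for other in ("single", "two"):
            if roc.get(other) is not None:
                comparisons[f"ai_vs_{other}"] = compare_auroc(
                    scores["ai"], scores[other], labels)
    return {"summary": summary, "mom": mom, "group_tests": tests,
            "roc": roc, "roc_comparisons": comparisons}
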