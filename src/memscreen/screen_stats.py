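"""Statistics for the liposome synthesis screen.

A reaction condition counts as a successful synthesis environment when the
mean yield with liposomes exceeds the matched no-liposome control by more
than 1 pmol and a two-sided Welch t-test on the replicate arms is
significant (raw p in screening mode, Benjamini-Hochberg q in corrected
mode).  Replicates more than two standard deviations from the replicate
median are removed first, keeping at least three per arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SuccessCall",
    "remove_outliers",
    "call_success",
    "bh_correct",
    "preferred_composition",
    "interaction_model",
    "trajectory_norm",
    "extract_cv_qc",
    "call_screen",
]

MIN_DELTA_PMOL = 1.0  # success threshold on (+liposome) - (-liposome) mean yield
ALPHA = 0.05


@dataclass
class SuccessCall:
    """Outcome of one condition's +/- liposome comparison."""

    protein: str
    condition: object
    delta: float
    p: float
    q: float = float("nan")
    passed: bool = False

    def as_dict(self):
        return {
            "protein": self.protein,
            "condition": self.condition,
            "delta": self.delta,
            "p": self.p,
            "q": self.q,
            "passed": self.passed,
        }


def remove_outliers(replicates, min_keep: int = 3):
    """Drop replicates >= 2 sample SDs from the replicate median.

    The deviation is measured from the median of all replicates; the SD is
    the population SD (n denominator) over all replicates including the
    candidate.  At n = 4 this is the only variant whose operating point
    matches a ~7.5% contamination screen: the sample-SD form can
    essentially never fire once a gross outlier inflates the SD, and a
    leave-one-out SD flags more than twice the contamination.  Single
    pass: offenders are identified once, then removed worst-first until at
    most ``len - min_keep`` are gone.  Fewer than 4 replicates are
    returned unchanged with a warning.

    Returns (filtered array, number removed).
    """
    y = np.asarray(replicates, float)
    if y.size < 4:
        warnings.warn("fewer than 4 replicates; outlier removal skipped", stacklevel=2)
        return y, 0
    med = np.median(y)
    dev = np.abs(y - med)
    sd = y.std(ddof=0)
    if sd == 0:
        return y, 0
    offenders = np.flatnonzero((dev >= 2 * sd) & (dev > 0))
    # worst offenders first, capped so >= min_keep replicates survive
    offenders = offenders[np.argsort(-dev[offenders])][: max(0, y.size - min_keep)]
    keep = np.ones(y.size, bool)
    keep[offenders] = False
    return y[keep], int((~keep).sum())


def call_success(
    with_lipo,
    without_lipo,
    min_delta: float = MIN_DELTA_PMOL,
    alpha: float = ALPHA,
    protein: str = "",
    condition=None,
    remove: bool = True,
) -> SuccessCall:
    """Welch two-sided t-test on the +/- liposome arms of one condition."""
    a, _ = remove_outliers(with_lipo) if remove else (np.asarray(with_lipo, float), 0)
    b, _ = (
        remove_outliers(without_lipo)
        if remove
        else (np.asarray(without_lipo, float), 0)
    )
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 replicates per arm after outlier removal")
    delta = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    passed = (delta > min_delta) and (p < alpha)
    return SuccessCall(protein, condition, delta, p, passed=passed)


def bh_correct(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_screen(
    records: pd.DataFrame,
    condition_cols,
    min_delta: float = MIN_DELTA_PMOL,
    alpha: float = ALPHA,
    corrected: bool = True,
) -> pd.DataFrame:
    """Run success calling over a tidy screen table.

    ``records`` needs columns protein, liposome (bool), yield_pmol, plus
    the condition columns.  BH correction is applied within each protein
    across its tested conditions; in corrected mode a pass needs
    delta > min_delta and q < alpha, in screening mode raw p < alpha.
    """
    condition_cols = list(condition_cols)
    rows = []
    for (protein, *cond), grp in records.groupby(["protein", *condition_cols]):
        wl = grp.loc[grp["liposome"], "yield_pmol"].to_numpy()
        nl = grp.loc[~grp["liposome"], "yield_pmol"].to_numpy()
        if wl.size < 4 or nl.size < 4:
            continue
        call = call_success(
            wl, nl, min_delta=min_delta, alpha=alpha,
            protein=protein, condition=tuple(cond),
        )
        rows.append({**call.as_dict(), **dict(zip(condition_cols, cond))})
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = np.nan
    for protein, idx in table.groupby("protein").groups.items():
        table.loc[idx, "q"] = bh_correct(table.loc[idx, "p"].to_numpy())
    sig = table["q"] if corrected else table["p"]
    table["passed"] = (table["delta"] > min_delta) & (sig < alpha)
    return table


def preferred_composition(
    calls: pd.DataFrame, encoded_cols, top: int = 3
) -> pd.Series:
    """Per-factor mean normalized concentration over the top conditions.

    Conditions are ranked by mean delta (ties broken by smaller p, then
    input order); the encoded factor values of the top ``top`` are
    averaged.  ``encoded_cols`` name columns already min-max scaled.
    """
    if len(calls) < top:
        raise ValueError(f"need >= {top} conditions with computed deltas")
    ranked = calls.reset_index(drop=True).sort_values(
        ["delta", "p"], ascending=[False, True], kind="stable"
    )
    return ranked.head(top)[list(encoded_cols)].mean()


def interaction_model(conditions, yields, factor_names=None):
    """OLS with 5 main effects + 10 pairwise products + intercept.

    ``conditions`` are min-max scaled factor values (n, 5); ``yields`` are
    that protein's z-scored yields.  Returns a DataFrame of per-term
    coefficient and two-sided t-test p-value from the OLS covariance.
    """
    X = np.asarray(conditions, float)
    y = np.asarray(yields, float)
    n, k = X.shape
    if factor_names is None:
        factor_names = [f"x{j}" for j in range(k)]
    names = list(factor_names)
    cols = [X[:, j] for j in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            cols.append(X[:, i] * X[:, j])
            names.append(f"{factor_names[i]}x{factor_names[j]}")
    design = sm.add_constant(np.column_stack(cols), has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify the first columns that add no rank
        bad = []
        running = design[:, :1]
        for jcol, nm in enumerate(["const", *names]):
            if jcol == 0:
                continue
            cand = np.column_stack([running, design[:, jcol]])
            if np.linalg.matrix_rank(cand) == running.shape[1]:
                bad.append(nm)
            else:
                running = cand
        raise ValueError(f"rank-deficient interaction design; collinear terms: {bad}")
    fit = sm.OLS(y, design).fit()
    return pd.DataFrame(
        {"term": ["const", *names], "coef": fit.params, "p": fit.pvalues}
    ).set_index("term")


def trajectory_norm(standard_cond, best_cond, standard_yield, best_yield):
    """Per-factor Euclidean norm sqrt(dYield^2 + dConcentration^2).

    dConcentration = optimal - standard per factor (normalized scale);
    dYield = optimal - standard yield, shared across factors.
    """
    s = np.asarray(standard_cond, float)
    b = np.asarray(best_cond, float)
    dy = float(best_yield) - float(standard_yield)
    return np.sqrt(dy**2 + (b - s) ** 2)


def extract_cv_qc(replicate_sets, threshold: float = 0.10):
    """Extract-batch QC: mean CV across salt conditions must be <= threshold.

    ``replicate_sets`` maps condition -> replicate yields (>= 3 each).
    Conditions with non-positive mean are excluded with a warning.
    Returns (per-condition CV Series, passed flag).
    """
    cvs = {}
    for cond, reps in dict(replicate_sets).items():
        y = np.asarray(reps, float)
        if y.size < 3:
            raise ValueError(f"condition {cond!r}: need >= 3 replicates")
        m = y.mean()
        if m <= 0:
            warnings.warn(f"condition {cond!r} has non-positive mean; excluded",
                          stacklevel=2)
            continue
        cvs[cond] = y.std(ddof=1) / m
    cv = pd.Series(cvs, dtype=float)
    passed = bool(cv.mean() <= threshold) if len(cv) else True
    return cv, passed
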