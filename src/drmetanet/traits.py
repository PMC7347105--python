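"""Per-line lifespan traits: means, DR-AL difference, rLS, response classes.

The relative change in lifespan (rLS) is the residual of an ordinary
least-squares regression of each line's mean DR lifespan on its mean AL
lifespan.  By construction rLS sums to zero and is uncorrelated with AL
lifespan, which removes the confounding of the raw DR-AL difference with
baseline (AL) longevity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_FDR_METHODS = {"by": "fdr_by", "bh": "fdr_bh"}


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Per line x diet mean, count and SD of age at death.

    ``records`` has columns ``line_id``, ``diet``, ``age`` (one row per
    fly).  SD is NaN for single-fly cells.  Empty cells are simply absent.
    """
    if (records["age"] <= 0).any():
        raise ValueError("ages at death must be positive")
    g = records.groupby(["line_id", "diet"])["age"]
    out = g.agg(mean="mean", n="count", sd=lambda x: x.std(ddof=1))
    return out.reset_index()


def build_trait_table(records: pd.DataFrame,
                      diets=("AL", "DR")) -> pd.DataFrame:
    """Wide per-line table: mean_AL, mean_DR, n_AL, n_DR (index line_id)."""
    s = summarize(records)
    al, dr = diets
    wide = s.pivot(index="line_id", columns="diet")
    out = pd.DataFrame(index=wide.index)
    out["mean_AL"] = wide.get(("mean", al))
    out["mean_DR"] = wide.get(("mean", dr))
    out["n_AL"] = wide.get(("n", al))
    out["n_DR"] = wide.get(("n", dr))
    return out


def compute_rls(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Add rLS = residual of OLS(mean_DR ~ mean_AL), plus the shared fit.

    Lines missing either diet are excluded from the fit and get NaN rLS.
    """
    tt = trait_table.copy()
    both = tt[["mean_AL", "mean_DR"]].dropna()
    if len(both) < 3:
        raise ValueError("need >= 3 lines with both diets to fit rLS")
    x = both["mean_AL"].to_numpy()
    y = both["mean_DR"].to_numpy()
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("zero variance in mean AL lifespan; rLS undefined")
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    tt["rLS"] = tt["mean_DR"] - (intercept + slope * tt["mean_AL"])
    tt["fit_slope"] = slope
    tt["fit_intercept"] = intercept
    return tt


def delta_lifespan(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Add delta_LS = mean_DR - mean_AL (days); NaN when a diet is missing."""
    tt = trait_table.copy()
    tt["delta_LS"] = tt["mean_DR"] - tt["mean_AL"]
    return tt


def classify_response(
    records: pd.DataFrame,
    fdr_alpha: float = 0.05,
    fdr_method: str = "by",
    equal_var: bool = True,
    diets=("AL", "DR"),
) -> pd.Series:
    """Classify each line's DR response: longer / no_change / shorter.

    A two-sample Student's t-test (equal-variance by default; Welch with
    ``equal_var=False``) compares AL vs DR flies per line; p-values are FDR
    adjusted across lines and lines significant at ``fdr_alpha`` are called
    by the sign of the DR-AL difference.  Lines with fewer than 2 flies in
    either diet are ``unclassified``.
    """
    if fdr_method not in _FDR_METHODS:
        raise ValueError(f"fdr_method must be one of {sorted(_FDR_METHODS)}")
    al, dr = diets
    lines = records["line_id"].unique()
    pvals, diffs, testable = [], [], []
    for line in lines:
        sub = records[records["line_id"] == line]
        a = sub.loc[sub["diet"] == al, "age"].to_numpy()
        d = sub.loc[sub["diet"] == dr, "age"].to_numpy()
        if len(a) < 2 or len(d) < 2:
            continue
        t, p = stats.ttest_ind(d, a, equal_var=equal_var)
        if np.isnan(p):  # both samples constant and identical
            p = 1.0
        pvals.append(p)
        diffs.append(d.mean() - a.mean())
        testable.append(line)

    out = pd.Series("unclassified", index=pd.Index(lines, name="line_id"),
                    name="response_class")
    if testable:
        reject = multipletests(pvals, alpha=fdr_alpha,
                               method=_FDR_METHODS[fdr_method])[0]
        for line, sig, diff in zip(testable, reject, diffs):
            if sig and diff > 0:
                out[line] = "longer"
            elif sig and diff < 0:
                out[line] = "shorter"
            else:
                out[line] = "no_change"
    return out


def lifespan_traits(
    records: pd.DataFrame,
    fdr_alpha: float = 0.05,
    fdr_method: str = "by",
    diets=("AL", "DR"),
) -> pd.DataFrame:
    """Full TraitTable: means, counts, delta_LS, rLS, fit, response class."""
    tt = build_trait_table(records, diets=diets)
    tt = delta_lifespan(tt)
    tt = compute_rls(tt)
    tt["response_class"] = classify_response(
        records, fdr_alpha=fdr_alpha, fdr_method=fdr_method, diets=diets)
    tt.loc[tt["delta_LS"].isna(), "response_class"] = "unclassified"
    return tt
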