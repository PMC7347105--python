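"""Metabolite-trait association, paired diet-effect tests, and PCA summary.

Each lifespan trait (mean AL lifespan, mean DR lifespan, rLS) is modeled
per metabolite by ordinary least squares,

    trait = alpha + beta * metabolite + gamma * body_mass + error,

with genotype-wide mean body mass as a covariate, and a two-sided t-test
on the metabolite slope.  Families of tests are adjusted with the
Benjamini-Yekutieli (BY) step-up procedure, which remains valid under
dependence between metabolites.  The change-in-abundance model replaces
the metabolite level with delta-mz = DR value - AL value per line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .preprocess import MetaboliteMatrix


@dataclass
class AssociationResult:
    """One metabolite-trait OLS fit."""

    metabolite_id: str
    trait_name: str
    diet_of_measurement: str  # "AL", "DR" or "delta"
    alpha_hat: float
    beta_hat: float
    se_beta: float
    p: float
    n: int
    q: float = np.nan


@dataclass
class PCASummary:
    variance_fraction: np.ndarray   # non-increasing, sums to <= 1
    scores: pd.DataFrame            # samples x components


def by_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_by")[1]


def diet_effect_tests(matrix: MetaboliteMatrix,
                      diets=("AL", "DR")) -> pd.DataFrame:
    """Paired Student's t-test of DR vs AL per metabolite, across lines.

    Expects an across-diet normalized matrix (the diet contrast is the
    signal of interest).  Lines present under both diets are paired.
    Returns per metabolite: ``mean_delta`` (DR-AL), ``t``, ``p``, ``q`` (BY).
    """
    al, dr = diets
    a = matrix.diet_slice(al)
    d = matrix.diet_slice(dr)
    common = a.index.intersection(d.index)
    if len(common) < 2:
        raise ValueError("need >= 2 lines measured under both diets")
    a, d = a.loc[common], d.loc[common]
    diff = d.to_numpy() - a.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"), \
            warnings.catch_warnings():
        # near-constant difference columns trip scipy's precision warning;
        # that case is detected and reported explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_rel(d.to_numpy(), a.to_numpy(), axis=0)
    # identical columns: zero difference everywhere -> t = 0, p = 1
    zero = np.all(diff == 0, axis=0)
    t = np.where(zero, 0.0, t)
    p = np.where(zero, 1.0, p)
    # exact constant shift: the difference column is (numerically) constant,
    # so the paired t is unbounded and p underflows toward 0
    mean_abs = np.abs(diff.mean(axis=0))
    exact = (~zero) & (diff.std(axis=0) <= 1e-9 * np.maximum(1.0, mean_abs))
    p = np.where(exact, 0.0, p)
    out = pd.DataFrame({
        "metabolite_id": matrix.metabolite_ids,
        "mean_delta": diff.mean(axis=0),
        "t": t,
        "p": p,
        "exact_shift": exact,
        "n": len(common),
    })
    out["q"] = by_adjust(out["p"].to_numpy())
    return out


def pca_summary(matrix: MetaboliteMatrix, n_components: int | None = None
                ) -> PCASummary:
    """Principal components of the sample x metabolite matrix.

    Columns (metabolites) are mean-centered; variance fractions are the
    usual explained-variance ratios.
    """
    X = matrix.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete matrix")
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCASummary(
        variance_fraction=pca.explained_variance_ratio_,
        scores=pd.DataFrame(scores, index=matrix.data.index, columns=cols),
    )


def _ols_slope_test(y: np.ndarray, X: np.ndarray, slope_col: int
                    ) -> tuple[np.ndarray, float, float]:
    """OLS fit; returns (coef, se of slope_col, two-sided p)."""
    n, k = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - rank
    rss = float(resid @ resid)
    if df <= 0:
        raise ValueError("not enough observations for the requested model")
    XtX_inv = np.linalg.pinv(X.T @ X)
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        return coef, 0.0, 0.0  # exact fit
    se = float(np.sqrt(rss / df * XtX_inv[slope_col, slope_col]))
    t = coef[slope_col] / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return coef, se, float(p)


def fit_trait_on_metabolite(
    trait: pd.Series,
    metabolite: pd.Series,
    body_mass: pd.Series | None = None,
    trait_name: str = "trait",
    diet_of_measurement: str = "AL",
) -> AssociationResult:
    """OLS of one lifespan trait on one metabolite (+ body-mass covariate).

    Lines with a missing trait, metabolite or covariate value are dropped.
    A constant covariate is dropped with a warning; a covariate perfectly
    collinear with the metabolite (|r| = 1) is an error.
    """
    df = pd.DataFrame({"trait": trait, "met": metabolite})
    if body_mass is not None:
        df["mass"] = body_mass.reindex(df.index)
        n_before = df[["trait", "met"]].dropna().shape[0]
        df = df.dropna()
        if df.shape[0] < n_before:
            warnings.warn(
                f"{n_before - df.shape[0]} line(s) dropped for missing "
                "body mass", stacklevel=2)
    else:
        df = df.dropna()
    if df.shape[0] < 4:
        raise ValueError(f"need >= 4 complete lines, got {df.shape[0]}")
    met = df["met"].to_numpy(dtype=float)
    if met.std() == 0:
        raise ValueError("metabolite is constant across lines; slope undefined")
    cols = [np.ones(len(df)), met]
    if body_mass is not None:
        mass = df["mass"].to_numpy(dtype=float)
        if mass.std() == 0:
            warnings.warn("body-mass covariate is constant; dropped from the "
                          "model", stacklevel=2)
        else:
            r = np.corrcoef(met, mass)[0, 1]
            if abs(r) >= 1.0 - 1e-12:
                raise ValueError(
                    "metabolite and body mass are perfectly collinear")
            cols.append(mass)
    X = np.column_stack(cols)
    y = df["trait"].to_numpy(dtype=float)
    coef, se, p = _ols_slope_test(y, X, slope_col=1)
    return AssociationResult(
        metabolite_id=str(metabolite.name), trait_name=trait_name,
        diet_of_measurement=diet_of_measurement,
        alpha_hat=float(coef[0]), beta_hat=float(coef[1]),
        se_beta=se, p=p, n=len(df),
    )


def associate_all(
    trait_table: pd.DataFrame,
    matrix: MetaboliteMatrix,
    body_mass: pd.Series | None = None,
    traits: tuple = ("mean_AL", "mean_DR", "rLS"),
    alpha: float = 0.01,
    diets=("AL", "DR"),
) -> pd.DataFrame:
    """One OLS fit per (trait, diet of measurement, metabolite).

    BY adjustment is applied separately within each (trait, diet) family,
    mirroring per-panel FDR cutoffs.  Returns a tidy table with a
    ``significant`` flag at ``alpha``.
    """
    rows = []
    for diet in diets:
        slab = matrix.diet_slice(diet)
        for trait_name in traits:
            y = trait_table[trait_name]
            for met in slab.columns:
                res = fit_trait_on_metabolite(
                    y, slab[met], body_mass=body_mass,
                    trait_name=trait_name, diet_of_measurement=diet)
                rows.append(res)
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["q"] = np.nan
    for (_, _), idx in out.groupby(["trait_name", "diet_of_measurement"]).groups.items():
        out.loc[idx, "q"] = by_adjust(out.loc[idx, "p"].to_numpy())
    out["significant"] = out["q"] <= alpha
    return out


def delta_metabolites(matrix: MetaboliteMatrix,
                      diets=("AL", "DR")) -> pd.DataFrame:
    """Per-line change in abundance, delta-mz = DR - AL (normalized scale)."""
    al, dr = diets
    a = matrix.diet_slice(al)
    d = matrix.diet_slice(dr)
    common = a.index.intersection(d.index)
    return d.loc[common] - a.loc[common]


def associate_delta(
    rls: pd.Series,
    delta: pd.DataFrame,
    body_mass: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """rLS ~ delta-mz + body mass per metabolite, BY-adjusted at ``alpha``."""
    rows = []
    for met in delta.columns:
        res = fit_trait_on_metabolite(
            rls, delta[met], body_mass=body_mass,
            trait_name="rLS", diet_of_measurement="delta")
        rows.append(res)
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["q"] = by_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] <= alpha
    return out


def rls_associated_metabolites(assoc: pd.DataFrame, diet: str,
                               alpha: float = 0.01) -> list[str]:
    """Metabolites significantly associated with rLS when measured under
    ``diet`` (the per-diet input set for the gene-level GWAS)."""
    sel = assoc[(assoc["trait_name"] == "rLS")
                & (assoc["diet_of_measurement"] == diet)
                & (assoc["q"] <= alpha)]
    return sorted(sel["metabolite_id"])
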