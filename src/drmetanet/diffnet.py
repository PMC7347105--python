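"""Diet-differential Spearman correlation network.

For each diet a Spearman correlation matrix over metabolites is computed
from line-level (within-diet normalized) abundances.  To test whether a
metabolite pair's correlation differs between diets, each per-diet rho is
mapped to the scaled statistic

    s = rho * sqrt((n - 2) / (1 - rho^2)),

whose null distribution is approximately standard normal (it is the
t-statistic of the correlation).  With independent samples in the two
diets, the difference D = s_AL - s_DR is approximately Normal(0, 2) under
the null of equal correlation, so z = D / sqrt(2) yields a two-sided
normal p-value per pair.

Edges are categorized following the display rules of the analysis:

* ``AL_gain`` (red):  q <= alpha and rho_AL - rho_DR > delta_rho_min,
* ``DR_gain`` (blue): q <= alpha and rho_DR - rho_AL > delta_rho_min,
* ``shared`` (yellow): |rho| > shared_abs_min under *both* diets (a pure
  threshold, no test),

with red/blue assigned only when the larger correlation is positive
(negative-correlation differential edges are flagged, not categorized).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import by_adjust

#: value used in place of an infinite scaled statistic at |rho| = 1
SCALED_RHO_CAP = 1e6


def spearman_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Midrank (average-rank) Spearman correlation matrix of the columns."""
    X = data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("spearman_matrix requires a complete matrix")
    ranks = stats.rankdata(X, axis=0)
    C = np.corrcoef(ranks, rowvar=False)
    C = np.atleast_2d(C)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=data.columns, columns=data.columns)


def scaled_rho(rho, n, cap: float = SCALED_RHO_CAP):
    """The scaled correlation statistic rho * sqrt((n - 2) / (1 - rho^2)).

    Values with |rho| >= 1 would be infinite and are capped at ``+-cap``.
    Accepts scalars or arrays; requires n > 2.
    """
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 2):
        raise ValueError("scaled_rho requires n > 2")
    with np.errstate(divide="ignore", invalid="ignore"):
        s = rho * np.sqrt((n - 2.0) / (1.0 - rho ** 2))
    s = np.where(np.abs(rho) >= 1.0, np.sign(rho) * cap, s)
    s = np.clip(s, -cap, cap)
    return s if s.ndim else float(s)


def differential_test(rho_AL, n_AL, rho_DR, n_DR):
    """Difference of scaled correlations, its z-score and two-sided p.

    Returns ``(D, z, p)`` where ``D = s_AL - s_DR``, ``z = D / sqrt(2)``
    and ``p`` is the standard-normal two-sided tail probability.  Each diet
    uses its own sample size in the scaling.
    """
    D = scaled_rho(rho_AL, n_AL) - scaled_rho(rho_DR, n_DR)
    z = D / np.sqrt(2.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return D, z, p


def differential_edges(data_AL: pd.DataFrame,
                       data_DR: pd.DataFrame) -> pd.DataFrame:
    """All-pairs differential test between two line x metabolite tables.

    Returns one row per unordered metabolite pair (i < j by column order)
    with per-diet correlations, scaled statistics, D, z, p and BY q.
    """
    if list(data_AL.columns) != list(data_DR.columns):
        raise ValueError("the two diets must share the same metabolite panel")
    mets = list(data_AL.columns)
    n_al, n_dr = len(data_AL), len(data_DR)
    C_al = spearman_matrix(data_AL).to_numpy()
    C_dr = spearman_matrix(data_DR).to_numpy()
    iu, ju = np.triu_indices(len(mets), k=1)
    rho_al = C_al[iu, ju]
    rho_dr = C_dr[iu, ju]
    s_al = scaled_rho(rho_al, n_al)
    s_dr = scaled_rho(rho_dr, n_dr)
    D, z, p = differential_test(rho_al, n_al, rho_dr, n_dr)
    edges = pd.DataFrame({
        "met_i": np.asarray(mets)[iu],
        "met_j": np.asarray(mets)[ju],
        "rho_AL": rho_al,
        "rho_DR": rho_dr,
        "n_AL": n_al,
        "n_DR": n_dr,
        "s_AL": s_al,
        "s_DR": s_dr,
        "D": D,
        "z": z,
        "p": p,
        "capped": (np.abs(rho_al) >= 1.0) | (np.abs(rho_dr) >= 1.0),
    })
    edges["q"] = by_adjust(edges["p"].to_numpy())
    return edges


def classify_edges(
    edges: pd.DataFrame,
    delta_rho_min: float = 0.4,
    shared_abs_min: float = 0.8,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Assign the category column (AL_gain / DR_gain / shared / none)."""
    out = edges.copy()
    sig = out["q"] <= alpha
    d = out["rho_AL"] - out["rho_DR"]
    red = sig & (d > delta_rho_min)
    blue = sig & (-d > delta_rho_min)
    larger = np.where(d > 0, out["rho_AL"], out["rho_DR"])
    neg = (red | blue) & (larger <= 0)
    red &= ~neg
    blue &= ~neg
    yellow = ((out["rho_AL"].abs() > shared_abs_min)
              & (out["rho_DR"].abs() > shared_abs_min))

    cat = np.full(len(out), "none", dtype=object)
    cat[yellow.to_numpy()] = "shared"
    cat[red.to_numpy()] = "AL_gain"   # significance-based calls win
    cat[blue.to_numpy()] = "DR_gain"
    out["category"] = cat
    out["negative_flagged"] = neg.to_numpy()
    return out


def node_degrees(edges: pd.DataFrame, category: str,
                 metabolites=None) -> pd.Series:
    """Incident-edge count per metabolite for one category, ranked.

    Sorted by descending degree, ties broken lexicographically by
    metabolite id.  ``metabolites`` optionally supplies the full node set
    (so zero-degree nodes appear).
    """
    sel = edges[edges["category"] == category]
    counts = pd.concat([sel["met_i"], sel["met_j"]]).value_counts()
    if metabolites is not None:
        counts = counts.reindex(metabolites, fill_value=0)
    df = counts.rename("degree").rename_axis("metabolite_id").reset_index()
    df = df.sort_values(["degree", "metabolite_id"],
                        ascending=[False, True], kind="stable")
    return df.set_index("metabolite_id")["degree"]


def simulate_null_differences(
    n_samples: int,
    n_pairs: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo draws of D for independent-null metabolite pairs.

    For each replicate pair, two independent standard-normal variables of
    length ``n_samples`` are drawn per diet; the per-diet Spearman rho is
    scaled and differenced.  Used to verify the Normal(0, 2) null
    calibration of :func:`differential_test`.
    """
    def batch_rho(x, y):
        rx = stats.rankdata(x, axis=1)
        ry = stats.rankdata(y, axis=1)
        rx = rx - rx.mean(axis=1, keepdims=True)
        ry = ry - ry.mean(axis=1, keepdims=True)
        denom = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum(axis=1))
        return (rx * ry).sum(axis=1) / denom

    s = []
    for _diet in range(2):
        x = rng.standard_normal((n_pairs, n_samples))
        y = rng.standard_normal((n_pairs, n_samples))
        s.append(scaled_rho(batch_rho(x, y), n_samples))
    return s[0] - s[1]
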