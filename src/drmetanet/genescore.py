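"""Gene-level GWAS scores via adaptive min-P permutation testing.

Per-variant association is an additive linear model,

    phenotype ~ intercept + dosage + covariates

(Wolbachia infection status and inversion karyotypes as covariates), with
a two-sided t-test on the dosage slope.  Variants are assigned to a gene
when they fall within the gene interval or its +-1 kb window, and a gene's
raw statistic is the minimum p-value over its assigned variants.

Because genes with more variants reach smaller minimum p-values by chance,
the raw min-P is calibrated by permutation: the rows of the genotype
matrix are shuffled relative to (phenotype, covariates) jointly -- which
preserves the between-variant correlation (LD) within each permuted genome
-- and the per-gene min-P is recomputed.  The gene score is the add-one
permutation probability

    score = (n_hits + 1) / (n_perm + 1),

where a hit is a permutation whose min-P is <= the observed min-P (ties
count as hits).  Genes whose initial-round score falls at or below
``escalate_p`` are re-scored with a larger permutation count, mirroring
the adaptive 10,000 -> 1,000,000 escalation of the full analysis.

Implementation notes.  The permutation loop uses the Frisch-Waugh-Lovell
decomposition: the covariate block (with intercept) is orthonormalized
once, both phenotype and the permuted dosage columns are residualized
against it, and the squared t-statistic per variant is obtained from the
residual cross-products.  Since all variants share the same residual
degrees of freedom after mean-imputation of missing dosages, comparing
min-P values is equivalent to comparing max t^2, and no p-value needs to
be computed inside the loop.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GeneAnnotation, GenotypeMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-300


def maf_filter(genotypes: GenotypeMatrix, min_maf: float = 0.05
               ) -> GenotypeMatrix:
    """Keep variants with minor-allele frequency strictly above ``min_maf``.

    Monomorphic variants (MAF 0) are always dropped.
    """
    keep = genotypes.maf > min_maf
    return GenotypeMatrix(
        line_ids=genotypes.line_ids,
        variants=genotypes.variants.loc[keep].reset_index(drop=True),
        dosage=genotypes.dosage[:, keep],
    )


def _covariate_design(n: int, covariates: pd.DataFrame | np.ndarray | None
                      ) -> np.ndarray:
    """Intercept + covariate columns as a dense array."""
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows do not match the number of lines")
    return np.column_stack([np.ones(n), C])


def _orthonormal_basis(C: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of C (rank-reduced)."""
    q, r = np.linalg.qr(C)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def _t2_stats(Dr: np.ndarray, yr: np.ndarray, df: int) -> np.ndarray:
    """Squared t-statistics of per-variant slopes from residualized data.

    ``Dr``: residualized dosage (n x m or b x n x m); ``yr``: residualized
    phenotype (n,).  Degenerate (constant) variants get t^2 = 0.
    """
    yy = float(yr @ yr)
    if Dr.ndim == 2:
        dd = np.einsum("nm,nm->m", Dr, Dr)
        dy = yr @ Dr
    else:
        dd = np.einsum("bnm,bnm->bm", Dr, Dr)
        dy = np.einsum("bnm,n->bm", Dr, yr)
    with np.errstate(divide="ignore", invalid="ignore"):
        expl = dy ** 2 / np.maximum(dd, _EPS)
        t2 = df * expl / np.maximum(yy - expl, _EPS)
    return np.where(dd <= 1e-12, 0.0, t2)


def variant_association(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-variant OLS slope, SE and two-sided p-value.

    Lines with a missing dosage are dropped for that variant; variants
    constant after filtering are skipped (NaN statistics, logged).
    """
    y = np.asarray(phenotype, dtype=float)
    n, m = genotypes.dosage.shape
    if y.shape[0] != n:
        raise ValueError("phenotype length does not match line count")
    if np.nanstd(y) == 0:
        raise ValueError("phenotype is constant; association undefined")
    C = _covariate_design(n, covariates)
    D = genotypes.dosage

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    n_used = np.zeros(m, dtype=int)

    complete = ~np.isnan(D).any(axis=0)
    # fast path: all lines present
    if complete.any():
        Q = _orthonormal_basis(C)
        k = Q.shape[1]
        df = n - k - 1
        if df < 1:
            raise ValueError("too few lines for the covariate model")
        yr = y - Q @ (Q.T @ y)
        Dc = D[:, complete]
        Dr = Dc - Q @ (Q.T @ Dc)
        dd = np.einsum("nm,nm->m", Dr, Dr)
        dy = yr @ Dr
        # constant -- or collinear with the covariates -- after projection
        ok = dd > 1e-8 * n
        b = np.where(ok, dy / np.maximum(dd, _EPS), np.nan)
        rss = np.maximum(float(yr @ yr) - b ** 2 * dd, 0.0)
        s = np.sqrt(rss / df / np.maximum(dd, _EPS))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b / s
        pv = 2.0 * stats.t.sf(np.abs(t), df)
        pv = np.where(rss <= 1e-12 * max(1.0, float(y @ y)), 0.0, pv)
        idx = np.flatnonzero(complete)
        beta[idx] = np.where(ok, b, np.nan)
        se[idx] = np.where(ok, s, np.nan)
        p[idx] = np.where(ok, pv, np.nan)
        n_used[idx] = n
        skipped = idx[~ok]
        if skipped.size:
            logger.info("variant_association: %d constant variant(s) skipped",
                        skipped.size)
    # slow path: variants with missing calls
    for j in np.flatnonzero(~complete):
        mask = ~np.isnan(D[:, j])
        nj = int(mask.sum())
        Cj = C[mask]
        if nj < Cj.shape[1] + 2:
            logger.info("variant %d: only %d complete lines; skipped", j, nj)
            continue
        d = D[mask, j]
        if d.min() == d.max():
            logger.info("variant %d: constant after filtering; skipped", j)
            continue
        Q = _orthonormal_basis(Cj)
        df = nj - Q.shape[1] - 1
        yj = y[mask]
        yr = yj - Q @ (Q.T @ yj)
        dr = d - Q @ (Q.T @ d)
        dd = float(dr @ dr)
        if dd <= 1e-8 * nj:
            logger.info("variant %d: collinear with covariates; skipped", j)
            continue
        b = float(dr @ yr) / dd
        rss = max(float(yr @ yr) - b ** 2 * dd, 0.0)
        s = np.sqrt(rss / df / dd)
        p[j] = (0.0 if rss <= 1e-12 * max(1.0, float(yj @ yj))
                else 2.0 * stats.t.sf(abs(b / s), df))
        beta[j], se[j], n_used[j] = b, s, nj

    out = genotypes.variants[["chrom", "pos"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n_used
    return out


def assign_variants(genotypes: GenotypeMatrix, annotation: GeneAnnotation
                    ) -> dict[str, np.ndarray]:
    """Gene -> variant-index multimap (interval +- window, inclusive).

    A variant may be assigned to several overlapping genes.  Genes with no
    assigned variants are omitted.
    """
    w = annotation.window_bp
    chrom = genotypes.variants["chrom"].to_numpy()
    pos = genotypes.variants["pos"].to_numpy()
    out: dict[str, np.ndarray] = {}
    for row in annotation.genes.itertuples(index=False):
        mask = ((chrom == row.chrom)
                & (pos >= row.start - w) & (pos <= row.end + w))
        idx = np.flatnonzero(mask)
        if idx.size:
            out[row.gene_id] = idx
    return out


def gene_min_p(variant_p: pd.DataFrame | pd.Series,
               gene_map: dict[str, np.ndarray]) -> pd.Series:
    """Minimum variant p-value per gene (NaN p-values are ignored)."""
    p = (variant_p["p"] if isinstance(variant_p, pd.DataFrame)
         else variant_p).to_numpy(dtype=float)
    out = {}
    for gene, idx in gene_map.items():
        vals = p[idx]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            out[gene] = float(vals.min())
    return pd.Series(out, name="observed_min_p").rename_axis("gene_id")


def _mean_impute(D: np.ndarray) -> np.ndarray:
    if not np.isnan(D).any():
        return D
    D = D.copy()
    means = np.nanmean(D, axis=0)
    nan_r, nan_c = np.where(np.isnan(D))
    D[nan_r, nan_c] = means[nan_c]
    return D


def _gene_arrays(gene_map: dict[str, np.ndarray]
                 ) -> tuple[list[str], np.ndarray, np.ndarray]:
    genes = list(gene_map)
    flat = np.concatenate([gene_map[g] for g in genes])
    starts = np.cumsum([0] + [len(gene_map[g]) for g in genes[:-1]])
    return genes, flat, starts


def _count_hits(
    D: np.ndarray, yr: np.ndarray, Q: np.ndarray, df: int,
    flat: np.ndarray, starts: np.ndarray, obs_t2: np.ndarray,
    perms, block: int = 64,
) -> tuple[np.ndarray, int]:
    """Count permutations whose per-gene max t^2 >= the observed value."""
    hits = np.zeros(len(starts), dtype=np.int64)
    n_done = 0
    buf = []
    def flush(buf):
        nonlocal n_done
        P = np.asarray(buf)
        Dp = D[P]                                  # (b, n, m)
        QtD = np.einsum("nk,bnm->bkm", Q, Dp)
        Dr = Dp - np.einsum("nk,bkm->bnm", Q, QtD)
        t2 = _t2_stats(Dr, yr, df)                 # (b, m)
        gmax = np.maximum.reduceat(t2[:, flat], starts, axis=1)
        # ties ("equal to or lower") count as hits; the relative slack
        # absorbs summation-order float noise in mathematically tied stats
        hits[:] += (gmax >= obs_t2 * (1.0 - 1e-9)).sum(axis=0)
        n_done += len(buf)
    for perm in perms:
        buf.append(perm)
        if len(buf) == block:
            flush(buf)
            buf = []
    if buf:
        flush(buf)
    return hits, n_done


def permutation_gene_score(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None,
    gene_map: dict[str, np.ndarray],
    n_init: int = 10_000,
    n_max: int = 1_000_000,
    escalate_p: float = 1e-3,
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Adaptive permutation gene scores.

    Missing dosages are mean-imputed per variant before the permutation
    rounds so every permutation sees the same design.  With
    ``exhaustive=True`` all ``n_lines!`` row orders are enumerated instead
    of sampled (small cohorts only); ``n_init``/``n_max`` are then ignored.

    Returns a table with ``gene_id``, ``n_variants_assigned``,
    ``observed_min_p``, ``n_perm``, ``n_hits``, ``score`` and ``escalated``.
    """
    if n_max < n_init:
        raise ValueError("n_max must be >= n_init")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    y = np.asarray(phenotype, dtype=float)
    if y.std() == 0:
        raise ValueError("phenotype is constant; permutation score undefined")
    if not gene_map:
        raise ValueError("empty gene -> variant map")

    n = genotypes.n_lines
    D = _mean_impute(genotypes.dosage)
    C = _covariate_design(n, covariates)
    Q = _orthonormal_basis(C)
    df = n - Q.shape[1] - 1
    if df < 1:
        raise ValueError("too few lines for the covariate model")
    yr = y - Q @ (Q.T @ y)

    genes, flat, starts = _gene_arrays(gene_map)
    Dr0 = D - Q @ (Q.T @ D)
    t2_obs = _t2_stats(Dr0, yr, df)
    obs_gene_t2 = np.maximum.reduceat(t2_obs[flat], starts)
    obs_min_p = 2.0 * stats.t.sf(np.sqrt(obs_gene_t2), df)

    rng = np.random.default_rng(seed)
    if exhaustive:
        perms = itertools.permutations(range(n))
        hits, n_perm = _count_hits(D, yr, Q, df, flat, starts,
                                   obs_gene_t2, perms)
        n_perm_arr = np.full(len(genes), n_perm)
        escalated = np.zeros(len(genes), dtype=bool)
    else:
        perms = (rng.permutation(n) for _ in range(n_init))
        hits, _ = _count_hits(D, yr, Q, df, flat, starts, obs_gene_t2, perms)
        n_perm_arr = np.full(len(genes), n_init)
        score0 = (hits + 1) / (n_init + 1)
        esc_idx = np.flatnonzero(score0 <= escalate_p)
        escalated = np.zeros(len(genes), dtype=bool)
        if esc_idx.size and n_max > n_init:
            escalated[esc_idx] = True
            sub_map = {genes[i]: gene_map[genes[i]] for i in esc_idx}
            _, sub_flat, sub_starts = _gene_arrays(sub_map)
            perms = (rng.permutation(n) for _ in range(n_max))
            sub_hits, _ = _count_hits(
                D, yr, Q, df, sub_flat, sub_starts,
                obs_gene_t2[esc_idx], perms)
            hits[esc_idx] = sub_hits
            n_perm_arr[esc_idx] = n_max

    score = (hits + 1) / (n_perm_arr + 1)
    return pd.DataFrame({
        "gene_id": genes,
        "n_variants_assigned": [len(gene_map[g]) for g in genes],
        "observed_min_p": obs_min_p,
        "n_perm": n_perm_arr,
        "n_hits": hits,
        "score": score,
        "escalated": escalated,
    })


def exhaustive_gene_score(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None,
    gene_map: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Brute-force oracle: enumerate all n! row orders with textbook OLS.

    Independent of the fast path (per-permutation ``numpy.linalg.lstsq``
    fits and explicit p-values); intended for tests on <= 8 lines.  The
    score here is the exact enumeration probability ``n_hits / n_perm``
    (no add-one smoothing).
    """
    y = np.asarray(phenotype, dtype=float)
    n = genotypes.n_lines
    if n > 8:
        raise ValueError("exhaustive enumeration is for <= 8 lines")
    D = _mean_impute(genotypes.dosage)
    C = _covariate_design(n, covariates)

    def min_p_per_gene(Dperm: np.ndarray) -> dict[str, float]:
        pv = np.empty(Dperm.shape[1])
        for j in range(Dperm.shape[1]):
            X = np.column_stack([C, Dperm[:, j]])
            coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            dfree = n - rank
            rss = float(resid @ resid)
            cov = np.linalg.pinv(X.T @ X)
            denom = rss / dfree * cov[-1, -1]
            if denom <= 0:
                pv[j] = 0.0 if abs(coef[-1]) > 0 else 1.0
                continue
            t = coef[-1] / np.sqrt(denom)
            pv[j] = 2.0 * stats.t.sf(abs(t), dfree)
        return {g: float(pv[idx].min()) for g, idx in gene_map.items()}

    obs = min_p_per_gene(D)
    genes = list(gene_map)
    hits = {g: 0 for g in genes}
    n_perm = 0
    for perm in itertools.permutations(range(n)):
        mp = min_p_per_gene(D[list(perm)])
        for g in genes:
            # same tie rule (and float slack) as the sampling path
            if mp[g] <= obs[g] * (1.0 + 1e-9) + 1e-300:
                hits[g] += 1
        n_perm += 1

    return pd.DataFrame({
        "gene_id": genes,
        "n_variants_assigned": [len(gene_map[g]) for g in genes],
        "observed_min_p": [obs[g] for g in genes],
        "n_perm": n_perm,
        "n_hits": [hits[g] for g in genes],
        "score": [hits[g] / n_perm for g in genes],
        "escalated": False,
    })
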