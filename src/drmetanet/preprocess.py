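"""Metabolome normalization pipeline.

Raw metabolite abundance tables (samples = fly line x diet, columns =
metabolite features) are carried through a fixed normalization pipeline:

    log -> missingness filter -> KNN imputation -> within-sample scaling
        -> batch regression

Two batch-correction modes are supported, reflecting how downstream
analyses consume the data:

* ``within_diet`` -- the batch model is fitted separately inside each diet
  stratum.  Used for per-diet association models and the diet-differential
  correlation network.
* ``across_diet`` -- one pooled fit over all samples regardless of diet.
  Used for PCA and the paired diet-effect tests, where the diet contrast
  itself is the quantity of interest and must not be absorbed per stratum.

All operations are pure: they return a new :class:`MetaboliteMatrix` and
never mutate their input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered stages a matrix can be in.
STAGES = ("raw", "logged", "filtered", "imputed", "scaled", "batch_corrected")


@dataclass
class MetaboliteMatrix:
    """A samples x metabolites abundance table with provenance flags.

    Parameters
    ----------
    data:
        DataFrame indexed by a two-level MultiIndex ``(line_id, diet)`` with
        one column per metabolite.  Missing cells are ``NaN`` (allowed up to
        the ``imputed`` stage).
    batch:
        Per-sample batch label, aligned with ``data.index``.
    stage:
        Which pipeline stage the values are in (one of :data:`STAGES`).
    normalization_mode:
        ``"within_diet"``, ``"across_diet"`` or ``"none"`` -- stamped by
        :func:`regress_out_batch`.
    """

    data: pd.DataFrame
    batch: pd.Series | None = None
    stage: str = "raw"
    normalization_mode: str = "none"

    def __post_init__(self) -> None:
        if self.data.index.nlevels != 2:
            raise ValueError(
                "MetaboliteMatrix.data must be indexed by (line_id, diet)"
            )
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.batch is not None:
            self.batch = self.batch.reindex(self.data.index)
            if self.batch.isna().any():
                raise ValueError("batch labels missing for some samples")
        idx = self.data.index
        if idx.names != ["line_id", "diet"]:
            self.data = self.data.copy()
            self.data.index = idx.set_names(["line_id", "diet"])

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def diets(self) -> list[str]:
        return sorted(self.data.index.get_level_values("diet").unique())

    def diet_slice(self, diet: str) -> pd.DataFrame:
        """Lines x metabolites values for one diet (index = line_id)."""
        return self.data.xs(diet, level="diet")

    def _evolve(self, data: pd.DataFrame, stage: str, **kw) -> "MetaboliteMatrix":
        return replace(self, data=data, stage=stage, **kw)


@dataclass
class PreprocessConfig:
    """Parameters of the normalization pipeline."""

    mode: str = "within_diet"          # batch-correction mode
    max_missing_fraction: float = 0.05  # strict '>' excludes
    knn_k: int = 10
    min_co_observed: int = 3            # neighbor usable below this -> fallback
    dropped: list = field(default_factory=list)  # filled by preprocess()


def log_transform(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Natural-log transform; missing cells stay missing.

    Raises
    ------
    ValueError
        If any non-missing value is <= 0 (names the offending cell).
    """
    vals = matrix.data.to_numpy(dtype=float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        sample = matrix.data.index[i]
        met = matrix.data.columns[j]
        raise ValueError(
            f"non-positive abundance {vals[i, j]!r} at sample {sample}, "
            f"metabolite {met!r}: cannot log-transform"
        )
    out = pd.DataFrame(np.log(vals), index=matrix.data.index,
                       columns=matrix.data.columns)
    return matrix._evolve(out, "logged")


def filter_missing(
    matrix: MetaboliteMatrix, max_missing_fraction: float = 0.05
) -> tuple[MetaboliteMatrix, list[str]]:
    """Drop metabolites whose missing fraction strictly exceeds the threshold.

    Returns the filtered matrix and the list of dropped metabolite ids.
    """
    frac = matrix.data.isna().mean(axis=0)
    dropped = list(frac.index[frac > max_missing_fraction])
    if len(dropped) == matrix.data.shape[1]:
        raise ValueError(
            f"all {len(dropped)} metabolites exceed the missingness "
            f"threshold {max_missing_fraction}"
        )
    out = matrix.data.drop(columns=dropped)
    if dropped:
        logger.info("filter_missing: dropped %d metabolites: %s",
                    len(dropped), dropped)
    return matrix._evolve(out, "filtered"), dropped


def impute_missing(
    matrix: MetaboliteMatrix, k: int = 10, min_co_observed: int = 3
) -> MetaboliteMatrix:
    """K-nearest-neighbor imputation with metabolites as neighbor objects.

    For a missing cell (sample *s*, metabolite *m*), candidate neighbors are
    the other metabolites observed at *s*; distance between two metabolites
    is the Euclidean distance over their co-observed samples.  The imputed
    value is the mean of the *k* nearest candidates.  Metabolites with fewer
    than ``min_co_observed`` co-observed samples against every candidate
    fall back to the metabolite mean (logged).
    """
    if matrix.stage != "filtered":
        raise ValueError(
            f"impute_missing expects a 'filtered' matrix, got {matrix.stage!r}"
        )
    X = matrix.data.to_numpy(dtype=float).copy()
    n, m = X.shape
    obs = ~np.isnan(X)
    if obs.all():
        return matrix._evolve(matrix.data.copy(), "imputed")

    col_means = np.nanmean(X, axis=0)
    # pairwise Euclidean distance over co-observed samples, per metabolite pair
    dist = np.full((m, m), np.inf)
    co_n = np.zeros((m, m), dtype=int)
    for a in range(m):
        for b in range(a + 1, m):
            both = obs[:, a] & obs[:, b]
            nb = int(both.sum())
            co_n[a, b] = co_n[b, a] = nb
            if nb >= 1:
                d = float(np.sqrt(np.sum((X[both, a] - X[both, b]) ** 2)))
                dist[a, b] = dist[b, a] = d

    out = X.copy()
    for s, j in np.argwhere(~obs):
        cand = np.flatnonzero(obs[s] & (co_n[:, j] >= min_co_observed))
        cand = cand[np.isfinite(dist[cand, j])]
        if cand.size == 0:
            logger.info(
                "impute_missing: metabolite %s has no usable neighbors at "
                "sample %s; falling back to metabolite mean",
                matrix.data.columns[j], matrix.data.index[s],
            )
            out[s, j] = col_means[j]
            continue
        order = cand[np.argsort(dist[cand, j], kind="stable")]
        out[s, j] = float(np.mean(X[s, order[:k]]))

    res = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return matrix._evolve(res, "imputed")


def scale_within_sample(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Mean-center and unit-scale each sample row (SD with n-1 denominator).

    Normalizes for variation in total analyte amount per sample (fly
    weight/size).  Rows with zero SD are an error.
    """
    X = matrix.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("scale_within_sample requires a complete matrix")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise ValueError(
            f"constant sample row(s), zero SD: {matrix.data.index[zero].tolist()}"
        )
    out = pd.DataFrame((X - mu) / sd, index=matrix.data.index,
                       columns=matrix.data.columns)
    return matrix._evolve(out, "scaled")


def regress_out_batch(matrix: MetaboliteMatrix, mode: str) -> MetaboliteMatrix:
    """Remove additive batch effects by linear model, per metabolite.

    Fitting ``value ~ intercept + batch`` by least squares and keeping
    residual + stratum grand mean is algebraically equivalent to subtracting
    each batch's mean and adding back the stratum grand mean (one-way ANOVA
    fitted values are the batch means); that closed form is used here.

    ``mode="within_diet"`` fits separately inside each diet; ``"across_diet"``
    fits one pooled model.  Strata with a single batch are returned unchanged.
    """
    if mode not in ("within_diet", "across_diet"):
        raise ValueError(f"unknown batch-correction mode {mode!r}")
    if matrix.batch is None:
        raise ValueError("matrix has no batch labels")
    if matrix.data.isna().any().any():
        raise ValueError("regress_out_batch requires a complete matrix")

    df = matrix.data
    batch = matrix.batch

    if mode == "across_diet":
        # warn when a batch never crosses diets: its effect is then
        # unidentifiable beyond the diet contrast it is nested in
        diets_per_batch = (
            pd.Series(df.index.get_level_values("diet"), index=df.index)
            .groupby(batch).nunique()
        )
        confounded = diets_per_batch.index[diets_per_batch == 1].tolist()
        if confounded and diets_per_batch.size > 1:
            warnings.warn(
                f"batch(es) {confounded} contain samples of a single diet; "
                "their batch effect is confounded with diet under "
                "across_diet correction",
                stacklevel=2,
            )
        strata = [df.index]
    else:
        strata = [
            df.index[df.index.get_level_values("diet") == d]
            for d in matrix.diets
        ]

    out = df.copy()
    for idx in strata:
        sub = df.loc[idx]
        b = batch.loc[idx]
        counts = b.value_counts()
        if len(counts) < 2:
            continue
        if (counts < 2).any():
            small = counts.index[counts < 2].tolist()
            warnings.warn(
                f"batch(es) {small} have <2 samples in stratum; batch means "
                "are poorly estimated", stacklevel=2,
            )
        grand = sub.mean(axis=0)
        batch_means = sub.groupby(b.to_numpy()).transform("mean")
        out.loc[idx] = sub - batch_means + grand

    return matrix._evolve(out, "batch_corrected", normalization_mode=mode)


def preprocess(
    raw: MetaboliteMatrix, config: PreprocessConfig | None = None
) -> MetaboliteMatrix:
    """Full pipeline: log -> filter -> impute -> scale -> batch regression.

    The dropped-metabolite list is recorded on ``config.dropped``.
    """
    config = config or PreprocessConfig()
    m = log_transform(raw)
    m, dropped = filter_missing(m, config.max_missing_fraction)
    config.dropped = dropped
    m = impute_missing(m, k=config.knn_k, min_co_observed=config.min_co_observed)
    m = scale_within_sample(m)
    m = regress_out_batch(m, config.mode)
    return m
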