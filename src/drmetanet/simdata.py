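"""Synthetic DGRP-like cohorts with planted gene->metabolite->lifespan paths.

The generator emulates the design of a dietary-restriction (DR) panel study:
a set of fully inbred fly lines, each measured under an ad libitum (AL) and
a DR diet, with

* a line x variant genotype matrix (inbred lines are homozygous, so dosage
  is coded 0/1 = non-carrier/carrier of the minor allele),
* a line x diet metabolite abundance table with diet-specific correlation
  blocks, additive batch offsets, and missing cells (MCAR),
* per-fly ages at death, where the line's DR mean responds linearly to its
  AL mean plus planted metabolite-mediated effects,
* line-level covariates (body mass, Wolbachia infection, inversion
  karyotypes).

Every planted effect is recorded so that downstream recovery can be scored
against known truth.  All outputs are deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import MetaboliteMatrix

DIETS = ("AL", "DR")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PlantedEffect:
    """A causal gene -> metabolite -> lifespan-response path.

    ``beta_gm`` is the per-allele shift of the target metabolite in z-units
    (latent log scale); ``beta_m_rls`` is the slope of the DR lifespan
    response on that metabolite, in days per z-unit.
    """

    gene_id: str
    causal_variant: int
    target_metabolite: str
    diet_of_effect: str = "both"  # "AL", "DR" or "both"
    beta_gm: float = 0.8
    beta_m_rls: float = 0.0

    def __post_init__(self) -> None:
        if self.diet_of_effect not in (*DIETS, "both"):
            raise ValueError(f"diet_of_effect {self.diet_of_effect!r}")


@dataclass
class CorrelationBlock:
    """A block of metabolites equicorrelated within each diet."""

    metabolites: list  # column indices into the metabolite panel
    rho_AL: float = 0.0
    rho_DR: float = 0.0


@dataclass
class SimConfig:
    """All knobs of the cohort generator.

    Defaults are a desk-scale cohort (40 lines, 500 variants, 30
    metabolites, 50 flies per line x diet); :func:`full_scale_config`
    returns the full study dimensions (178 lines, 105 metabolites, 200
    flies per cell).
    """

    n_lines: int = 40
    n_variants: int = 500
    n_genes: int = 50
    n_metabolites: int = 30
    maf_range: tuple = (0.1, 0.5)
    exact_maf: bool = False
    n_flies_per_cell: int = 50
    diet_labels: tuple = DIETS
    n_batches: int = 3
    missing_rate: float = 0.02
    missing_rate_cap: float = 0.05     # safety margin vs. the >5% filter
    planted_effects: list = field(default_factory=list)
    correlation_blocks: list = field(default_factory=list)
    noise_sd: float = 0.1              # measurement noise on latent z scale
    batch_effect_sd: float = 0.5       # per (batch, metabolite) offset SD
    diet_shift_sd: float = 0.0         # per-metabolite DR-vs-AL log shift SD
    # lifespan model (days)
    al_mean: float = 40.0
    al_sd: float = 7.0
    dr_intercept: float = 10.0
    dr_slope: float = 1.0
    rls_sd: float = 6.0                # line-level DR-response noise
    fly_sd: float = 10.0               # per-fly age-at-death SD
    lifespan_dist: str = "normal"      # "normal" (truncated at 0) or "gompertz"
    # genome layout
    chrom: str = "2R"
    variant_spacing: int = 2000        # bp between adjacent variants
    gene_window_bp: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.missing_rate >= self.missing_rate_cap:
            raise ValueError(
                f"missing_rate {self.missing_rate} >= cap {self.missing_rate_cap}: "
                "whole metabolites would be at risk of exclusion downstream"
            )
        if self.n_flies_per_cell < 2:
            raise ValueError("n_flies_per_cell must be >= 2")
        if len(self.diet_labels) != 2:
            raise ValueError("exactly two diet labels required")
        if self.lifespan_dist not in ("normal", "gompertz"):
            raise ValueError(f"lifespan_dist {self.lifespan_dist!r}")
        self.planted_effects = [
            PlantedEffect(**e) if isinstance(e, dict) else e
            for e in self.planted_effects
        ]
        self.correlation_blocks = [
            CorrelationBlock(**b) if isinstance(b, dict) else b
            for b in self.correlation_blocks
        ]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(d["maf_range"])
        d["diet_labels"] = list(d["diet_labels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["maf_range"] = tuple(d["maf_range"])
        d["diet_labels"] = tuple(d["diet_labels"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def full_scale_config(**overrides) -> SimConfig:
    """Config mirroring the full study dimensions (178 lines x 2 diets,
    105 metabolites, ~200 flies per line x diet)."""
    base = dict(
        n_lines=178, n_variants=5000, n_genes=500, n_metabolites=105,
        n_flies_per_cell=200, n_batches=6,
    )
    base.update(overrides)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Line x variant dosage matrix for inbred (homozygous) lines.

    ``dosage`` entries are 0/1 (carrier coding) with NaN for missing calls.
    """

    line_ids: list
    variants: pd.DataFrame  # chrom, pos (1-based), ref, alt, monomorphic
    dosage: np.ndarray      # (n_lines, n_variants) float

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.line_ids), len(self.variants)):
            raise ValueError("dosage shape does not match line/variant counts")
        if (self.variants["pos"] < 1).any():
            raise ValueError("positions are 1-based and must be >= 1")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant, from non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f = np.nanmean(self.dosage, axis=0)
        return np.minimum(f, 1.0 - f)


@dataclass
class GeneAnnotation:
    """Gene intervals (1-based, inclusive) with a flanking window."""

    genes: pd.DataFrame  # gene_id, chrom, start, end
    window_bp: int = 1000

    def __post_init__(self) -> None:
        if (self.genes["start"] > self.genes["end"]).any():
            raise ValueError("gene start must be <= end")


@dataclass
class SyntheticCohort:
    """Everything a downstream stage needs, plus the ground truth."""

    config: SimConfig
    genotypes: GenotypeMatrix
    annotation: GeneAnnotation
    metabolome_raw: MetaboliteMatrix
    latent: pd.DataFrame          # truth: (line, diet) x metabolite z values
    lifespans: pd.DataFrame       # per-fly: line_id, diet, age
    covariates: pd.DataFrame      # per line: body_mass, wolbachia, inversions
    line_truth: pd.DataFrame      # per line: true AL/DR means, true rLS


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n_lines: int,
    n_variants: int,
    maf_range=(0.05, 0.5),
    seed: int = 0,
    exact_freq: bool = False,
    max_redraws: int = 10,
    chrom: str = "2R",
    spacing: int = 2000,
) -> GenotypeMatrix:
    """Draw independent biallelic variants for inbred lines.

    Each variant gets a target minor-allele frequency drawn uniformly from
    ``maf_range``.  With ``exact_freq=True`` exactly ``round(maf * n_lines)``
    lines carry the minor allele (at least one); otherwise carriers are
    Bernoulli draws, re-drawn up to ``max_redraws`` times if the column comes
    out monomorphic, after which the variant is flagged ``monomorphic``.
    """
    if n_lines < 3:
        raise ValueError("need at least 3 lines")
    if n_variants < 1:
        raise ValueError("need at least 1 variant")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")

    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_variants)
    dosage = np.zeros((n_lines, n_variants))
    mono = np.zeros(n_variants, dtype=bool)
    for v in range(n_variants):
        if exact_freq:
            k = max(1, int(round(mafs[v] * n_lines)))
            carriers = rng.choice(n_lines, size=min(k, n_lines - 1), replace=False)
            col = np.zeros(n_lines)
            col[carriers] = 1.0
        else:
            col = (rng.random(n_lines) < mafs[v]).astype(float)
            tries = 0
            while col.min() == col.max() and tries < max_redraws:
                col = (rng.random(n_lines) < mafs[v]).astype(float)
                tries += 1
            if col.min() == col.max():
                mono[v] = True
        dosage[:, v] = col

    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=n_variants)
    alt = np.array([rng.choice(bases[bases != r]) for r in ref])
    variants = pd.DataFrame({
        "chrom": chrom,
        "pos": 1 + spacing * np.arange(n_variants),
        "ref": ref,
        "alt": alt,
        "monomorphic": mono,
    })
    line_ids = [f"line_{i:03d}" for i in range(n_lines)]
    return GenotypeMatrix(line_ids, variants, dosage)


def make_gene_annotation(
    genotypes: GenotypeMatrix, n_genes: int, window_bp: int = 1000
) -> GeneAnnotation:
    """Tile the variant positions into ``n_genes`` contiguous gene intervals."""
    pos = genotypes.variants["pos"].to_numpy()
    chrom = genotypes.variants["chrom"].iloc[0]
    groups = np.array_split(np.arange(len(pos)), n_genes)
    rows = []
    for g, idx in enumerate(groups):
        if idx.size == 0:
            continue
        rows.append({
            "gene_id": f"gene_{g:03d}",
            "chrom": chrom,
            "start": int(pos[idx[0]]),
            "end": int(pos[idx[-1]]),
        })
    return GeneAnnotation(pd.DataFrame(rows), window_bp=window_bp)


def _block_cholesky(n_metabolites: int, blocks: list, diet: str) -> np.ndarray:
    """Cholesky factor of the per-diet block correlation matrix."""
    C = np.eye(n_metabolites)
    for b in blocks:
        rho = b.rho_AL if diet == "AL" else b.rho_DR
        idx = np.asarray(b.metabolites, dtype=int)
        for i in idx:
            for j in idx:
                if i != j:
                    C[i, j] = rho
    w = np.linalg.eigvalsh(C)
    if w.min() < -1e-10:
        raise ValueError(
            f"correlation specification for diet {diet} is not positive "
            f"semi-definite (min eigenvalue {w.min():.3g}); reduce block "
            "correlations or block overlap"
        )
    # jitter exactly-singular specs so Cholesky succeeds
    return np.linalg.cholesky(C + 1e-10 * np.eye(n_metabolites))


def simulate_metabolome(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Draw the raw metabolome and its latent truth.

    Per diet, line-level latent z values come from a multivariate normal
    with the diet's block correlation; planted ``beta_gm`` shifts are added
    for minor-allele carriers.  The observed table adds measurement noise,
    per-(batch, metabolite) offsets (one offset per batch, shared across
    diets), an optional per-metabolite diet main effect
    (``diet_shift_sd``), and a per-metabolite baseline, is
    exponentiated (so raw abundances are positive and log-normal), and has
    cells blanked completely at random at ``missing_rate``.

    Returns ``(raw_matrix, latent)`` where ``latent`` is the (line, diet) x
    metabolite truth on the z scale (planted shifts included, noise and
    batch excluded).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, m = genotypes.n_lines, config.n_metabolites
    met_ids = [f"met_{j:03d}" for j in range(m)]
    met_pos = {mid: j for j, mid in enumerate(met_ids)}

    frames, batches = [], []
    latents = []
    mu = rng.normal(3.0, 1.0, size=m)  # per-metabolite baseline log abundance
    # one offset per (batch, metabolite): handling batches span diets, so a
    # pooled across-diet batch fit can remove them
    offsets = rng.normal(0.0, config.batch_effect_sd,
                         size=(config.n_batches, m))
    # optional systematic diet response of the metabolome (log scale)
    diet_shift = (rng.normal(0.0, config.diet_shift_sd, size=m)
                  if config.diet_shift_sd > 0 else np.zeros(m))
    for diet in config.diet_labels:
        L = _block_cholesky(m, config.correlation_blocks, diet)
        z = rng.standard_normal((n, m)) @ L.T
        for eff in config.planted_effects:
            if eff.beta_gm and eff.diet_of_effect in (diet, "both"):
                carriers = genotypes.dosage[:, eff.causal_variant] == 1
                z[carriers, met_pos[eff.target_metabolite]] += eff.beta_gm
        idx = pd.MultiIndex.from_arrays(
            [genotypes.line_ids, [diet] * n], names=["line_id", "diet"])
        latents.append(pd.DataFrame(z, index=idx, columns=met_ids))

        # balanced batch assignment within diet
        order = rng.permutation(n)
        batch = np.empty(n, dtype=object)
        batch[order] = [f"batch_{i % config.n_batches}" for i in range(n)]
        batch_num = np.array([int(b.split("_")[1]) for b in batch])
        shift = diet_shift if diet == config.diet_labels[1] else 0.0
        observed = (mu + shift + z
                    + config.noise_sd * rng.standard_normal((n, m))
                    + offsets[batch_num])
        raw = np.exp(observed)
        if config.missing_rate > 0:
            raw[rng.random((n, m)) < config.missing_rate] = np.nan
        frames.append(pd.DataFrame(raw, index=idx, columns=met_ids))
        batches.append(pd.Series(batch, index=idx, name="batch"))

    data = pd.concat(frames)
    batch = pd.concat(batches)
    latent = pd.concat(latents)
    return MetaboliteMatrix(data=data, batch=batch, stage="raw"), latent


def _effect_term(latent: pd.DataFrame, config: SimConfig,
                 line_ids: list) -> np.ndarray:
    """Planted metabolite-mediated contribution to each line's DR response."""
    term = np.zeros(len(line_ids))
    for eff in config.planted_effects:
        if not eff.beta_m_rls:
            continue
        if eff.diet_of_effect == "both":
            vals = latent[eff.target_metabolite].groupby(level="line_id").mean()
        else:
            vals = latent[eff.target_metabolite].xs(
                eff.diet_of_effect, level="diet")
        term += eff.beta_m_rls * vals.reindex(line_ids).to_numpy()
    return term


def simulate_lifespans(
    genotypes: GenotypeMatrix,
    latent: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-fly ages at death.

    Line mean AL lifespan ~ Normal(``al_mean``, ``al_sd``).  Line mean DR
    lifespan = ``dr_intercept + dr_slope * AL_mean`` + planted metabolite
    effects + Normal(0, ``rls_sd``) noise; the latter two terms are the
    line's true lifespan response (rLS) up to the fitted regression.
    Per-fly ages are truncated-normal (at 0) around the line x diet mean, or
    Gompertz with matched mean when ``lifespan_dist="gompertz"``.

    Returns ``(records, line_truth)``: per-fly rows ``(line_id, diet, age)``
    and the per-line truth table (true means and true rLS deviation).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = genotypes.n_lines
    al = rng.normal(config.al_mean, config.al_sd, size=n)
    effect = _effect_term(latent, config, genotypes.line_ids)
    resp_noise = (rng.normal(0.0, config.rls_sd, size=n)
                  if config.rls_sd > 0 else np.zeros(n))
    dr = config.dr_intercept + config.dr_slope * al + effect + resp_noise

    bad = (al <= 0) | (dr <= 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} simulated line mean lifespans were <= 0 and "
            "were truncated to 1 day", stacklevel=2)
        al = np.maximum(al, 1.0)
        dr = np.maximum(dr, 1.0)

    k = config.n_flies_per_cell
    rows = {"line_id": [], "diet": [], "age": []}
    for means, diet in ((al, "AL"), (dr, "DR")):
        diet_label = config.diet_labels[0] if diet == "AL" else config.diet_labels[1]
        for i, line in enumerate(genotypes.line_ids):
            if config.lifespan_dist == "normal":
                a = (0.0 - means[i]) / config.fly_sd
                ages = stats.truncnorm.rvs(
                    a, np.inf, loc=means[i], scale=config.fly_sd,
                    size=k, random_state=rng)
            else:  # Gompertz with shape c=2, scale matched to the mean
                c = 2.0
                scale = means[i] / stats.gompertz.mean(c)
                ages = stats.gompertz.rvs(c, scale=scale, size=k,
                                          random_state=rng)
            rows["line_id"].extend([line] * k)
            rows["diet"].extend([diet_label] * k)
            rows["age"].extend(np.asarray(ages, dtype=float))
    records = pd.DataFrame(rows)

    line_truth = pd.DataFrame({
        "line_id": genotypes.line_ids,
        "al_mean_true": al,
        "dr_mean_true": dr,
        # deviation from the population DR~AL line: metabolite effects + noise
        "rls_true": effect + resp_noise,
    })
    return records, line_truth


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Compose genotypes, metabolome, lifespans and covariates; record truth."""
    ss = np.random.SeedSequence(config.seed)
    s_geno, s_met, s_life, s_cov = ss.spawn(4)
    genotypes = simulate_genotypes(
        config.n_lines, config.n_variants, config.maf_range,
        seed=s_geno, exact_freq=config.exact_maf,
        chrom=config.chrom, spacing=config.variant_spacing)
    annotation = make_gene_annotation(genotypes, config.n_genes,
                                      window_bp=config.gene_window_bp)
    metabolome, latent = simulate_metabolome(
        genotypes, config, rng=np.random.default_rng(s_met))
    lifespans, line_truth = simulate_lifespans(
        genotypes, latent, config, rng=np.random.default_rng(s_life))

    rng = np.random.default_rng(s_cov)
    covariates = pd.DataFrame({
        "line_id": genotypes.line_ids,
        "body_mass": np.maximum(rng.normal(1.2, 0.15, config.n_lines), 0.5),
        "wolbachia": rng.integers(0, 2, config.n_lines),
        "In2Lt": (rng.random(config.n_lines) < 0.2).astype(int),
        "In3RP": (rng.random(config.n_lines) < 0.1).astype(int),
    }).set_index("line_id")

    return SyntheticCohort(
        config=config, genotypes=genotypes, annotation=annotation,
        metabolome_raw=metabolome, latent=latent, lifespans=lifespans,
        covariates=covariates, line_truth=line_truth,
    )
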