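"""Shared fixtures: small synthetic cohorts and study-scale presets."""

import numpy as np
import pandas as pd
import pytest

import drmetanet as dm


@pytest.fixture(scope="session")
def desk_cohort():
    """Default desk-scale cohort (40 lines, 500 variants, 30 metabolites)."""
    return dm.simulate_cohort(dm.SimConfig(seed=11))


@pytest.fixture(scope="session")
def desk_processed(desk_cohort):
    return dm.preprocess(desk_cohort.metabolome_raw,
                         dm.PreprocessConfig(mode="within_diet"))


@pytest.fixture(scope="session")
def desk_traits(desk_cohort):
    return dm.lifespan_traits(desk_cohort.lifespans)


def planted_path_config(seed: int) -> dm.SimConfig:
    """Study-scale cohort with one planted gene -> metabolite -> rLS path.

    Full-study-scale statistical surface (178 lines x 2 diets, 105 metabolites)
    over a small genome of 12 genes x 4 variants (3 kb spacing keeps the
    +-1 kb windows from crossing gene boundaries).  The causal variant sits
    at MAF 0.3 with a 0.8 z-unit AL-specific metabolite shift, and the
    target metabolite drives the DR response at 4 days per z-unit.
    """
    return dm.SimConfig(
        seed=seed,
        n_lines=178,
        n_metabolites=105,
        n_variants=48,
        n_genes=12,
        variant_spacing=3000,
        exact_maf=True,
        maf_range=(0.3, 0.3),
        planted_effects=[dm.PlantedEffect(
            gene_id="gene_005", causal_variant=20,
            target_metabolite="met_005", diet_of_effect="AL",
            beta_gm=0.8, beta_m_rls=4.0)],
    )


def tiny_genotypes(n_lines, dosage_cols, seed=0):
    """GenotypeMatrix from explicit dosage columns (for oracle fixtures)."""
    dosage = np.column_stack(dosage_cols).astype(float)
    n_var = dosage.shape[1]
    variants = pd.DataFrame({
        "chrom": "2R",
        "pos": 1 + 2000 * np.arange(n_var),
        "ref": "C", "alt": "T",
        "monomorphic": False,
    })
    lines = [f"line_{i:03d}" for i in range(n_lines)]
    return dm.GenotypeMatrix(lines, variants, dosage)
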